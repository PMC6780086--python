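"""Core domain types shared by all analysis stages.

The experimental design is a reciprocal phosphate perturbation: cultures
grown phosphate-replete (PR), shifted to phosphate-depleted medium (PD),
and then restored to replete medium (PDR), each sampled in triplicate.
Expression values are TPM (transcripts per million); annotation maps genes
to EC numbers (enzymes are frequently encoded by several gene copies) and
to metabolic pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, InputError

#: Culture conditions in experimental order.
CONDITIONS = ("PR", "PD", "PDR")

#: Relative phosphate level of the growth medium under each condition.
DEFAULT_PHOSPHATE_LEVEL = {"PR": 1.0, "PD": 0.0, "PDR": 1.0}


@dataclass(frozen=True)
class SampleDesign:
    """One sequenced/measured sample.

    Parameters
    ----------
    sample_id :
        Unique sample name, used as the column header in all tables.
    condition :
        One of ``PR``, ``PD``, ``PDR``.
    replicate :
        1-based replicate index within the condition.
    phosphate_level :
        Relative phosphate concentration of the medium (PR=1, PD=0,
        PDR=1 by default).  Used as the reference vector when judging
        whether an expression profile tracks phosphate.
    """

    sample_id: str
    condition: str
    replicate: int
    phosphate_level: float = -1.0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DesignError(
                f"unknown condition {self.condition!r} for sample "
                f"{self.sample_id!r}; expected one of {CONDITIONS}"
            )
        if self.replicate < 1:
            raise DesignError(f"replicate must be >= 1 for sample {self.sample_id!r}")
        if self.phosphate_level == -1.0:
            object.__setattr__(
                self, "phosphate_level", DEFAULT_PHOSPHATE_LEVEL[self.condition]
            )
        if self.phosphate_level < 0:
            raise DesignError(
                f"phosphate_level must be non-negative for sample {self.sample_id!r}"
            )


def validate_design(samples: list[SampleDesign]) -> None:
    """Check that sample ids are unique."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DesignError(f"duplicate sample ids in design: {dupes}")


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative TPM values.

    ``data`` is indexed by gene id with one column per sample, ordered as
    in ``samples``.  The matrix must be complete: no missing values.
    """

    data: pd.DataFrame
    samples: list[SampleDesign]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        validate_design(self.samples)
        cols = list(self.data.columns)
        ids = [s.sample_id for s in self.samples]
        if cols != ids:
            raise DesignError(
                f"matrix columns {cols} do not match design sample ids {ids}"
            )
        if self.data.index.duplicated().any():
            dupes = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if np.isnan(values).any():
            gene = self.data.index[np.isnan(values).any(axis=1)][0]
            raise FormatError(f"missing value in expression matrix at gene {gene!r}")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative value at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    def condition_samples(self, condition: str) -> list[str]:
        ids = [s.sample_id for s in self.samples if s.condition == condition]
        if not ids:
            raise DesignError(f"no samples for condition {condition!r}")
        return ids

    def condition_values(self, condition: str) -> np.ndarray:
        """Gene x replicate array of TPM for one condition."""
        return self.data[self.condition_samples(condition)].to_numpy()

    def phosphate_vector(self) -> np.ndarray:
        """Per-sample medium phosphate level, in column order."""
        return np.array([s.phosphate_level for s in self.samples], dtype=float)

    def subset(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise InputError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[genes].copy(), list(self.samples))


@dataclass
class AnnotationTable:
    """Gene -> EC number(s) and pathway membership mapping.

    A gene may carry several EC numbers (it contributes fully to each
    enzyme) and belong to several pathways; an enzyme (EC number) is
    typically encoded by more than one gene copy.
    """

    ec_numbers: dict[str, tuple[str, ...]]
    pathways: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.ec_numbers) != set(self.pathways):
            raise FormatError("annotation EC and pathway maps cover different genes")

    @property
    def genes(self) -> list[str]:
        return list(self.ec_numbers)

    def ec_to_genes(self) -> dict[str, tuple[str, ...]]:
        """Invert the gene->EC map: EC number -> encoding gene copies."""
        out: dict[str, list[str]] = {}
        for gene, ecs in self.ec_numbers.items():
            for ec in ecs:
                out.setdefault(ec, []).append(gene)
        return {ec: tuple(genes) for ec, genes in out.items()}

    def pathway_to_genes(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for gene, pws in self.pathways.items():
            for pw in pws:
                out.setdefault(pw, []).append(gene)
        return {pw: tuple(genes) for pw, genes in out.items()}


@dataclass
class ContrastResult:
    """Per-gene two-group comparison for one condition pair (B over A)."""

    gene_id: str
    mean_a: float
    mean_b: float
    log2fc: float
    p_value: float
    fdr: float
    direction: str  # up / down / flat

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise InputError(f"p_value out of [0,1] for gene {self.gene_id!r}")
        if not (0.0 <= self.fdr <= 1.0):
            raise InputError(f"fdr out of [0,1] for gene {self.gene_id!r}")
        if self.direction not in ("up", "down", "flat"):
            raise InputError(f"bad direction {self.direction!r}")


def default_design(n_replicates: int = 3) -> list[SampleDesign]:
    """Standard PR/PD/PDR triplicate design with 1/0/1 phosphate levels."""
    return [
        SampleDesign(f"{cond}_{r}", cond, r)
        for cond in CONDITIONS
        for r in range(1, n_replicates + 1)
    ]
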