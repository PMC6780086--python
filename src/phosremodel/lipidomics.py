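"""Lipid species parsing, per-cell normalization and remodeling analysis.

The lipidome covers 15 classes: the membrane phospholipids (PA, PC, PE,
PG, PI and the lyso forms LPC, LPE, LPG), the phosphorus-free thylakoid
lipids (MGDG, DGDG galactolipids and the sulfolipid SQDG), the
phosphorus-free betaine lipid DGTS, free fatty acids (FFA) and the
neutral lipids DG and TG.  Species are written in shorthand such as
``PC(16:0/20:5)`` — class token, then acyl chains in sn order separated
by '/' when the sn positions are resolved ('_' when not).

Species levels are peak areas per million cells.  Classes are the exact
sum of member species; differential calls reuse the shared two-group
test at two reporting tiers (2-fold and 1.5-fold).  A species' pathway
of origin follows the sn2 rule: a C16:X chain at sn2 marks plastid
("prokaryotic") synthesis, a C18:X chain marks ER ("eukaryotic")
synthesis; anything else (e.g. 20:4, 20:5) is unassigned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import welch_log_test
from .errors import DesignError, FormatError, InputError
from .types import SampleDesign, validate_design

#: The 15 lipid classes and the number of acyl chains each carries.
CHAINS_PER_CLASS = {
    "DGDG": 2, "DGTS": 2, "FFA": 1, "LPC": 1, "LPE": 1, "LPG": 1,
    "MGDG": 2, "PA": 2, "PC": 2, "PE": 2, "PG": 2, "PI": 2,
    "SQDG": 2, "DG": 2, "TG": 3,
}

LIPID_CLASSES = tuple(sorted(CHAINS_PER_CLASS))

PHOSPHOLIPID_CLASSES = ("LPC", "LPE", "LPG", "PA", "PC", "PE", "PG", "PI")
THYLAKOID_CLASSES = ("DGDG", "MGDG", "SQDG")

_CHAIN_RE = re.compile(r"^(\d+):(\d+)(n-\d+)?$")
_NAME_RE = re.compile(r"^([A-Za-z]+)\(([^()]*)\)$")


@dataclass(frozen=True)
class AcylChain:
    carbons: int
    double_bonds: int
    omega_tag: str | None = None

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise FormatError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if not 0 <= self.double_bonds < self.carbons:
            raise FormatError(
                f"double bonds must be in [0, carbons) for {self.carbons}:{self.double_bonds}"
            )

    def __str__(self) -> str:
        tag = self.omega_tag or ""
        return f"{self.carbons}:{self.double_bonds}{tag}"


@dataclass
class LipidSpecies:
    """One lipid species, optionally carrying per-sample levels."""

    class_token: str
    chains: tuple[AcylChain, ...]
    sn_resolved: bool
    levels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.class_token not in CHAINS_PER_CLASS:
            raise FormatError(f"unknown lipid class {self.class_token!r}")
        expected = CHAINS_PER_CLASS[self.class_token]
        if len(self.chains) != expected:
            raise FormatError(
                f"{self.class_token} carries {expected} chain(s), got {len(self.chains)}"
            )

    @property
    def name(self) -> str:
        sep = "/" if self.sn_resolved else "_"
        return f"{self.class_token}({sep.join(str(c) for c in self.chains)})"

    @property
    def sn2_chain(self) -> AcylChain | None:
        """The sn2 chain: second of two, middle of three; None if single-chain."""
        if len(self.chains) < 2:
            return None
        return self.chains[1]


@dataclass
class LipidTable:
    """Parsed lipid species with levels aligned to a sample design."""

    species: list[LipidSpecies]
    samples: list[SampleDesign]
    cell_counts: np.ndarray | None = None  # cells per sample, if known

    def __post_init__(self) -> None:
        validate_design(self.samples)
        n = len(self.samples)
        names = set()
        for sp in self.species:
            if sp.levels is None or len(sp.levels) != n:
                raise FormatError(f"species {sp.name} levels do not match design")
            if sp.name in names:
                raise FormatError(f"duplicate species {sp.name}")
            names.add(sp.name)

    def levels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [sp.levels for sp in self.species],
            index=[sp.name for sp in self.species],
            columns=[s.sample_id for s in self.samples],
        )


@dataclass
class ClassContrastStats:
    """Two-tier differential call for one class (or stratum) and contrast."""

    contrast: str
    fold_change: float
    p_value: float
    tier_2x: str  # up / down / none
    tier_1p5x: str


@dataclass
class LipidClassSummary:
    class_token: str
    n_species: int
    levels: np.ndarray  # summed per sample
    stats: dict[str, ClassContrastStats] = field(default_factory=dict)


@dataclass
class OriginStratumSummary:
    class_token: str
    origin: str  # prokaryotic / eukaryotic / unassigned
    n_species: int
    levels: np.ndarray
    stats: dict[str, ClassContrastStats] = field(default_factory=dict)


@dataclass
class LipidTestConfig:
    alpha: float = 0.05
    pseudocount: float = 1.0
    contrasts: tuple[tuple[str, str], ...] = (("PR", "PD"), ("PD", "PDR"))


def parse_species(name: str) -> LipidSpecies:
    """Parse a shorthand species name such as ``PC(16:0/20:5)``.

    '/' separators mean the sn positions are resolved, '_' means they are
    not.  The class token fixes the expected chain count (lyso classes
    and FFA: one; TG: three; all other classes: two).
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise FormatError(f"unparseable species name {name!r}")
    token, inner = m.group(1), m.group(2)
    if token not in CHAINS_PER_CLASS:
        raise FormatError(f"unknown lipid class {token!r} in {name!r}")
    if "/" in inner and "_" in inner:
        raise FormatError(f"mixed sn separators in {name!r}")
    sep = "_" if "_" in inner else "/"
    parts = inner.split(sep) if inner else []
    chains = []
    for part in parts:
        cm = _CHAIN_RE.match(part.strip())
        if not cm:
            raise FormatError(f"unparseable acyl chain {part!r} in {name!r}")
        chains.append(
            AcylChain(int(cm.group(1)), int(cm.group(2)), cm.group(3))
        )
    return LipidSpecies(
        class_token=token, chains=tuple(chains), sn_resolved=(sep == "/")
    )


def normalize_per_cell(peak_areas, cell_counts) -> np.ndarray:
    """Peak area per million cells: ``area_i / (cells_i / 1e6)``."""
    areas = np.asarray(peak_areas, dtype=float)
    cells = np.asarray(cell_counts, dtype=float)
    if areas.shape[-1] != cells.shape[-1]:
        raise InputError("peak areas and cell counts differ in length")
    if (cells <= 0).any():
        raise InputError("cell counts must be positive")
    return areas / (cells / 1e6)


def classify_origin(species: LipidSpecies) -> str:
    """Pathway of origin from the sn2 acyl chain.

    C16:X at sn2 -> ``prokaryotic`` (plastid); C18:X -> ``eukaryotic``
    (ER); any other sn2 chain, or an unresolved species, ->
    ``unassigned``.  Raises for single-chain species (lyso classes and
    FFA), where no sn2 position exists.
    """
    if len(species.chains) < 2:
        raise InputError(
            f"origin classification not applicable to single-chain species {species.name}"
        )
    if not species.sn_resolved:
        return "unassigned"
    sn2 = species.sn2_chain
    if sn2.carbons == 16:
        return "prokaryotic"
    if sn2.carbons == 18:
        return "eukaryotic"
    return "unassigned"


def _origin_stratum(species: LipidSpecies) -> str:
    """Origin for stratified aggregation; single-chain species -> unassigned."""
    if len(species.chains) < 2:
        return "unassigned"
    return classify_origin(species)


def _two_tier_stats(
    levels: np.ndarray,
    samples: list[SampleDesign],
    config: LipidTestConfig,
) -> dict[str, ClassContrastStats]:
    out = {}
    pc = config.pseudocount
    for cond_a, cond_b in config.contrasts:
        ia = [i for i, s in enumerate(samples) if s.condition == cond_a]
        ib = [i for i, s in enumerate(samples) if s.condition == cond_b]
        if len(ia) < 2 or len(ib) < 2:
            raise DesignError(f"contrast {cond_b}/{cond_a} needs >= 2 replicates")
        va, vb = levels[ia], levels[ib]
        fold = float((vb.mean() + pc) / (va.mean() + pc))
        p = float(
            welch_log_test(np.log2(va + pc)[None, :], np.log2(vb + pc)[None, :])[0]
        )
        label = f"{cond_b}/{cond_a}"
        out[label] = ClassContrastStats(
            contrast=label,
            fold_change=fold,
            p_value=p,
            tier_2x=_tier(fold, p, 2.0, config.alpha),
            tier_1p5x=_tier(fold, p, 1.5, config.alpha),
        )
    return out


def _tier(fold: float, p: float, threshold: float, alpha: float) -> str:
    if p < alpha and fold > threshold:
        return "up"
    if p < alpha and fold < 1.0 / threshold:
        return "down"
    return "none"


def class_levels(
    table: LipidTable, config: LipidTestConfig | None = None
) -> list[LipidClassSummary]:
    """Aggregate species to classes and run the two-tier differential calls.

    The class level is the exact per-sample sum of its member species.
    """
    config = config or LipidTestConfig()
    groups: dict[str, list[LipidSpecies]] = {}
    for sp in table.species:
        groups.setdefault(sp.class_token, []).append(sp)
    out = []
    for token in sorted(groups):
        members = groups[token]
        levels = np.sum([sp.levels for sp in members], axis=0)
        out.append(
            LipidClassSummary(
                class_token=token,
                n_species=len(members),
                levels=levels,
                stats=_two_tier_stats(levels, table.samples, config),
            )
        )
    return out


def origin_stratified_levels(
    table: LipidTable, config: LipidTestConfig | None = None
) -> list[OriginStratumSummary]:
    """Class aggregation stratified by pathway of origin.

    Species with an unresolved or non-16/18 sn2 chain, and single-chain
    species, fall in the ``unassigned`` stratum so the strata partition
    every class exactly.
    """
    config = config or LipidTestConfig()
    groups: dict[tuple[str, str], list[LipidSpecies]] = {}
    for sp in table.species:
        groups.setdefault((sp.class_token, _origin_stratum(sp)), []).append(sp)
    out = []
    for token, origin in sorted(groups):
        members = groups[(token, origin)]
        levels = np.sum([sp.levels for sp in members], axis=0)
        out.append(
            OriginStratumSummary(
                class_token=token,
                origin=origin,
                n_species=len(members),
                levels=levels,
                stats=_two_tier_stats(levels, table.samples, config),
            )
        )
    return out


def epa_ara_species(table: LipidTable) -> list[LipidSpecies]:
    """PC/PE species carrying EPA (20:5) or ARA (20:4) at the sn2 position."""
    out = []
    for sp in table.species:
        if sp.class_token not in ("PC", "PE") or not sp.sn_resolved:
            continue
        sn2 = sp.sn2_chain
        if sn2 is not None and (sn2.carbons, sn2.double_bonds) in ((20, 5), (20, 4)):
            out.append(sp)
    return out


def fatty_acid_totals(table: LipidTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-acyl-chain level totals and their percent composition.

    Each species contributes its level once per occurrence of a chain
    among its sn positions (a chain present twice counts twice).  Returns
    ``(totals, percent)`` DataFrames indexed by chain shorthand with one
    column per sample; percentages are of the per-sample grand total.
    """
    sample_ids = [s.sample_id for s in table.samples]
    totals: dict[str, np.ndarray] = {}
    for sp in table.species:
        for chain in sp.chains:
            key = str(chain)
            totals[key] = totals.get(key, 0.0) + np.asarray(sp.levels, dtype=float)
    df = pd.DataFrame.from_dict(totals, orient="index", columns=sample_ids).sort_index()
    grand = df.sum(axis=0)
    percent = 100.0 * df / grand.replace(0.0, np.nan)
    return df, percent.fillna(0.0)


def load_lipid_table(
    path, design: list[SampleDesign], cell_counts_path=None
) -> LipidTable:
    """Read a species-level TSV (species_name + one area column per sample).

    When ``cell_counts_path`` (sample_id, cells columns) is given, areas
    are converted to per-million-cell levels; otherwise the columns are
    taken as already normalized.  Species that are zero in every sample
    are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species_name": str})
    if "species_name" not in df.columns:
        raise FormatError("lipid table must have a species_name column")
    design_ids = [s.sample_id for s in design]
    missing = [i for i in design_ids if i not in df.columns]
    if missing:
        raise DesignError(f"lipid table lacks sample columns {missing}")
    cells = None
    if cell_counts_path is not None:
        cdf = pd.read_csv(cell_counts_path, sep="\t", dtype={"sample_id": str})
        if not {"sample_id", "cells"}.issubset(cdf.columns):
            raise FormatError("cell count table must have sample_id and cells columns")
        lookup = dict(zip(cdf["sample_id"], cdf["cells"].astype(float)))
        absent = [i for i in design_ids if i not in lookup]
        if absent:
            raise DesignError(f"cell count table lacks samples {absent}")
        cells = np.array([lookup[i] for i in design_ids])
    species = []
    for _, row in df.iterrows():
        sp = parse_species(row["species_name"])
        areas = row[design_ids].to_numpy(dtype=float)
        if (areas < 0).any():
            raise FormatError(f"negative level for species {sp.name}")
        if (areas == 0).all():
            continue
        sp.levels = normalize_per_cell(areas, cells) if cells is not None else areas
        species.append(sp)
    return LipidTable(species=species, samples=list(design), cell_counts=cells)


def write_lipid_table(table: LipidTable, path) -> None:
    df = table.levels_frame()
    df.index.name = "species_name"
    df.to_csv(path, sep="\t", float_format="%.9g")


def write_lipid_areas(table: LipidTable, path) -> None:
    """Write raw peak areas (levels times cells per million) per species.

    The inverse of :func:`normalize_per_cell`; requires cell counts.
    Reading the result back with the cell-count companion table restores
    the per-million-cell levels.
    """
    if table.cell_counts is None:
        raise InputError("lipid table carries no cell counts")
    df = table.levels_frame() * (np.asarray(table.cell_counts) / 1e6)
    df.index.name = "species_name"
    df.to_csv(path, sep="\t", float_format="%.9g")


def write_lipid_cells(table: LipidTable, path) -> None:
    """Write the per-sample cell counts companion table."""
    if table.cell_counts is None:
        raise InputError("lipid table carries no cell counts")
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in table.samples],
            "cells": table.cell_counts,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
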