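"""Synthetic transcriptome and lipidome generators with ground truth.

The generators emulate the statistical structure the analysis assumes —
not raw reads or spectra.  The transcriptome is a 7140-gene TPM matrix
over a PR/PD/PDR triplicate design with planted reciprocal responders
(genes moving up on depletion and back down on restoration, or the
mirror image), one-contrast-only responders, a multi-copy enzyme
structure in which most enzymes are encoded by two or more gene copies,
and a few pathways whose member enzymes all shift modestly in one
direction (known positives for the concordance test).  The lipidome is a
15-class, ~95-species table with planted phospholipid -> DGTS/TG
remodeling under depletion, fully restored after replenishment.

Replicate noise is lognormal with a fixed coefficient of variation: the
pipeline consumes normalized intensities (TPM, peak areas), not counts,
and triplicate scatter on such scales is well described multiplicatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .lipidomics import (
    CHAINS_PER_CLASS,
    LIPID_CLASSES,
    PHOSPHOLIPID_CLASSES,
    THYLAKOID_CLASSES,
    AcylChain,
    LipidSpecies,
    LipidTable,
    normalize_per_cell,
)
from .types import AnnotationTable, ExpressionMatrix, SampleDesign, default_design


def _default_copies() -> dict[int, float]:
    # ~23% single-copy enzymes, ~77% with two or more gene copies
    return {1: 0.23, 2: 0.40, 3: 0.25, 4: 0.12}


def _default_remodeling() -> dict[str, float | dict[str, float]]:
    folds: dict[str, float | dict[str, float]] = {c: 0.4 for c in PHOSPHOLIPID_CLASSES}
    folds.update({c: 0.6 for c in THYLAKOID_CLASSES})
    folds.update({"DGTS": 3.0, "TG": 8.0, "DG": 1.0, "FFA": 1.0})
    return folds


def _default_sn2_pool() -> dict[str, float]:
    return {
        "16:0": 0.25, "16:1": 0.25, "18:1": 0.15, "18:2": 0.10,
        "20:4": 0.10, "20:5n-3": 0.15,
    }


def _default_sn1_pool() -> dict[str, float]:
    return {"14:0": 0.15, "16:0": 0.35, "16:1": 0.25, "18:1": 0.15, "18:2": 0.10}


@dataclass
class TranscriptomeSimConfig:
    """Study conditions for the synthetic transcriptome.

    Defaults mirror the analysed dataset: 7140 genes measured in
    triplicate under PR/PD/PDR, ~4.8% of genes responding inversely to
    phosphate (up on depletion) and ~3.5% positively, a 4-fold planted
    effect (``effect_log2fc = 2``), 20% replicate CV, and a copy-number
    distribution in which most enzymes have two or more gene copies.
    """

    n_genes: int = 7140
    n_replicates: int = 3
    frac_inverse_responders: float = 0.048  # ~342/7140
    frac_positive_responders: float = 0.035  # ~247/7140
    frac_oneway_de: float = 0.04
    effect_log2fc: float = 2.0
    noise_cv: float = 0.2
    n_pathways: int = 40
    genes_per_pathway: tuple[int, int] = (8, 40)
    copies_per_ec: dict[int, float] = field(default_factory=_default_copies)
    frac_ec_genes: float = 0.6
    n_concordant_pathways: int = 4
    concordant_fold: float = 1.4
    baseline_log10_mean: float = 1.5
    baseline_log10_sd: float = 0.55  # ~4 decades of expression across the gene set
    seed: int = 0

    def validate(self) -> None:
        total = (
            self.frac_inverse_responders
            + self.frac_positive_responders
            + self.frac_oneway_de
        )
        if total > 1:
            raise ConfigError(f"responder fractions sum to {total} > 1")
        for name in ("n_genes", "n_replicates", "n_pathways"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.effect_log2fc < 0 or self.noise_cv <= 0:
            raise ConfigError("effect_log2fc must be >= 0 and noise_cv > 0")
        if abs(sum(self.copies_per_ec.values()) - 1.0) > 1e-9:
            raise ConfigError("copies_per_ec probabilities must sum to 1")
        if self.n_concordant_pathways > self.n_pathways:
            raise ConfigError("n_concordant_pathways exceeds n_pathways")


@dataclass
class LipidomeSimConfig:
    """Study conditions for the synthetic lipidome.

    Fifteen classes with ~95 species in total; under depletion the
    phospholipid classes fall to 0.4x, the thylakoid lipids to 0.6x,
    DGTS rises 3x and TG 8x, and every class returns to its replete
    level after restoration.  A ``remodeling_map`` value may be a single
    fold or a per-origin dict (``prokaryotic`` / ``eukaryotic`` /
    ``unassigned``) to plant origin-dependent remodeling.
    """

    classes: tuple[str, ...] = LIPID_CLASSES
    species_per_class: tuple[int, int] = (4, 9)
    remodeling_map: dict[str, float | dict[str, float]] = field(
        default_factory=_default_remodeling
    )
    sn1_chain_pool: dict[str, float] = field(default_factory=_default_sn1_pool)
    sn2_chain_pool: dict[str, float] = field(default_factory=_default_sn2_pool)
    noise_cv: float = 0.2
    n_replicates: int = 3
    cells_per_sample: tuple[float, float] = (1e6, 5e6)
    class_log10_mean: float = 4.0
    class_log10_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        unknown = [c for c in self.remodeling_map if c not in CHAINS_PER_CLASS]
        if unknown:
            raise ConfigError(f"unknown class token(s) in remodeling_map: {unknown}")
        missing = [c for c in self.classes if c not in self.remodeling_map]
        if missing:
            raise ConfigError(f"remodeling_map missing class(es): {missing}")
        for cls, fold in self.remodeling_map.items():
            values = fold.values() if isinstance(fold, dict) else [fold]
            if any(f <= 0 for f in values):
                raise ConfigError(f"non-positive fold for class {cls}")
        if self.noise_cv <= 0 or self.n_replicates < 2:
            raise ConfigError("noise_cv must be > 0 and n_replicates >= 2")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset.

    ``gene_labels`` maps every gene to one of ``inverse`` / ``positive``
    / ``oneway`` / ``null``; ``concordant_pathways`` records the planted
    shift direction of concordance-positive pathways; ``class_folds`` and
    ``species_origins`` describe the planted lipidome.
    """

    gene_labels: dict[str, str] = field(default_factory=dict)
    concordant_pathways: dict[str, str] = field(default_factory=dict)
    class_folds: dict[str, float | dict[str, float]] = field(default_factory=dict)
    species_origins: dict[str, str] = field(default_factory=dict)


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    # unit-mean multiplicative noise with the requested CV
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def generate_transcriptome(
    config: TranscriptomeSimConfig | None = None,
) -> tuple[ExpressionMatrix, AnnotationTable, GroundTruth]:
    """Simulate the TPM matrix, annotation and ground truth."""
    config = config or TranscriptomeSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(4, len(str(n)))
    genes = [f"g{i + 1:0{width}d}" for i in range(n)]
    design = default_design(config.n_replicates)

    baseline = 10.0 ** rng.normal(
        config.baseline_log10_mean, config.baseline_log10_sd, size=n
    )

    # --- multi-copy enzyme structure -------------------------------------
    n_ec_genes = int(round(config.frac_ec_genes * n))
    copy_values = np.array(sorted(config.copies_per_ec))
    copy_probs = np.array([config.copies_per_ec[c] for c in copy_values], dtype=float)
    ec_of_gene: dict[str, tuple[str, ...]] = {g: () for g in genes}
    ec_members: dict[str, list[int]] = {}
    shuffled = rng.permutation(n)
    pos = 0
    ec_idx = 0
    while pos < n_ec_genes:
        copies = int(rng.choice(copy_values, p=copy_probs))
        copies = min(copies, n_ec_genes - pos)
        ec_idx += 1
        ec = f"{ec_idx % 6 + 1}.{ec_idx % 9 + 1}.{ec_idx % 25 + 1}.{ec_idx}"
        members = [int(i) for i in shuffled[pos : pos + copies]]
        ec_members[ec] = members
        for gi in members:
            ec_of_gene[genes[gi]] = (ec,)
        pos += copies
        # enzyme copies share one planted enzyme level, split at random
        enzyme_level = 10.0 ** rng.normal(
            config.baseline_log10_mean + 0.3, config.baseline_log10_sd
        )
        split = rng.dirichlet(np.ones(copies))
        baseline[members] = enzyme_level * split

    # --- pathways over enzymes -------------------------------------------
    ec_list = sorted(ec_members)
    pathway_members: dict[str, list[str]] = {}
    concordant: dict[str, str] = {}
    lo, hi = config.genes_per_pathway
    pw_width = len(str(config.n_pathways))
    for p in range(config.n_pathways):
        pw = f"pw{p + 1:0{pw_width}d}"
        target = int(rng.integers(lo, hi + 1))
        order = rng.permutation(len(ec_list))
        chosen: list[str] = []
        count = 0
        for j in order:
            ec = ec_list[j]
            chosen.append(ec)
            count += len(ec_members[ec])
            if count >= target:
                break
        pathway_members[pw] = chosen
        if p < config.n_concordant_pathways:
            concordant[pw] = "down" if p % 2 == 0 else "up"

    pathways_of_gene: dict[str, list[str]] = {g: [] for g in genes}
    for pw, ecs in pathway_members.items():
        for ec in ecs:
            for gi in ec_members[ec]:
                pathways_of_gene[genes[gi]].append(pw)

    # --- planted responder labels ----------------------------------------
    concordant_gene_idx: set[int] = set()
    for pw in concordant:
        for ec in pathway_members[pw]:
            concordant_gene_idx.update(ec_members[ec])
    eligible = np.array([i for i in range(n) if i not in concordant_gene_idx])
    n_inv = int(round(config.frac_inverse_responders * n))
    n_pos = int(round(config.frac_positive_responders * n))
    n_one = int(round(config.frac_oneway_de * n))
    picked = rng.choice(eligible, size=n_inv + n_pos + n_one, replace=False)
    inv_idx = picked[:n_inv]
    pos_idx = picked[n_inv : n_inv + n_pos]
    one_idx = picked[n_inv + n_pos :]
    labels = {g: "null" for g in genes}
    for i in inv_idx:
        labels[genes[i]] = "inverse"
    for i in pos_idx:
        labels[genes[i]] = "positive"
    for i in one_idx:
        labels[genes[i]] = "oneway"

    # --- condition means ---------------------------------------------------
    eff = 2.0 ** config.effect_log2fc
    mult = np.ones((n, 3))  # columns PR, PD, PDR
    mult[inv_idx, 1] = eff  # up on depletion, back down on restoration
    mult[pos_idx, 1] = 1.0 / eff
    # one-way genes: half persist after restoration (DE only in PD/PR),
    # half move only on restoration (DE only in PDR/PD); direction random
    signs = rng.choice([1.0, -1.0], size=len(one_idx))
    for j, i in enumerate(one_idx):
        f = eff ** signs[j]
        if j % 2 == 0:
            mult[i, 1] = f
            mult[i, 2] = f
        else:
            mult[i, 2] = f
    for pw, direction in concordant.items():
        f = config.concordant_fold if direction == "up" else 1.0 / config.concordant_fold
        for ec in pathway_members[pw]:
            for gi in ec_members[ec]:
                mult[gi, 1] = f

    cond_index = {"PR": 0, "PD": 1, "PDR": 2}
    means = baseline[:, None] * mult[:, [cond_index[s.condition] for s in design]]
    values = means * _lognormal_noise(rng, config.noise_cv, means.shape)
    values *= 1e6 / values.sum(axis=0, keepdims=True)  # TPM contract

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=[s.sample_id for s in design]),
        design,
    )
    annotation = AnnotationTable(
        ec_numbers=ec_of_gene,
        pathways={g: tuple(sorted(pws)) for g, pws in pathways_of_gene.items()},
    )
    truth = GroundTruth(gene_labels=labels, concordant_pathways=concordant)
    return matrix, annotation, truth


def _resolve_fold(fold: float | dict[str, float], origin: str) -> float:
    if isinstance(fold, dict):
        return float(fold.get(origin, 1.0))
    return float(fold)


def generate_lipidome(
    config: LipidomeSimConfig | None = None,
) -> tuple[LipidTable, GroundTruth]:
    """Simulate the species-level lipid table and ground truth.

    Per-cell species levels are drawn, multiplied into peak areas using
    per-sample cell counts, then normalized back to per-million-cell
    levels through :func:`normalize_per_cell`, so the normalization path
    is exercised end to end.  PC and PE are guaranteed one EPA-sn2
    species each (and PE one ARA-sn2 species) so the long-chain PUFA
    tracking always has material.
    """
    config = config or LipidomeSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = default_design(config.n_replicates)
    n_samples = len(design)

    sn1 = _pool(config.sn1_chain_pool)
    sn2 = _pool(config.sn2_chain_pool)

    species: list[LipidSpecies] = []
    truth = GroundTruth(class_folds=dict(config.remodeling_map))
    lo, hi = config.species_per_class
    forced = {"PC": ["20:5n-3"], "PE": ["20:5n-3", "20:4"]}
    for cls in config.classes:
        n_species = int(rng.integers(lo, hi + 1))
        n_chains = CHAINS_PER_CLASS[cls]
        names_seen: set[str] = set()
        forced_sn2 = list(forced.get(cls, []))
        made = 0
        attempts = 0
        while made < n_species and attempts < 500:
            attempts += 1
            if n_chains == 1:
                chains = (_draw(rng, sn1),)
            elif n_chains == 2:
                sn2_chain = (
                    _parse_chain(forced_sn2.pop(0)) if forced_sn2 else _draw(rng, sn2)
                )
                chains = (_draw(rng, sn1), sn2_chain)
            else:
                chains = (_draw(rng, sn1), _draw(rng, sn2), _draw(rng, sn1))
            sp = LipidSpecies(class_token=cls, chains=chains, sn_resolved=True)
            if sp.name in names_seen:
                continue
            names_seen.add(sp.name)
            species.append(sp)
            made += 1

    cells = rng.uniform(*config.cells_per_sample, size=n_samples)
    cond_index = {"PR": 0, "PD": 1, "PDR": 2}
    class_mean = {
        cls: 10.0 ** rng.normal(config.class_log10_mean, config.class_log10_sd)
        for cls in config.classes
    }
    by_class: dict[str, list[LipidSpecies]] = {}
    for sp in species:
        by_class.setdefault(sp.class_token, []).append(sp)
    for cls, members in by_class.items():
        weights = rng.dirichlet(np.ones(len(members)))
        for sp, w in zip(members, weights):
            origin = "unassigned" if len(sp.chains) < 2 else _origin(sp)
            truth.species_origins[sp.name] = origin
            pd_fold = _resolve_fold(config.remodeling_map[cls], origin)
            cond_folds = np.array([1.0, pd_fold, 1.0])  # PR, PD, PDR (restored)
            per_cell = class_mean[cls] * w
            level_mean = per_cell * cond_folds[
                [cond_index[s.condition] for s in design]
            ]
            level = level_mean * _lognormal_noise(rng, config.noise_cv, n_samples)
            areas = level * (cells / 1e6)
            sp.levels = normalize_per_cell(areas, cells)

    table = LipidTable(species=species, samples=design, cell_counts=cells)
    return table, truth


def _pool(weights: dict[str, float]) -> tuple[list[AcylChain], np.ndarray]:
    chains = [_parse_chain(c) for c in weights]
    w = np.array(list(weights.values()), dtype=float)
    return chains, w / w.sum()


def _draw(rng: np.random.Generator, pool: tuple[list[AcylChain], np.ndarray]) -> AcylChain:
    chains, probs = pool
    return chains[int(rng.choice(len(chains), p=probs))]


def _parse_chain(text: str) -> AcylChain:
    from .lipidomics import _CHAIN_RE

    m = _CHAIN_RE.match(text)
    if not m:
        raise ConfigError(f"bad acyl chain {text!r} in chain pool")
    return AcylChain(int(m.group(1)), int(m.group(2)), m.group(3))


def _origin(sp: LipidSpecies) -> str:
    from .lipidomics import classify_origin

    return classify_origin(sp)
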