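"""Enzyme-level aggregation and pathway direction-concordance testing.

Enzymes in this organism are frequently encoded by two or more gene
copies, so the transcriptional level of an enzyme (EC number) is the sum
of its member gene TPMs per sample.  Each enzyme's change between two
conditions is placed in one of two tiers:

* *significant* — fold change beyond 1.5 (either way) with p < 0.05 from
  the shared two-group test on the summed, logged levels;
* *moderate*   — fold change beyond a 10% band but not significant;
* otherwise *unchanged*.

Whether a pathway's enzymes move coherently is then asked with a
one-sided exact sign test: among the ``n`` direction-altered enzymes
(moderate plus significant), the probability that at least the observed
majority share one direction under a fair coin,
``p = sum_{i=n_maj}^{n} C(n, i) (1/2)^n``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .de import welch_log_test
from .errors import DesignError, InputError
from .types import AnnotationTable, ExpressionMatrix, SampleDesign


@dataclass
class ConcordanceConfig:
    """Tier thresholds for enzyme-level change classification.

    significant_fold
        Fold beyond which a change with p < ``alpha`` is *significant*
        (default 1.5).
    moderate_band
        Fractional band for *moderate* alteration (default 0.10: beyond
        10%).  With ``band_mode='ratio'`` the band is symmetric in ratio
        space (up if fold > 1.1, down if fold < 1/1.1); with
        ``band_mode='fraction'`` down means fold < 0.9.
    """

    significant_fold: float = 1.5
    moderate_band: float = 0.10
    alpha: float = 0.05
    pseudocount: float = 1.0
    band_mode: str = "ratio"

    def __post_init__(self) -> None:
        if not self.significant_fold > 1:
            raise InputError("significant_fold must be > 1")
        if not 0 < self.moderate_band < 1:
            raise InputError("moderate_band must be in (0, 1)")
        if self.band_mode not in ("ratio", "fraction"):
            raise InputError("band_mode must be 'ratio' or 'fraction'")


@dataclass
class EnzymeProfile:
    """Summed expression of all gene copies sharing one EC number."""

    ec_number: str
    copy_gene_ids: tuple[str, ...]
    values: np.ndarray  # summed TPM per sample, design order
    samples: list[SampleDesign]

    @property
    def copy_number(self) -> int:
        return len(self.copy_gene_ids)


@dataclass
class EnzymeTier:
    """Change tier of one enzyme for one contrast (B over A)."""

    ec_number: str
    contrast: str  # e.g. "PD/PR"
    fold_change: float
    p_value: float
    tier: str  # significant_up/down, moderate_up/down, unchanged

    @property
    def direction(self) -> str | None:
        if self.tier.endswith("_up"):
            return "up"
        if self.tier.endswith("_down"):
            return "down"
        return None


@dataclass
class ConcordanceResult:
    """One-sided exact sign test for one pathway and contrast."""

    pathway_id: str
    contrast: str
    n_altered: int
    n_up: int
    n_down: int
    n_majority: int
    majority_direction: str
    p_value: float
    tied: bool = False


def aggregate_enzymes(
    matrix: ExpressionMatrix, annotation: AnnotationTable
) -> list[EnzymeProfile]:
    """Sum gene copies per EC number, per sample.

    Genes carrying several EC numbers contribute fully to each; genes
    without an EC number are ignored.  ECs with no gene present in the
    matrix are dropped.
    """
    present = set(matrix.genes)
    profiles = []
    for ec, genes in sorted(annotation.ec_to_genes().items()):
        members = tuple(g for g in genes if g in present)
        if not members:
            continue
        values = matrix.data.loc[list(members)].to_numpy(dtype=float).sum(axis=0)
        profiles.append(
            EnzymeProfile(
                ec_number=ec,
                copy_gene_ids=members,
                values=values,
                samples=list(matrix.samples),
            )
        )
    return profiles


def classify_enzyme_change(
    profile: EnzymeProfile,
    cond_a: str,
    cond_b: str,
    config: ConcordanceConfig | None = None,
) -> EnzymeTier:
    """Assign the two-tier change class for one enzyme and contrast."""
    config = config or ConcordanceConfig()
    va = _condition_values(profile, cond_a)
    vb = _condition_values(profile, cond_b)
    pc = config.pseudocount
    fold = float((vb.mean() + pc) / (va.mean() + pc))
    p = float(welch_log_test(np.log2(va + pc)[None, :], np.log2(vb + pc)[None, :])[0])
    sig = config.significant_fold
    up_band = 1.0 + config.moderate_band
    down_band = 1.0 / up_band if config.band_mode == "ratio" else 1.0 - config.moderate_band
    if p < config.alpha and fold > sig:
        tier = "significant_up"
    elif p < config.alpha and fold < 1.0 / sig:
        tier = "significant_down"
    elif fold > up_band:
        tier = "moderate_up"
    elif fold < down_band:
        tier = "moderate_down"
    else:
        tier = "unchanged"
    return EnzymeTier(
        ec_number=profile.ec_number,
        contrast=f"{cond_b}/{cond_a}",
        fold_change=fold,
        p_value=p,
        tier=tier,
    )


def concordance_test(
    tiers: list[EnzymeTier], pathway_id: str = ""
) -> ConcordanceResult:
    """Exact one-sided sign test on the direction-altered enzymes.

    ``tiers`` are the enzymes of one pathway for one contrast; unchanged
    enzymes are excluded, significant ones count together with moderate
    ones.  On a tie the result is reported for the up direction with
    ``tied`` set.
    """
    if not tiers:
        raise InputError("empty tier list")
    contrasts = {t.contrast for t in tiers}
    if len(contrasts) > 1:
        raise InputError(f"tiers mix contrasts: {sorted(contrasts)}")
    altered = [t for t in tiers if t.direction is not None]
    if not altered:
        raise InputError("no direction-altered enzymes to test")
    n_up = sum(1 for t in altered if t.direction == "up")
    n_down = len(altered) - n_up
    tied = n_up == n_down
    majority = "up" if n_up >= n_down else "down"
    n_majority = max(n_up, n_down)
    n = len(altered)
    p = float(stats.binom.sf(n_majority - 1, n, 0.5))
    return ConcordanceResult(
        pathway_id=pathway_id,
        contrast=altered[0].contrast,
        n_altered=n,
        n_up=n_up,
        n_down=n_down,
        n_majority=n_majority,
        majority_direction=majority,
        p_value=p,
        tied=tied,
    )


def pathway_concordance(
    matrix: ExpressionMatrix,
    annotation: AnnotationTable,
    contrasts: tuple[tuple[str, str], ...] = (("PR", "PD"), ("PD", "PDR")),
    config: ConcordanceConfig | None = None,
) -> tuple[list[EnzymeTier], list[ConcordanceResult]]:
    """Tier every enzyme and sign-test every pathway for each contrast.

    Pathways with no direction-altered enzyme in a contrast are skipped
    for that contrast.
    """
    config = config or ConcordanceConfig()
    profiles = aggregate_enzymes(matrix, annotation)
    by_ec = {p.ec_number: p for p in profiles}
    # pathway -> member ECs, via the ECs of its member genes
    pathway_ecs: dict[str, set[str]] = {}
    for gene, pws in annotation.pathways.items():
        for pw in pws:
            pathway_ecs.setdefault(pw, set()).update(annotation.ec_numbers[gene])
    all_tiers: list[EnzymeTier] = []
    tier_lookup: dict[tuple[str, str], EnzymeTier] = {}
    for cond_a, cond_b in contrasts:
        for profile in profiles:
            tier = classify_enzyme_change(profile, cond_a, cond_b, config)
            all_tiers.append(tier)
            tier_lookup[(profile.ec_number, tier.contrast)] = tier
    results = []
    for pw, ecs in sorted(pathway_ecs.items()):
        member_ecs = sorted(ec for ec in ecs if ec in by_ec)
        if not member_ecs:
            continue
        for cond_a, cond_b in contrasts:
            label = f"{cond_b}/{cond_a}"
            tiers = [tier_lookup[(ec, label)] for ec in member_ecs]
            if not any(t.direction for t in tiers):
                continue
            results.append(concordance_test(tiers, pathway_id=pw))
    return all_tiers, results


def _condition_values(profile: EnzymeProfile, condition: str) -> np.ndarray:
    idx = [i for i, s in enumerate(profile.samples) if s.condition == condition]
    if len(idx) < 2:
        raise DesignError(f"condition {condition!r} needs >= 2 replicates")
    return profile.values[idx]
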