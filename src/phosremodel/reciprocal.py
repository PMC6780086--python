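"""Phosphate-specific responsive genes from the reciprocal design.

Genes differentially expressed in *both* opposed contrasts — depletion
(PD over PR) and restoration (PDR over PD) — respond to both the removal
and the return of phosphate and are therefore taken as phosphate-specific
responders, as opposed to generic stress responders that move in only one
contrast.  The overlap of the two DE sets is scored with a hypergeometric
upper tail; common genes are classified by the direction pair of their
two fold changes and grouped by k-means clustering of their standardized
nine-sample profiles, with each group labelled by the sign of the
correlation between its mean profile and the medium phosphate level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .enrichment import hypergeom_logtail, hypergeom_tail
from .errors import InputError
from .types import ContrastResult, ExpressionMatrix


@dataclass
class CommonDEResult:
    """Overlap of the depletion and restoration DE gene sets."""

    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap_size: int
    overlap_p: float
    overlap_log10_p: float
    common_genes: list[tuple[str, str, str]] = field(default_factory=list)
    # (gene_id, direction in contrast A, direction in contrast B)


@dataclass
class ResponseGroup:
    """One k-means group of common DE genes."""

    group_id: int
    member_genes: tuple[str, ...]
    mean_profile: np.ndarray
    phosphate_correlation: float
    correlation_label: str  # inverse / positive


def common_de(
    de_a: dict[str, str], de_b: dict[str, str], universe_size: int
) -> CommonDEResult:
    """Intersect two DE gene sets and score the overlap.

    ``de_a`` / ``de_b`` map gene id to call direction ('up'/'down').  The
    overlap p-value is the hypergeometric upper tail P(X >= overlap) for a
    population of ``universe_size`` genes with ``|de_a|`` successes and
    ``|de_b|`` draws.
    """
    if universe_size <= 0:
        raise InputError("universe_size must be positive")
    if len(de_a) > universe_size or len(de_b) > universe_size:
        raise InputError("a DE set exceeds the universe")
    common = sorted(set(de_a) & set(de_b))
    if common:
        logp = hypergeom_logtail(len(common), len(de_b), len(de_a), universe_size)
        p = float(min(1.0, np.exp(logp)))
        log10p = logp / np.log(10.0)
    else:
        p, log10p = 1.0, 0.0
    return CommonDEResult(
        set_a_size=len(de_a),
        set_b_size=len(de_b),
        universe_size=universe_size,
        overlap_size=len(common),
        overlap_p=p,
        overlap_log10_p=float(log10p),
        common_genes=[(g, de_a[g], de_b[g]) for g in common],
    )


def classify_direction(
    gene: str,
    contrast_pd_pr: list[ContrastResult] | dict[str, ContrastResult],
    contrast_pdr_pd: list[ContrastResult] | dict[str, ContrastResult],
) -> str:
    """Per-gene response class from the signs of the two fold changes.

    ``inverse``  — up on depletion, down on restoration (tracks phosphate
    loss); ``positive`` — down on depletion, up on restoration;
    ``discordant`` — anything else (including a zero fold change).
    """
    a = _index(contrast_pd_pr)
    b = _index(contrast_pdr_pd)
    if gene not in a or gene not in b:
        raise InputError(f"gene {gene!r} absent from a contrast")
    fa, fb = a[gene].log2fc, b[gene].log2fc
    if fa > 0 and fb < 0:
        return "inverse"
    if fa < 0 and fb > 0:
        return "positive"
    return "discordant"


def kmeans_groups(
    matrix: ExpressionMatrix,
    k: int = 10,
    seed: int = 0,
    n_restarts: int = 50,
) -> list[ResponseGroup]:
    """Cluster standardized gene profiles into ``k`` direction groups.

    Each gene's profile over the nine samples is z-scored (mean 0,
    variance 1), then Lloyd's algorithm with k-means++ initialization is
    run ``n_restarts`` times keeping the lowest within-cluster sum of
    squares.  Groups are labelled ``inverse`` or ``positive`` by the sign
    of the Pearson correlation between the group mean profile and the
    per-sample phosphate level, and renumbered so inverse groups come
    first (most negative correlation first).
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if matrix.n_genes < k:
        raise InputError(f"k={k} exceeds number of genes ({matrix.n_genes})")
    values = matrix.data.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    if (sd == 0).any():
        gene = matrix.genes[int(np.argmax(sd == 0))]
        raise InputError(f"gene {gene!r} has a constant profile; cannot standardize")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(z)
    phosphate = matrix.phosphate_vector()
    groups = []
    for label in range(k):
        members = [g for g, lab in zip(matrix.genes, km.labels_) if lab == label]
        profile = z[km.labels_ == label].mean(axis=0)
        corr = _pearson(profile, phosphate)
        groups.append(
            ResponseGroup(
                group_id=0,
                member_genes=tuple(members),
                mean_profile=profile,
                phosphate_correlation=corr,
                correlation_label="inverse" if corr < 0 else "positive",
            )
        )
    groups.sort(key=lambda g: (g.correlation_label != "inverse", g.phosphate_correlation))
    for i, g in enumerate(groups, start=1):
        g.group_id = i
    return groups


def _index(results) -> dict[str, ContrastResult]:
    if isinstance(results, dict):
        return results
    return {r.gene_id: r for r in results}


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])
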