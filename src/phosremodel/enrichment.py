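"""Pathway enrichment of a gene subset against the whole transcriptome.

For a pathway with ``K`` annotated genes in a universe of ``N`` genes, of
which ``k`` fall in a subset of size ``m``:

* fold enrichment ``FE = (k/m) / (K/N)``;
* significance is the hypergeometric upper tail ``P(X >= k)``.

Enrichment calls use the raw p-value; Bonferroni-adjusted values over the
number of pathways tested are reported alongside but do not gate the
filter.  A binomial tail model (sampling with replacement, i.e. the
infinite-universe approximation of the hypergeometric) is available
because several legacy enrichment tools report it; the exact
hypergeometric tail is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import InputError
from .types import AnnotationTable


@dataclass
class EnrichmentResult:
    """Enrichment of one pathway in a gene subset."""

    pathway_id: str
    k: int  # pathway genes in the subset
    m: int  # subset size
    K: int  # pathway genes in the universe
    N: int  # universe size
    fold_enrichment: float
    p_value: float
    p_bonferroni: float
    passes_filter: bool


def _validate_margins(k: int, m: int, K: int, N: int) -> None:
    for name, v in (("k", k), ("m", m), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise InputError(f"{name} must be a non-negative integer, got {v!r}")
    if m == 0 or K == 0 or N == 0:
        raise InputError("m, K and N must be positive")
    if m > N or K > N:
        raise InputError("m and K cannot exceed N")
    if k > min(m, K):
        raise InputError(f"k={k} exceeds min(m={m}, K={K})")


def fold_enrichment(k: int, m: int, K: int, N: int) -> float:
    """Fold enrichment ``(k/m) / (K/N)`` of a pathway in a subset."""
    _validate_margins(k, m, K, N)
    return (k / m) / (K / N)


def hypergeom_logtail(k: int, m: int, K: int, N: int) -> float:
    """Natural log of the hypergeometric upper tail ``P(X >= k)``.

    Summed in log space so extreme overlaps (p far below the smallest
    positive float) remain quantifiable.
    """
    _validate_margins(k, m, K, N)
    if k == 0:
        return 0.0
    ks = np.arange(k, min(m, K) + 1)
    return float(logsumexp(stats.hypergeom.logpmf(ks, N, K, m)))


def hypergeom_tail(k: int, m: int, K: int, N: int) -> float:
    """Hypergeometric upper tail ``P(X >= k)`` for hypergeometric(N, K, m)."""
    return float(min(1.0, np.exp(hypergeom_logtail(k, m, K, N))))


def binom_tail(k: int, m: int, K: int, N: int) -> float:
    """Binomial upper tail ``P(X >= k)`` with X ~ Binomial(m, K/N).

    The with-replacement approximation of :func:`hypergeom_tail`; slightly
    conservative for small K/N, and the statistic reported by a number of
    older enrichment web services.
    """
    _validate_margins(k, m, K, N)
    if k == 0:
        return 1.0
    return float(min(1.0, stats.binom.sf(k - 1, m, K / N)))


def enrich(
    subset: set[str],
    annotation: AnnotationTable,
    universe: set[str],
    min_pathway_genes: int = 5,
    fe_threshold: float = 2.0,
    alpha: float = 0.05,
    min_count_on: str = "subset",
    tail_model: str = "hypergeom",
) -> list[EnrichmentResult]:
    """Test every annotated pathway for enrichment in ``subset``.

    Parameters
    ----------
    subset, universe :
        Gene sets with ``subset`` contained in ``universe``.  Unannotated
        genes still count toward the universe size ``N``.
    min_pathway_genes :
        Minimum gene count for a pathway to pass the filter; applied to
        the subset hits ``k`` by default, or to the universe count ``K``
        when ``min_count_on='universe'``.
    fe_threshold, alpha :
        A pathway passes the filter when ``FE > fe_threshold`` and the
        raw ``p < alpha`` and the count rule holds.
    tail_model :
        ``'hypergeom'`` (exact, default) or ``'binomial'``.

    Results are sorted by fold enrichment descending, then p ascending.
    """
    outside = subset - universe
    if outside:
        raise InputError(f"subset genes outside universe: {sorted(outside)[:5]}")
    if min_count_on not in ("subset", "universe"):
        raise InputError("min_count_on must be 'subset' or 'universe'")
    tail = {"hypergeom": hypergeom_tail, "binomial": binom_tail}.get(tail_model)
    if tail is None:
        raise InputError("tail_model must be 'hypergeom' or 'binomial'")
    m = len(subset)
    N = len(universe)
    if m == 0:
        raise InputError("subset is empty")
    pathway_genes = {
        pw: set(genes) & universe for pw, genes in annotation.pathway_to_genes().items()
    }
    pathway_genes = {pw: g for pw, g in pathway_genes.items() if g}
    n_tests = len(pathway_genes)
    results = []
    for pw, genes in sorted(pathway_genes.items()):
        K = len(genes)
        k = len(genes & subset)
        fe = fold_enrichment(k, m, K, N)
        p = tail(k, m, K, N)
        count = k if min_count_on == "subset" else K
        results.append(
            EnrichmentResult(
                pathway_id=pw,
                k=k,
                m=m,
                K=K,
                N=N,
                fold_enrichment=fe,
                p_value=p,
                p_bonferroni=min(1.0, p * n_tests),
                passes_filter=(fe > fe_threshold and p < alpha and count >= min_pathway_genes),
            )
        )
    results.sort(key=lambda r: (-r.fold_enrichment, r.p_value, r.pathway_id))
    return results
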