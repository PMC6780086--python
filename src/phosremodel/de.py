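"""Two-group differential expression on TPM.

The comparison contract is a Welch (unequal-variance) t-test on
log2(TPM + pseudocount), with the fold change computed on pseudocounted
replicate means and Benjamini-Hochberg control of the false discovery
rate across all genes of a contrast.  A gene is called differentially
expressed when |fold change| exceeds the threshold (strictly) and the
adjusted (or raw, if ``use_fdr`` is off) p-value is strictly below
``alpha``.  The same two-group contract is reused for summed enzyme
levels and lipid class levels.

Degenerate inputs: when both groups have zero variance the t statistic
is undefined; the contract then assigns p = 1 for equal means and p = 0
for unequal means, which keeps constant synthetic fixtures well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, InputError
from .types import ContrastResult, ExpressionMatrix


@dataclass
class DECallConfig:
    """Thresholds for differential-expression calls.

    fold_threshold
        Linear fold-change cutoff (default 2: a gene must change more
        than two-fold).
    alpha
        Significance cutoff on the (adjusted) p-value, default 0.05.
    use_fdr
        Gate calls on the BH-adjusted p-value (default) rather than the
        raw p-value.
    pseudocount
        Added to TPM before log transformation and to means before the
        ratio, guarding against log(0) and division by zero.
    """

    fold_threshold: float = 2.0
    alpha: float = 0.05
    use_fdr: bool = True
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise InputError("fold_threshold must be > 1")
        if not (0 < self.alpha < 1):
            raise InputError("alpha must be in (0, 1)")
        if self.pseudocount < 0:
            raise InputError("pseudocount must be non-negative")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_log_test(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch t-test p-values on already-logged values.

    ``a`` and ``b`` are 2-D (rows x replicates).  Rows where both groups
    have zero variance get p = 1 (equal means) or p = 0 (unequal means).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DesignError("each group needs >= 2 replicates")
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0
    return p


def contrast(
    matrix: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    config: DECallConfig | None = None,
) -> list[ContrastResult]:
    """Compare condition ``cond_b`` over ``cond_a`` for every gene.

    Returns one :class:`ContrastResult` per gene with
    ``log2fc = log2((mean_b + pc) / (mean_a + pc))``, the Welch p-value on
    log2(TPM + pc), the BH-adjusted p-value over all genes, and the call
    direction under ``config``.
    """
    config = config or DECallConfig()
    va = matrix.condition_values(cond_a)
    vb = matrix.condition_values(cond_b)
    if va.shape[1] < 2 or vb.shape[1] < 2:
        raise DesignError(
            f"contrast {cond_b}/{cond_a} needs >= 2 replicates per condition"
        )
    pc = config.pseudocount
    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)
    log2fc = np.log2((mean_b + pc) / (mean_a + pc))
    p = welch_log_test(np.log2(va + pc), np.log2(vb + pc))
    fdr = bh_adjust(p)
    crit = fdr if config.use_fdr else p
    thr = np.log2(config.fold_threshold)
    results = []
    for i, gene in enumerate(matrix.genes):
        if crit[i] < config.alpha and log2fc[i] > thr:
            direction = "up"
        elif crit[i] < config.alpha and log2fc[i] < -thr:
            direction = "down"
        else:
            direction = "flat"
        results.append(
            ContrastResult(
                gene_id=gene,
                mean_a=float(mean_a[i]),
                mean_b=float(mean_b[i]),
                log2fc=float(log2fc[i]),
                p_value=float(p[i]),
                fdr=float(fdr[i]),
                direction=direction,
            )
        )
    return results


def call_de(
    results: list[ContrastResult], config: DECallConfig | None = None
) -> dict[str, str]:
    """Genes passing the fold and significance cutoffs, tagged up/down.

    Inequalities are strict on both axes: ``|log2fc| > log2(fold)`` and
    ``(fdr or p) < alpha``.
    """
    config = config or DECallConfig()
    thr = np.log2(config.fold_threshold)
    out: dict[str, str] = {}
    for r in results:
        crit = r.fdr if config.use_fdr else r.p_value
        if crit < config.alpha and abs(r.log2fc) > thr:
            out[r.gene_id] = "up" if r.log2fc > 0 else "down"
    return out
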