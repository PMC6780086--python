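# Methods

`phosremodel` analyses a reciprocal phosphate perturbation experiment in
a marine microalga: triplicate cultures sampled phosphate-replete (PR),
after three days of phosphate depletion (PD), and three days after
restoring phosphate to depleted cultures (PDR). The package covers the
transcriptomic branch (differential expression on TPM, reciprocal
responder identification, pathway enrichment, enzyme-level concordance)
and the lipidomic branch (class aggregation, two-tier differential
abundance, pathway-of-origin stratification, acyl-chain composition),
plus a synthetic data generator that emulates the statistical structure
of both data types with known ground truth.

## Two-group comparison contract

Every differential call — gene, summed enzyme, lipid class or stratum —
uses one contract: for conditions A and B with replicate means `m_A`,
`m_B` and pseudocount `c` (default 1),

```
log2FC = log2((m_B + c) / (m_A + c))
p      = two-sided Welch t-test on log2(value + c)
```

with Benjamini–Hochberg adjustment across the genes of a contrast. A
call requires `|fold| > threshold` and `p < alpha`, both strict. The
pseudocount guards `log(0)`; on TPM it suppresses apparent fold changes
of genes expressed near or below ~1 TPM, which is intentional — such
changes are not reliably measurable at this depth.

Degenerate inputs: if both groups have zero variance, `p = 1` when the
means are equal and `p = 0` otherwise, keeping constant fixtures
well-defined. At n = 3 the Welch test is *conservative*: its
Satterthwaite degrees of freedom fall below the pooled value, and the
measured null rejection rate at nominal 0.05 is ≈ 0.034. Tests therefore
check that the false-positive rate does not exceed the nominal level
rather than that it equals it.

The test is a deliberate stand-in behind a single interface: the
original count-level analysis (RSEM + edgeR) needs raw reads, which this
package does not consume. A count-model variant can replace
`welch_log_test` without touching any caller.

### FDR versus raw p

The experiment's selection of *common* DE genes uses the unadjusted
`p < 0.05` with the 2-fold cutoff, so the pipeline's reciprocal
identification defaults to raw p (`RunConfig.de.use_fdr = False`), while
the DE module's own default is FDR-gated (`DECallConfig.use_fdr =
True`). Both rules are one flag apart. At the default synthetic
conditions (4-fold effects, CV 0.2, n = 3), BH-gating demands raw
p ≲ 0.004, beyond the power of a three-replicate Welch test, and would
drop joint sensitivity from ~0.97 to well under 0.8 without improving
the (already ~0) false-discovery proportion, because the reciprocal
design itself is a powerful filter: a null gene must pass fold and p in
*both* opposed contrasts with *opposite* signs to be miscalled.

## Reciprocal responder identification

Genes called DE in both the depletion (PD/PR) and restoration (PDR/PD)
contrasts form the common set; its size is scored against the
hypergeometric upper tail `P(X ≥ overlap)` for `|DE_a|` successes and
`|DE_b|` draws from the gene universe, computed in log space so
astronomically small tails remain quantifiable (the log10 tail is
reported alongside).

Each common gene is classified by the sign pair of its two fold changes:
`inverse` (up on depletion, down on restoration — tracks phosphate
loss), `positive` (the mirror), else `discordant`. Separately, the
common genes' z-scored nine-sample profiles are clustered with k-means
(k = 10 by default; k-means++, Lloyd, best of 50 restarts under a fixed
seed) and each group is labelled by the sign of the Pearson correlation
between its mean profile and the per-sample medium phosphate level
(1, 0, 1 for PR, PD, PDR by default; overridable in the design table).
Inverse-correlated groups are numbered first. The per-gene sign rule
exists alongside the group-level labels because downstream gene lists
(enrichment, concordance) should not inherit clustering noise; on
planted reciprocal responders the two agree for ≥ 95% of genes.
Euclidean distance on z-scored profiles is an assumption — the original
clustering tool's metric is not recorded.

## Pathway enrichment

For a pathway with `K` genes among `N` universe genes, `k` of them in a
subset of size `m`:

* fold enrichment `FE = (k/m) / (K/N)`;
* p-value: upper tail of `Hypergeometric(N, K, m)` at `k`, summed in
  log space (default), or of `Binomial(m, K/N)` with
  `tail_model="binomial"` — the with-replacement approximation reported
  by several legacy enrichment web services. For the margins
  (6, 342, 51, 7140) the exact tail is 0.0339 and the binomial tail
  0.0377; the package exposes both rather than silently blending them.

A pathway passes the filter when `FE > 2`, raw `p < 0.05` and `k ≥ 5`
(the subset-hit reading of the minimum-gene rule; filtering on `K`
instead is a switch). Bonferroni-adjusted values over the pathways
tested are reported but do not gate the filter, which reproduces the
published filtering behaviour. Unannotated genes count toward `N`.

## Enzyme aggregation and concordance

Most enzymes in this transcriptome are encoded by two or more gene
copies, so an enzyme's level is the per-sample *sum* of its copies'
TPM; a gene carrying several EC numbers contributes fully to each (no
split rule is defensible without isoform evidence, and double counting
is transparent in the output). Enzyme changes are tiered per contrast:

* `significant` — fold beyond 1.5 (either direction) with p < 0.05 from
  the shared contract on the summed, logged levels;
* `moderate` — fold beyond the 10% band but not significant (band
  symmetric in ratio space: up > 1.1, down < 1/1.1 ≈ 0.909; a
  `fraction` mode uses down < 0.9);
* `unchanged` otherwise.

Pathway concordance asks whether the direction-altered enzymes
(moderate + significant) predominantly move one way, with the one-sided
exact sign test `p = Σ_{i=n_maj}^{n} C(n, i) 2^{-n}`. This identity was
fixed because it reproduces all four worked examples from the printed
counts (9/10 → 0.0107; 8/9 → 0.0195; 11/14 → 0.0287; 12/13 → 0.0017).
Ties report the up direction with a `tied` flag.

## Lipidomics

Species are parsed from shorthand (`PC(16:0/20:5)`; `_` separators mean
sn positions unresolved; lyso classes and FFA carry one chain, TG
three). Levels are peak areas per million cells:
`level = area / (cells / 1e6)`. Classes are exact sums of member
species and are tested at two tiers (2-fold and 1.5-fold) under the
shared contract, mirroring the two reporting levels used for membrane
lipids: phospholipid classes clear the 2-fold tier under depletion
while the thylakoid lipids (MGDG, DGDG, SQDG) move only at the 1.5-fold
tier.

Pathway of origin follows the sn2 rule: C16:X at sn2 → plastid
("prokaryotic") synthesis; C18:X → ER ("eukaryotic"); other sn2 chains
(20:4, 20:5) and unresolved species are unassigned. For TG the middle
chain of three is treated as sn2. Unassigned species are excluded from
origin-stratified comparisons but retained in class totals; strata
partition each class exactly. EPA/ARA-bearing PC and PE are available
through a dedicated filter since their sn2 chains are never
origin-informative. Acyl-chain totals weight a species' level by the
multiplicity of each chain among its positions.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

Transcriptome: 7140 genes × 9 samples. Baselines are lognormal with
sd(log10) = 0.55 — chosen so the generated gene set spans ≈ 4 decades
of expression. 4.8% of genes are inverse responders (×2^2 under PD
only), 3.5% positive responders (mirror), 4% one-contrast-only movers
(half persist after restoration, half move only on restoration).
Replicate noise is lognormal with CV 0.2 — a free parameter, as no
within-condition dispersion is published for these data — and columns
are renormalized to sum to 10^6 (the TPM contract). 60% of genes carry
an EC number; copy numbers are drawn from {1: 0.23, 2: 0.40, 3: 0.25,
4: 0.12}, so ~77% of enzymes are multi-copy; copies share one enzyme
level split by a Dirichlet draw. Pathways are sets of enzymes; the
first four are planted concordant (all member enzymes shifted ×1.4 in
one direction under PD, mirrored under PDR), giving the sign test known
positives. Effects are symmetric in log space, so the two contrasts are
mirror images for planted genes.

Lipidome: 15 classes, 4–9 species each (~95 total), chains drawn from
weighted sn1/sn2 pools (PC and PE are guaranteed EPA-sn2 species, PE
also an ARA-sn2 species). Planted depletion folds: phospholipid
classes ×0.4, thylakoid lipids ×0.6, DGTS ×3, TG ×8, DG/FFA ×1, all
restored to ×1 under PDR; a map value may be a per-origin dict to plant
origin-dependent remodeling. Species levels are multiplied into peak
areas using per-sample cell counts (1–5 × 10^6) and normalized back, so
the per-cell normalization path is exercised end to end.

What the generator does **not** emulate: read counts and their
mean–variance relation, transcript-length effects, isoform ambiguity,
batch structure, correlated noise between co-regulated genes, spectral
artefacts, adducts, or missing lipid identifications. Recovery results
on synthetic data therefore demonstrate that the pipeline's logic and
thresholds behave as designed under the assumed noise model — not that
real data of this type would yield the same sensitivity.

## Numerical choices

* Tails in log space (`logsumexp` over `logpmf`) so overlap p-values
  far below float underflow stay quantifiable via the log10 tail.
* Strict inequalities at every threshold.
* k-means ties across restarts resolve to the first-best restart under
  the fixed seed; a constant gene profile is an error, not a silent
  drop.
* Floats are written with 9 significant digits; read-back agrees to at
  least 6.
* Single-threaded, deterministic reductions; the run report excludes
  timings so reruns are byte-comparable.

## Problem sizes

Default-scale runs are used throughout: the full synthetic pipeline
(7140 genes, ~2,700 enzymes, ~95 lipid species) completes in a few
seconds, the 100-seed lipid remodeling recovery in ~4 s, and the whole
test suite in under a minute on one CPU.

## Known limitations

* The Welch stand-in is conservative at n = 3 and is not a count model;
  absolute DE counts from real count data will differ.
* Enrichment treats pathways independently; no gene-set overlap
  correction.
* The sn2 origin rule is a heuristic from plant/algal glycerolipid
  biochemistry; it cannot classify PUFA-sn2 or unresolved species.
* Multi-EC genes are double-counted across enzymes by design.
* The generator's noise model is the simplest consistent with the
  design (independent lognormal); see above for what that excludes.
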