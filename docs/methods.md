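# Methods

`gsamultiverse` models how a result-driven analyst can tweak a gene set
analysis (GSA) toward a preferred outcome, and how much that tweaking biases
the reported results.  This note describes the statistical machinery, the
synthetic data it runs on, the defaults, and the deliberate design choices.

## The analysis pipeline and its degrees of freedom

Every evaluated pipeline variant runs the same stages on a gene × sample
count matrix with a two-level condition:

1. **duplicate-ID removal** after many-to-one gene-ID conversion
   (`keep_first` or `keep_highest_mean` source row per target ID),
2. **prefiltering** of lowly expressed genes (`none`, row-sum threshold
   `total_count:θ`, or `cpm:c:k` — CPM > c in ≥ k samples),
3. **transformation/normalization** (`cpm`, `log2_cpm:pseudocount`, or
   `median_ratio_log`: median-of-ratios size factors with a geometric-mean
   reference over all-nonzero genes, then log2(x+1)),
4. **differential-expression scoring** (`welch_t`, `snr`, `wilcoxon_z`,
   `moderated_t`), and
5. a **GSA archetype** with its own parameters (gene set database, ORA
   universe, ranking metric, p-value null, enrichment-score weight).

Each stage is addressable by a string option key; the set of (step, option)
pairs forms the *choice space* the optimizer explores.

The four DE scores are deliberately self-contained archetypes rather than
re-implementations of limma/voom, DESeq2 or edgeR.  The optimizer only
needs interchangeable options with genuinely different behavior; the
moderated t shrinks per-gene pooled variances toward their mean with a
fixed prior weight of 4 pseudo-observations (an intentionally simple,
testable stand-in for empirical-Bayes shrinkage), and the SNR statistic
floors each group SD at max(0.2·|group mean|, 1e−8) to avoid infinities on
low-variance genes.  `snr` carries `p = NaN`: it is a ranking metric only.

## GSA archetypes

* **ORA** — upper-tail hypergeometric probability of the observed overlap
  between the DE gene list (BH-adjusted DE p < 0.05) and each set, given a
  configurable universe (`all_measured`, `post_filter`, `all_annotated`);
  BH adjustment across sets.
* **GSEA, sample-permutation null** — weighted Kolmogorov–Smirnov
  enrichment score over the ranked gene list (hits add |metric|^p_w
  normalized over hits, misses subtract 1/(N−N_hit); ES = signed maximum
  deviation).  The DE scoring and ranking are *recomputed* for every
  sample-label permutation (group sizes preserved), so inter-gene
  correlation propagates into the null.
* **GSEA, preranked** — identical ES machinery on a fixed ranked list; the
  null permutes set membership over list positions (gene permutation),
  implicitly assuming independent genes.
* **Weighted FCS** — a PADOG-style score: per-set weighted mean of
  |moderated t| with gene weights 1 + sqrt((f_max−f_g)/(f_max−f_min)),
  where f_g counts the database sets containing gene g; standardized
  against a sample-permutation null.

NES divides each ES by the absolute mean of same-sign null ES.  Permutation
p-values use the pseudocount estimator (1 + b)/(1 + B), counting same-sign
null scores at least as extreme among B permutations, so p is never 0 and
never above 1; when a set has no same-sign null scores its p is 1 with a
logged note.  This estimator is conservative when the sign classes are
balanced (its null distribution concentrates below ~0.5), which mainly
matters for single isolated sets; the FDR-inflation phenomenon of interest
involves many co-extreme sets and is unaffected.

FDR control is Benjamini–Hochberg on the raw (permutation or
hypergeometric) p-values for every archetype.  The two published
significance conventions — BH-adjusted p < 0.05 (R-package tools) and
q < 0.25 (web GSEA tools) — are both expressed through `MethodSpec`
(`threshold`, `threshold_on`); numerically both compare BH-adjusted values,
with the q label carried as metadata.  Using BH in place of the
ratio-of-tails q estimator of the original GSEA is a deliberate
simplification: it is deterministic and keeps the threshold convention
orthogonal to the null mechanism.

With B = 100–200 permutations the smallest attainable p is 1/(B+1) ≈
0.005–0.01, so single sets essentially cannot clear BH at 0.05 among ~50
sets; detections require either the analytic ORA p or many jointly extreme
sets.  This resolution is adequate for the calibration/inflation contrasts
the package quantifies; raise `n_permutations` for sharper per-set
inference.

**Ranks.**  The rank goal uses *dense* ranking of sets by ascending
adjusted p (tied values share a rank) divided by the maximum assigned rank.
Dense ranking is chosen because it satisfies the boundary property exactly:
an adjusted p of 1 always gives a relative rank of 1.

## Greedy stepwise optimization

The optimizer mimics a stepwise (not exhaustive) tweaker.  Steps are
processed in a fixed a-priori order — duplicate removal, DE method,
prefilter, transformation, database, ORA universe, ranking metric, p-value
null, ES weight — i.e., preprocessing before parameters, with the DE method
deliberately optimized *before* prefiltering because prefiltering
conventions are tied to the DE method.  At each step every alternative is
evaluated with all other steps held at their current choices; the strictly
best improving option is adopted (equality never improves; ties go to the
earlier-declared alternative; a crashing option is logged and counts as
non-improving).  The final objective is therefore monotone in the goal's
direction, and the trajectory records every evaluation for audit.

Three goals: maximize the DEGS count; minimize a target set's adjusted p;
minimize its relative rank.  The database choice is exploited only for the
DEGS-count goal (a named target set from one database typically does not
exist in another); the universe only for ORA; metric/null/weight only for
the ES-based archetypes.  A target set missing from a results table (e.g.,
removed by set-size bounds) contributes the worst-case objective (adjusted
p = 1, relative rank 1), keeping the objective total.

All evaluations within one optimization run share a single permutation
seed, so option comparisons measure the options rather than Monte-Carlo
noise.

## Study grid

A *setting* is one (goal, data set, label assignment, method[, target
set]) combination; the reference design uses 3 goals × 2 data sets × (10
random label permutations + the true labels) × 7 method slots, with three
manual-only (web) slots excluded from the rank goal and two target sets for
the target goals — 638 settings.  Label permutations destroy any true
signal, so any improvement of the objective under them is pure
overoptimism; under the true labels the same delta measures variability
rather than overoptimism.  Each setting's child seed is a deterministic
hash of the master seed and the setting descriptor, so single settings
re-run in isolation; the runner skips settings already on disk, making
studies resumable and byte-reproducible.

## Synthetic data

The generator produces the structure the conclusions depend on; it is a
stand-in, not a model of any real data set:

* counts ~ NB with gene-wise log-uniform means (natural-log range
  default (0.7, 6.5)) and a common dispersion α = 0.2 (variance
  μ + αμ²), typical of bulk RNA-seq;
* per-sample library-size factors, log-uniform in (0.7, 1.3);
* a latent per-block Gaussian factor: gene g in sample j receives a
  multiplicative log-mean perturbation exp(s·η − s²/2) with s = 0.8 and
  corr(η_g, η_g′) = ρ inside a correlation block (default block size 50,
  ρ = 0 unless stated), independent across blocks.  The mean correction
  keeps expected counts unchanged, so ρ only moves dependence, not
  marginals;
* optional signal sets: member genes get a between-group log2-mean
  difference equal to the stated effect (half up in group 1, half down in
  group 2);
* many-to-one ID tables: a chosen fraction of target IDs receives two
  source IDs; gene set databases are drawn on the *target* ID space with a
  controlled overlap between consecutive sets, or aligned 1:1 with the
  correlation blocks (`block_aligned`) — the configuration under which
  gene-permutation nulls are miscalibrated.

What the generator does **not** emulate: read-level noise, batch effects,
length/GC bias, >2 conditions, per-gene dispersion, empirically realistic
mean–variance trends, or the ontology-like nesting of real gene set
databases.  Passing tests therefore demonstrate internal correctness and
the qualitative mechanisms (calibration, inflation, overoptimism), not
quantitative agreement with any real benchmark data set.

## Numerical choices and degenerate inputs

* Ranked lists sort decreasing by metric with lexicographic gene-ID
  tie-break — fully deterministic.  NaN metrics are an error naming genes.
* ES sets whose hit weights sum to zero (all member metrics zero under
  p_w = 1) fall back to equal hit weights; at an exact magnitude tie
  between the positive and negative extremum of the running sum the first
  position of the maximal |deviation| wins.
* Set-size bounds default to [5, 500] after intersection with analyzed
  genes; excluded sets are absent from the results table.
* Prefiltering that removes every gene, all-zero sample columns, and
  fewer than two samples per group are errors; median-of-ratios without
  an all-nonzero gene falls back to column-sum size factors with a
  warning; DE sources absent from the ID table are dropped with a warning.
* Welch t on zero-variance genes maps the undefined 0/0 statistic to 0
  with p = 1.
* The two-sample rank-sum z uses the exact finite-population variance of
  the rank sum, which absorbs ties without a separate correction term.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on generated data sized for
a single CPU: null-calibration and inflation contrasts use 20 replicates of
2000 genes × 50 sets × (10+10) samples with 100 permutations per GSA call
(block size 40 so the 50 sets align with 50 correlation blocks);
signal-recovery uses 50 replicates of 1000 genes × 30 sets with one
30-gene set at log2 effect 2.0; the overoptimism contrast runs 20
permutation settings per archetype at 1000 genes × 25 sets.  These sizes
are the package's own defaults for a desk-scale reproduction; all scale up
linearly via their parameters.

## Known limitations

* The archetypes stand in for families of tools; absolute DEGS counts are
  not comparable to any specific published tool.
* The q < 0.25 convention is honored via BH-adjusted values, not a
  Storey-type q estimator.
* Permutation resolution bounds attainable significance (see above).
* The greedy optimizer is order-dependent by design; it reproduces the
  stepwise behavior of a human tweaker, not the global optimum of the
  multiverse.
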