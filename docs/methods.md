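# Methods

## The model behind the package

Bulk RNA-seq read counts measure relative, not absolute, abundance.
With `mu[g, k]` the expected transcripts per cell of gene *g* in
condition *k*, `L[g]` the gene length and `N[k, r]` the library size,
the expected count is

    E(X[g, k, r]) = mu[g, k] * L[g] / S[k] * N[k, r],
    S[k] = sum_g mu[g, k] * L[g],

where `S[k]` is the transcriptome size of condition *k*. The ratio of
raw counts between two conditions therefore confounds the biological
ratio `mu[g, 2] / mu[g, 1]` with both the library-size ratio and the
transcriptome-size ratio `S[1] / S[2]`. When regulation is asymmetric
(most changed genes move in one direction), `S` differs between
conditions and every unchanged gene's count share shifts — the
composition bias that scaling normalization removes. TMM, RLE and MRN
all estimate a per-sample (or per-condition) relative transcriptome
size from ratios of counts to a reference and divide it out.

## Procedures and conventions

All three methods are implemented in the same seven-step frame:
pre-normalization (`Y = X / N`, columns sum to 1), reference
construction, ratio-based relative factors, optional unit-product
adjustment, effective library sizes, final size factors, normalized
counts. The numerically load-bearing conventions:

* **Median** — midpoint interpolation between the two central order
  statistics at even counts (the default of mainstream statistical
  software). Consequence: the RLE/MRN equality at two samples is exact
  only when the usable-gene count is odd, because only then does the
  median commute with monotone transforms such as `sqrt` and
  reciprocals. At even counts the mismatch is second-order in the
  relative gap between the two central order statistics (≈ gap²/8),
  which shrinks like 1/G; tests use odd-count fixtures for
  machine-precision assertions and a 1e-6 band, at ten-thousand-gene
  scale, otherwise. (A lower-order-statistic median would *not* fix
  this: it fails to commute with reciprocals at even counts, producing
  first-order discrepancies.)
* **Trimming** — `floor(trim_frac * n)` values are removed from each
  tail, rank-based, with ties broken by original gene order (stable
  sort). M-trim and A-trim are applied independently and the survivors
  intersected; intersection makes the order immaterial. The default
  trims are 0.30 (M) and 0.05 (A) per tail. A trim of exactly 0.5 is
  special-cased to the exact median, so the TMM→median limit — the
  hinge of the TMM/MRN equivalence — holds to machine precision
  rather than approximately (a 0.499 trim leaves stray genes in the
  mean). Per-tail semantics were chosen because they make the
  0.5 → median limit exact.
* **TMM mean scale** — the default averages the surviving ratios
  directly (`mean_scale="ratio"`); `"log2"` averages M-values and
  returns `2**mean(M)`, the form common in the literature. Both are
  provided because they genuinely differ away from the median limit;
  at a 50% M-trim they coincide. Inverse-variance precision weighting
  is deliberately not implemented: the unweighted trimmed mean is the
  analyzed object here, and weighting would break the exact median
  limit.
* **Reference choices** — TMM defaults to the sample whose upper
  quartile of pre-normalized values (type-7 linear interpolation) is
  closest to the mean upper quartile, ties to the lowest index; the
  equivalence checks pin the reference to the first sample, as the
  equalities require. MRN defaults to the first condition in order of
  appearance. RLE needs no choice.
* **Zeros** — a gene is usable for a pairwise comparison only when
  both entries are strictly positive (M/A values undefined otherwise);
  for RLE, any zero annihilates the geometric-mean pseudo-reference
  and excludes the gene; for MRN, both replicate-averaged condition
  means must be positive. This MRN rule was chosen because it reduces
  exactly to RLE's usable set in the two-sample no-replicate design,
  which the size-factor equality requires. All-zero rows may be
  present in the input; they are never removed from the matrix, only
  from the medians.
* **Counts** — non-negative integers expected; real values (expected
  counts) are accepted by the in-memory container with a logged
  warning, while the file reader rejects non-integral cells by default
  (`strict_integers=False` opts into the warn-and-accept path).

The equivalence checks report `max |a-b| / max(|a|, |b|)` over entries.
The CPM rescaling constant in the three-way check is the geometric
mean of the library sizes, which for two samples is `sqrt(N1*N2)`;
it falls out of the algebra of the unit-product adjustment
(`e_TMM = f_RLE * sqrt(N1*N2)`), and is verified numerically rather
than assumed.

## The simulator

`SimulationConfig` draws counts from the expectation model above.
Defaults, chosen once as a realistic bulk design: 5000 genes, 2
conditions × 3 replicates, gene means log-normal(1, 1.3) (heavy-tailed
expression), lengths log-normal around 1.5 kb, library sizes
log-uniform on 5×10⁵–5×10⁶ reads, negative-binomial noise with
dispersion 0.1 (`Var = m + 0.1 m²`; dispersion 0 gives Poisson for
exact-limit tests). Differential expression multiplies `de_fraction`
of genes by `fold_change` in every non-reference condition;
`de_up_share` controls the up/down split, and values near 1 create
strong composition bias. `make_composition_bias_fixture` builds the
canonical two-sample stress case: 1001 genes, 30% of genes four-fold
up in condition 2, none down, sub-seed advanced until the usable-gene
count is odd.

What the simulator does **not** emulate: gene-length biases beyond the
linear `L[g]` factor, GC/positional effects, batch structure,
correlated genes, or single-cell zero inflation. Passing tests
therefore demonstrate correctness of the estimators under the
expectation model and their exact algebraic relationships — not
robustness to artifacts the model lacks.

## What the checks measure, and their operating characteristics

* **Equivalence checks** (no-replicate TMM=MRN; two-sample RLE=MRN;
  three-way normalized counts): max relative discrepancies over 50
  simulated designs each, asserted at 1e-12 on odd-count fixtures.
  The even-count RLE/MRN band (1e-6) runs at ~10⁴ genes, where the
  interpolation error analysis above puts the worst of 50 matrices
  near 2×10⁻⁷ with negligible tail risk; at ~10³ genes the same
  implementation measurably exceeds 1e-6, purely from interpolation.
* **Structural invariants**: unit geometric mean of TMM adjusted
  factors and of MRN size factors, unit column sums after
  pre-normalization, at 1e-10 on every fixture.
* **Depth correlation separation**: on cohorts of 80 samples (2 × 40)
  with ~25-fold library-size variation and strong one-sided bias, TMM
  size factors must be uncorrelated with depth (|Pearson r| < 0.3)
  while RLE and MRN factors track it (r > 0.7), on ≥ 18 of 20 seeds.
  The cohort size matters: the null sd of r is ≈ 1/sqrt(S−1), so at
  80 samples the TMM bound is a ≈ 2.7σ event per seed and the 18/20
  rule has ≈ 99.9% power; at 9 samples the same rule would fail for
  any correct implementation (P(|r| < 0.3) ≈ 0.6 per seed).
* **Loop-oracle agreement**: the vectorized medians-of-ratios and
  double-trimming paths agree to 1e-12 with naive per-gene loop
  reimplementations (python `statistics`, explicit sorting) on 100
  random 50 × 6 matrices.
* **MRN parameter recovery**: under 30% one-sided four-fold DE, the
  median-of-ratios estimator is *not* an unbiased estimate of the
  noiseless ratio `S1/S2`: the sample median sits at the 5/7 quantile
  of the non-DE genes' noise distribution, an upward shift of ~18% at
  dispersion 0.1 (~5% even for Poisson noise) that any
  median-of-ratios implementation shares. The recovery check
  therefore compares the pipeline estimate against the model-implied
  median of the observed-ratio distribution, computed by an
  independent Monte-Carlo draw from the configured truth, and asserts
  the mean error over 20 cohorts (5000 genes, 2 × 3 samples) is
  within 3% (measured ≈ 0.2%, per-cohort spread ≈ ±2.5%). The
  noiseless-truth gap is a property of the estimator under asymmetric
  DE, documented here so nobody mistakes it for a bug.

## Known limitations

* Bit-exact replication of the reference R implementations is a
  non-goal: edgeR's TMM additionally precision-weights the trimmed
  mean and uses its own rank conventions. The unweighted RLE paths
  were spot-checked against DESeq2's `estimateSizeFactorsForMatrix`
  and edgeR's `calcNormFactors(method="RLE")` and agree to printed
  precision.
* MRN's final size factors are provably independent of the reference
  condition only when the relevant medians fall on data points (odd
  usable counts); the package documents, and tests, the invariance on
  such fixtures only.
* Scaling normalization as a whole assumes most genes are not
  differentially expressed; none of these methods is meaningful when
  that fails.
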