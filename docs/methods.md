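# Methods

## Count model and simulation design

Counts are generated per gene and sample as Poisson(`mu`) when the
dispersion is zero and as negative binomial with mean `mu` and size
`1/alpha` otherwise (variance `mu + alpha*mu^2`), drawn as a gamma–Poisson
mixture. A simulated dataset is defined by `SimConfig`:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 10 000 | genes (rows) |
| `n_samples_per_group` | (10, 10) | two-group design |
| `dispersion` | 0.1 | NB `alpha`, shared by all genes of a dataset |
| `de_fraction` | 0.3 | fraction of genes made DE (exactly `round(0.3 n)`) |
| `fc_range` | (1.3, 4.0) | DE fold changes, uniform; direction up/down with prob 1/2 |
| `mean_source` | `"parametric"` | log-normal base means, or a file of empirical means |
| `log_mean`, `log_sd` | ln 500, 2.0 | log-scale location/spread of the parametric means |

The studied dispersion levels are 0 (technical replicates), 0.001–0.01
(technical / some genetically identical replicates), 0.1–0.3 (unrelated
biological replicates) — the ranges observed when per-gene NB dispersions
are estimated on public bulk RNA-seq datasets of each replicate type.

The parametric mean distribution is a log-normal truncated below at 1
(median ≈ 500, spanning roughly 1–10^5), standing in for base means sampled
from a deep bulk dataset; a file-based mode lets users supply real per-gene
means instead. Group 1 keeps the base mean; group 2 is multiplied or
divided by the fold change. Counts are simulated at the normalized scale
(all true size factors 1); an optional per-sample depth multiplier
exercises the normalization path. Binomial thinning (`downsample`)
implements depth titration: each entry is replaced by a Binomial(X, p)
draw, which maps Poisson(mu) marginals to Poisson(p·mu) exactly.

What the generator does **not** emulate: inter-gene correlation (gene
scores are independent across genes, so gene-permuting GSEA faces no
correlation-induced false positives here), zero inflation and other
single-cell features, per-gene dispersion heterogeneity within a dataset,
and compositional library-size effects. Tests passing on these simulations
therefore speak to the count-noise mechanism only, not to every failure
mode of real data.

One root seed drives three spawned streams (means, DE injection, count
sampling), so each stage is independently reproducible; repeated
experiments use `root_seed + repeat_index` per repeat.

## Normalization

Median-of-ratios size factors: reference genes are those with strictly
positive counts in every sample; the per-gene geometric mean is computed in
log space; a sample's factor is the median of its counts' ratios to the
reference (arithmetic mean of the two central ratios for even reference
counts). Note that with a geometric-mean reference over `m` samples,
rescaling one sample by `k` moves its factor by `k^((m-1)/m)` and every
other factor by `k^(-1/m)`: only factor *ratios* are exactly scale
equivariant, which is what division by the factors consumes.

## Per-gene scores

* **SNR** `(mean1 - mean2)/(sd1 + sd2)` with `n-1` sample SDs on normalized
  counts. Genes whose two SDs are both zero are undefined and excluded from
  rankings (a GSEA-style variance floor `sd >= 0.2 |mean|` is available
  behind a flag, default off, because the theory concerns the plain SNR).
* **Welch T** `(mean1 - mean2)/sqrt(sd1^2/n1 + sd2^2/n2)`.
* **Naive NB LRT**: full model with one mean per group, null with a common
  mean, sample offsets `log(size_factor)`. Each model's single per-gene
  dispersion is estimated by maximum likelihood, alternating closed-form
  mean updates (a damped fixed point of the NB score equation, exact in one
  step for equal size factors) with a bounded ternary search over
  `log(alpha)` in [1e-8, 10] (45 iterations, bracket < 1e-6 in log units —
  far below estimator noise). The statistic `2(ll_full - ll_null)` is
  referred to chi-square(1); BH q-values follow. This reproduces the
  likelihood ratios of fitting both models with `MASS::glm.nb` to numerical
  precision (verified against an Rscript oracle during development).
  Known finite-sample behavior: with ML-estimated dispersion at small n
  (e.g. 7+7), the null p-values are mildly anticonservative in the bulk
  (null ECDF excess ~0.05 at p ≈ 0.25); BH discoveries on null data remain
  at the handful level.
* **Dispersion estimators**: a pooled within-group moment estimator
  `max(0, sum_k w_k (v_k - m_k)/m_k^2)` with `w_k ∝ n_k - 1`, and a
  profile MLE (group means of normalized counts plugged in, same bounded
  search). The profile MLE carries the usual downward ML bias of order
  `(n - 2)/n`; no shrinkage across genes is applied by design.

## Closed-form theory

`snr_analytic`, `snr_upper_bound`, `snr_lower_bound` and
`coefficient_ratio` implement the SNR as a function of (mu1, fold, alpha)
and its bounds, with the convention `mu1 >= mu2`, `fold >= 1`; `alpha = 0`
takes the exact Poisson branch. The lower bound is returned in two forms:
the tight intermediate form `(1 - 1/sqrt(f))/sqrt(1/mu1 + alpha)` and the
envelope `c(f) * min(1/sqrt(alpha), sqrt(mu1))` with
`c(f) = (1 - 1/sqrt(f))/sqrt(2)`. The envelope uses the *min* of the two
branch constants: a max-form envelope would exceed the upper bound whenever
`mu1 * alpha` is large and cannot be a lower bound; the min-form follows
from `1/(1/mu1 + alpha) >= min(mu1, 1/alpha)/2` and is verified against the
analytic SNR on a dense grid in the tests. The coefficient ratio attains
its supremum ≈ 1.2071 near `f ≈ 5.83`.

## Bias profiling

Genes are sorted by mean normalized count (ties broken by gene identifier),
cut into consecutive bins of 1000, and summarized by SNR quantiles
(5/25/50/75/95%), the IQR, and — given DE calls — the per-bin DE
proportion. `bias_trend` reduces a channel to the Spearman rank correlation
with the bin index, optionally skipping initial low-count bins.

Two structural caveats, found while validating and worth knowing before
interpreting the scalar:

* The IQR channel is insensitive to the count bias when the DE fraction is
  ≤ ~0.25 per tail: the null-gene SNR is pivotal (numerator and denominator
  both scale like sqrt(mu)), so the central 25–75% band is flat in the
  count even for Poisson data. The bias lives in the outer quantiles; use
  the recorded q05/q95 band for Poisson-regime contrasts.
* Spearman correlation is scale-free: it detects *any* consistent
  monotone gradient, however shallow. Large-dispersion data retain weak
  positive gradients (the sqrt(mu) branch at small counts, plus a
  composition effect — up-regulated DE genes have larger overall means and
  accumulate in high bins), so the trend statistic does not decrease
  reliably with dispersion even though the *magnitude* of the per-bin
  contrast collapses. The profile-level tests therefore assert the
  magnitude contrasts (outer-band growth at `alpha = 0`; capped, flat band
  with a depressed first bin at `alpha = 0.3`) rather than trend ordering
  across dispersions.

## GSEA

Weighted running-sum enrichment score (hit increments `|score|^p`
normalized by the set total, p = 1 by default; miss decrements
`1/(N - K)`); the ES is the extreme signed deviation, with exact magnitude
ties resolved to the positive peak. Sample-permuting mode recomputes every
gene's SNR under random relabelings that preserve group sizes (exhaustive
enumeration when fewer distinct relabelings than requested permutations
exist); preranked mode draws random same-size sets against the fixed
ranking, with independent draws per set (whole-row rejection sampling of
k-subsets, exact). NES divides the ES by the mean |null ES| of matching
sign per set; nominal p is one-sided against the matching-sign null; FDR
follows the canonical pooled-null NES-ratio with sign-stratified
numerator and denominator, capped at 1. Default 1000 permutations; ranking
ties broken by gene identifier; genes with undefined SNR are removed from
the universe and sets shrink accordingly.

The false-positive experiment simulates, per (dispersion, DE-fraction)
cell and repeat, a dataset with randomly chosen DE genes (half up, half
down, fixed 2-fold), partitions the genes into 100 disjoint random sets,
and runs both GSEA modes on the same data, counting sets with q < 0.05.
Because the canonical FDR compares 100 observed null sets against their own
pooled permutation null, the most extreme observed set occasionally lands
past the q = 0.05 line by order statistics alone (~0.1 sets per repeat and
sign in our runs; an independent implementation, gseapy, flags the same
sets). A literal zero false positives is therefore the idealized
expectation, not a guarantee of the procedure.

## Problem sizes and numerics

Default experiment sizes (10 000 genes, 7–10 samples per group, 100 sets
of 100, 500–1000 permutations, 3–10 repeats) were chosen so that every
estimator runs fully vectorized across genes: a complete simulate +
normalize + LRT pass takes a few seconds, and a 100-set × 1000-permutation
GSEA run takes ~1 s (preranked) to ~8 s (sample-permuting). Degenerate
inputs are handled explicitly: all-zero genes get LRT statistic 0 and
p = 1; genes with zero total SD are excluded from rankings; means are
floored at 1e-12 inside log-likelihoods; the dispersion search is clamped
to [1e-8, 10].
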