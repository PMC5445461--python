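# dispbias

Gene dispersion and the read-count bias in RNA-seq differential expression
and gene-set enrichment analysis.

## The problem

In two-group differential-expression (DE) analysis of RNA-seq counts, genes
with larger read counts (equivalently, longer genes) often receive larger
differential scores and are called significant more often — the *read-count
bias*. This package provides simulation, closed-form theory and inference
tools showing that the per-gene negative-binomial **dispersion** — not
sequencing depth or replicate number — determines whether this bias occurs,
and that the bias inflates false positives in sample-permuting GSEA but not
in preranked GSEA. It is aimed at methodologists and analysts who want to
check whether a dataset's replicate structure (technical, cell-line, or
unrelated biological replicates) puts it in the biased regime.

## The model

Counts are modelled as `X_ij ~ NB(mu_ij, sigma_ij^2)` with the standard
variance function

```
sigma^2 = mu + alpha * mu^2
```

where `alpha` is the gene's dispersion (`alpha -> 0` recovers Poisson).
For group means `mu_1 >= mu_2 = mu_1 / f`, the per-gene signal-to-noise
ratio on normalized counts,

```
SNR = (mu_1 - mu_2) / (sigma_1 + sigma_2),
```

satisfies

```
(1 - 1/sqrt(f)) / sqrt(1/mu_1 + alpha)  <=  SNR  <=  min(1/sqrt(alpha), sqrt(mu_1)),
```

and the ratio of the two bound coefficients, `((1-1/f)/(1+1/f)) / (1-1/sqrt(f))`,
stays inside `(1, 1.21)` for every fold change. Consequences:

* `alpha = 0` (technical replicates): `SNR ≈ sqrt(mu_1) - sqrt(mu_2)` grows
  without bound in the count — strong read-count bias, at any depth.
* `alpha >= 0.1` (unrelated biological replicates): SNR is capped by
  `1/sqrt(alpha)` regardless of count, fold change or gene length — no bias
  except at small counts (< tens), where the `sqrt(mu_1)` branch is active.
* With `mu = c N L` (transcript abundance x length), the same cap removes
  the gene-length bias whenever the dispersion is appreciable.

The package implements, as separately usable modules: an NB count simulator
with controlled dispersion and DE injection (`simdata`), median-of-ratios
normalization (`normalize`), per-gene SNR / Welch-T / naive NB
likelihood-ratio scores and dispersion estimators (`estimators`), the
closed-form bounds (`theory`), count-binned bias profiling (`biasmetrics`),
and weighted-KS GSEA with sample-permuting and preranked nulls plus a
false-positive experiment driver (`gsea`).

## Worked example

Simulate a dataset in which 30% of genes are DE at 2-fold but *randomly
chosen*, so no gene set is truly enriched, then count falsely significant
sets (FDR < 0.05) among 100 disjoint random sets of 100 genes:

```python
import numpy as np
import dispbias as db

for alpha in (0.001, 0.3):
    cm, truth = db.simulate_dataset(db.SimConfig(
        n_genes=10_000, n_samples_per_group=(10, 10),
        dispersion=alpha, de_fraction=0.3, fc_range=(2.0, 2.0), seed=0))
    norm, factors = db.median_ratio_normalize(cm)
    snr = db.snr_scores(norm, cm.group)["snr"]
    sets = db.make_gene_sets(cm.gene_ids, 100, seed=1)
    sample = db.sample_permute_gsea(norm, cm.group, sets, n_perm=500, seed=2)
    prerank = db.preranked_gsea(snr, sets, n_perm=500, seed=2)
    print(f"alpha={alpha}: |SNR| 99th pct = {snr.abs().quantile(0.99):.2f}, "
          f"bound 1/sqrt(alpha) = {1/np.sqrt(alpha):.2f}")
    print(f"  falsely significant sets (FDR<0.05): "
          f"sample-permuting = {(sample['fdr_q'] < 0.05).sum()}, "
          f"preranked = {(prerank['fdr_q'] < 0.05).sum()}")
```

prints

```
alpha=0.001: |SNR| 99th pct = 12.75, bound 1/sqrt(alpha) = 31.62
  falsely significant sets (FDR<0.05): sample-permuting = 99, preranked = 0
alpha=0.3: |SNR| 99th pct = 1.13, bound 1/sqrt(alpha) = 1.83
  falsely significant sets (FDR<0.05): sample-permuting = 1, preranked = 1
```

At the small dispersion typical of technical replicates, a handful of
high-count DE genes dominates the SNR ranking (scores up to ~13 against a
null spread of ~1) and virtually every random set is called "enriched" by
sample-permuting GSEA; at the dispersion typical of unrelated biological
replicates the SNR is capped near `1/sqrt(0.3) ≈ 1.8` and the false
positives all but disappear. The preranked (gene-permuting) null is immune
in both regimes.

The same pipeline is scriptable from the shell: `dispbias simulate`,
`dispbias de`, `dispbias bias`, `dispbias gsea`, `dispbias gsea-fp` and
`dispbias theory` (see `dispbias --help`); every run writes a
`manifest.json` with all parameters and the seed.

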