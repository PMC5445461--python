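"""Synthetic RNA-seq count matrices with controlled per-gene dispersion.

The generator emulates the statistical structure of bulk RNA-seq count data
from two-group designs: per-gene base means drawn from a heavy-tailed
log-scale distribution (or supplied from a file of empirical means), a
chosen fraction of differentially expressed genes with uniform fold changes,
and per-entry Poisson (dispersion 0) or negative-binomial (dispersion > 0)
sampling with variance ``mu + alpha * mu**2``.  Binomial thinning emulates
lower sequencing depth, and a random balanced partition of the genes
provides disjoint gene sets for enrichment-analysis null experiments.

Defaults match the simulation design the analyses in this package assume:
10,000 genes, ten samples per group, 30% DE genes with fold changes uniform
on [1.3, 4] (direction up or down with equal probability), and dispersion
levels spanning technical (0-0.01) to unrelated-replicate (0.1-0.3) data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "CountMatrix",
    "sample_base_means",
    "inject_de",
    "simulate_counts",
    "simulate_dataset",
    "downsample",
    "make_gene_sets",
]

#: log-scale location of the parametric base-mean distribution (median ~500,
#: a "high depth" dataset), and its log-scale spread.
DEFAULT_LOG_MEAN = math.log(500.0)
DEFAULT_LOG_SD = 2.0


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated two-group count dataset."""

    n_genes: int = 10_000
    n_samples_per_group: tuple[int, int] = (10, 10)
    dispersion: float = 0.1
    de_fraction: float = 0.3
    fc_range: tuple[float, float] = (1.3, 4.0)
    mean_source: str = "parametric"  # "parametric" or a path to one mean per line
    log_mean: float = DEFAULT_LOG_MEAN
    log_sd: float = DEFAULT_LOG_SD
    seed: int = 0
    depth_factors: tuple[float, ...] | None = None  # optional per-sample multipliers

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        n1, n2 = self.n_samples_per_group
        if n1 < 1 or n2 < 1:
            raise ValueError("both groups need at least one sample")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        lo, hi = self.fc_range
        if lo < 1 or hi < lo:
            raise ValueError("fc_range must satisfy 1 <= low <= high")
        if self.depth_factors is not None:
            if len(self.depth_factors) != n1 + n2:
                raise ValueError("depth_factors must have one entry per sample")
            if any(d <= 0 for d in self.depth_factors):
                raise ValueError("depth_factors must be positive")


@dataclass
class CountMatrix:
    """Integer gene x sample counts with a two-level group factor.

    ``counts`` is a genes-by-samples DataFrame of non-negative integers;
    ``group`` maps each sample (column) to its group label.
    """

    counts: pd.DataFrame
    group: pd.Series = field(default=None)

    def __post_init__(self):
        if self.group is not None:
            self.group = pd.Series(self.group)
            if list(self.group.index) != list(self.counts.columns):
                if len(self.group) != self.counts.shape[1]:
                    raise ValueError("group labels must match the sample columns")
                self.group.index = self.counts.columns
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in count matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def sample_base_means(
    n_genes: int,
    mean_source: str = "parametric",
    seed=0,
    *,
    log_mean: float = DEFAULT_LOG_MEAN,
    log_sd: float = DEFAULT_LOG_SD,
) -> np.ndarray:
    """Draw per-gene base means (expected normalized counts).

    ``mean_source="parametric"`` draws from a log-normal with the given
    log-scale location/spread, truncated below at 1 (by resampling), which
    gives a heavy right tail spanning several orders of magnitude.  Any
    other value is treated as a path to a text file with one positive mean
    per line, sampled with replacement.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _as_rng(seed)
    if mean_source == "parametric":
        out = rng.lognormal(log_mean, log_sd, n_genes)
        low = out < 1.0
        while low.any():
            out[low] = rng.lognormal(log_mean, log_sd, int(low.sum()))
            low = out < 1.0
        return out
    path = Path(mean_source)
    if not path.exists():
        raise ValueError(
            f"unknown mean_source {mean_source!r}: not 'parametric' and not a file"
        )
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                v = float(line)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno} is not a number") from exc
            if v <= 0:
                raise ValueError(f"{path}: line {lineno} has non-positive mean {v}")
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no mean values found")
    return rng.choice(np.asarray(values, dtype=float), size=n_genes, replace=True)


def inject_de(
    base_means, de_fraction: float, fc_range: tuple[float, float], seed=0
) -> pd.DataFrame:
    """Mark a fraction of genes as DE with uniform fold changes.

    Exactly ``round(de_fraction * n)`` genes get a fold change drawn
    uniformly from ``fc_range`` and a direction (up/down in group 2) with
    probability 1/2 each; the rest keep fold change 1.  Returns the
    ground-truth table (gene_id, base_mean, fold_change, direction, is_de).
    """
    base_means = np.asarray(base_means, dtype=float)
    if np.any(base_means <= 0):
        raise ValueError("base_means must be strictly positive")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    lo, hi = fc_range
    if lo < 1 or hi < lo:
        raise ValueError("fc_range must satisfy 1 <= low <= high")
    rng = _as_rng(seed)
    n = base_means.size
    n_de = int(round(de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    fold = np.ones(n)
    fold[de_idx] = rng.uniform(lo, hi, n_de)
    direction = np.full(n, "none", dtype=object)
    direction[de_idx] = np.where(rng.random(n_de) < 0.5, "up", "down")
    width = len(str(n))
    truth = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:0{width}d}" for i in range(n)],
            "base_mean": base_means,
            "fold_change": fold,
            "direction": direction,
            "is_de": fold > 1.0,
        }
    )
    return truth


def _group_means(truth: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Expected normalized counts per group: group 1 keeps the base mean,
    group 2 is multiplied (up) or divided (down) by the fold change."""
    mu1 = truth["base_mean"].to_numpy(dtype=float)
    f = truth["fold_change"].to_numpy(dtype=float)
    direction = truth["direction"].to_numpy()
    mu2 = np.where(direction == "up", mu1 * f, np.where(direction == "down", mu1 / f, mu1))
    return mu1, mu2


def simulate_counts(
    truth: pd.DataFrame,
    n_samples_per_group: tuple[int, int],
    seed=0,
    *,
    depth_factors=None,
) -> CountMatrix:
    """Draw a count matrix from the ground-truth table.

    Genes with dispersion 0 are Poisson; genes with dispersion alpha > 0 are
    negative binomial with mean ``mu`` and size ``1/alpha`` (variance
    ``mu + alpha mu^2``), drawn as a gamma-Poisson mixture.  ``depth_factors``
    optionally multiplies each sample's means to emulate unequal depths.
    """
    rng = _as_rng(seed)
    if "dispersion" not in truth.columns:
        raise ValueError("truth table must carry a 'dispersion' column")
    alpha = truth["dispersion"].to_numpy(dtype=float)
    if np.any(alpha < 0):
        raise ValueError("dispersion must be >= 0")
    n1, n2 = n_samples_per_group
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one sample")
    mu1, mu2 = _group_means(truth)
    mu = np.concatenate(
        [np.repeat(mu1[:, None], n1, axis=1), np.repeat(mu2[:, None], n2, axis=1)],
        axis=1,
    )
    if depth_factors is not None:
        depth = np.asarray(depth_factors, dtype=float)
        if depth.size != n1 + n2 or np.any(depth <= 0):
            raise ValueError("depth_factors must be positive, one per sample")
        mu = mu * depth[None, :]
    lam = mu.copy()
    over = alpha > 0
    if over.any():
        a = alpha[over][:, None]
        lam[over] = rng.gamma(shape=1.0 / a, scale=a * mu[over])
    counts = rng.poisson(lam)
    samples = [f"s{j + 1:02d}_g1" for j in range(n1)] + [
        f"s{j + 1:02d}_g2" for j in range(n2)
    ]
    frame = pd.DataFrame(counts, index=truth["gene_id"].to_numpy(), columns=samples)
    frame.index.name = "gene_id"
    group = pd.Series(["group1"] * n1 + ["group2"] * n2, index=samples, name="group")
    return CountMatrix(frame, group)


def simulate_dataset(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """End-to-end simulation: base means -> DE injection -> counts.

    A single root seed drives three dedicated child streams so each stage is
    independently reproducible.
    """
    root = np.random.default_rng(config.seed)
    means_rng, de_rng, count_rng = root.spawn(3)
    means = sample_base_means(
        config.n_genes,
        config.mean_source,
        means_rng,
        log_mean=config.log_mean,
        log_sd=config.log_sd,
    )
    truth = inject_de(means, config.de_fraction, config.fc_range, de_rng)
    truth["dispersion"] = config.dispersion
    cm = simulate_counts(
        truth,
        config.n_samples_per_group,
        count_rng,
        depth_factors=config.depth_factors,
    )
    return cm, truth


def downsample(counts, fraction, seed=0):
    """Binomial thinning: each entry X is replaced by Binomial(X, fraction).

    ``fraction`` may be a scalar or a per-sample vector (e.g. to equalize
    library sizes to a target sample's total).  Accepts a CountMatrix or a
    DataFrame and returns the same type.
    """
    is_cm = isinstance(counts, CountMatrix)
    frame = counts.counts if is_cm else counts
    x = frame.to_numpy()
    frac = np.asarray(fraction, dtype=float)
    if frac.ndim == 0:
        frac = np.full(frame.shape[1], float(frac))
    if frac.size != frame.shape[1]:
        raise ValueError("fraction must be scalar or one value per sample")
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("fraction must lie in [0, 1]")
    rng = _as_rng(seed)
    thinned = rng.binomial(x, frac[None, :])
    out = pd.DataFrame(thinned, index=frame.index, columns=frame.columns)
    return CountMatrix(out, counts.group) if is_cm else out


def make_gene_sets(gene_ids, n_sets: int, seed=0) -> dict[str, list[str]]:
    """Randomly partition the genes into ``n_sets`` disjoint sets whose sizes
    differ by at most one; the union is exactly the input genes."""
    ids = np.asarray(list(gene_ids), dtype=object)
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if n_sets > ids.size:
        raise ValueError(f"n_sets={n_sets} exceeds the number of genes ({ids.size})")
    rng = _as_rng(seed)
    perm = rng.permutation(ids.size)
    chunks = np.array_split(ids[perm], n_sets)
    width = len(str(n_sets))
    return {f"set_{i + 1:0{width}d}": list(chunk) for i, chunk in enumerate(chunks)}
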