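"""Median-of-ratios (DESeq-style) size-factor normalization.

Each sample's size factor is the median, over reference genes, of the ratio
of its count to the gene's geometric mean across samples.  Reference genes
are those with a strictly positive count in every sample (the classic
all-positive rule; the geometric mean is computed in log space).  Dividing
each column by its factor puts all samples on a common count scale before
SNR scoring, dispersion estimation and GSEA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simdata import CountMatrix

__all__ = ["size_factors", "normalize_counts", "median_ratio_normalize"]


def _frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Raises if no gene has positive counts in all samples (no reference set).
    The median over an even number of reference genes is the arithmetic mean
    of the two central ratios.
    """
    frame = _frame(counts)
    x = frame.to_numpy(dtype=float)
    ref = (x > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no reference genes: every gene has a zero count in some sample; "
            "filter samples or use a dataset with consistently detected genes"
        )
    logs = np.log(x[ref])
    geo = np.exp(logs.mean(axis=1))
    ratios = x[ref] / geo[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=frame.columns, name="size_factor")


def normalize_counts(counts, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    frame = _frame(counts)
    f = np.asarray(factors, dtype=float)
    if f.size != frame.shape[1]:
        raise ValueError("need exactly one size factor per sample")
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("size factors must be positive and finite")
    return frame / f


def median_ratio_normalize(counts) -> tuple[pd.DataFrame, pd.Series]:
    """Convenience: estimate size factors and return normalized counts."""
    f = size_factors(counts)
    return normalize_counts(counts, f), f
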