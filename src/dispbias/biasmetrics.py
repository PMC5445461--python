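"""Quantifying read-count bias along the count axis.

Genes are sorted by mean normalized count and grouped into consecutive bins
of fixed size (1000 genes by default in the analyses).  Per bin the profile
records quantiles and spread of the SNR scores and, once differential calls
are supplied, the proportion of genes called DE.  A scalar trend statistic
-- the Spearman rank correlation between bin index and a per-bin channel --
summarizes whether significance concentrates at large counts (+1: bias
strictly increasing with count).  The Spearman trend is a stand-in summary:
the underlying bias is usually assessed visually, and outputs label it as
such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = ["BiasProfile", "TrendResult", "bin_genes", "de_proportion_per_bin", "bias_trend", "plot_profile"]

SNR_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass
class BiasProfile:
    """Per-bin summary table plus the gene -> bin assignment."""

    table: pd.DataFrame
    assignment: pd.Series  # gene_id -> 1-based bin index, ascending mean count

    @property
    def n_bins(self) -> int:
        return len(self.table)


class TrendResult(NamedTuple):
    value: float
    degenerate: bool  # True when the channel is constant across bins

    def __float__(self) -> float:
        return self.value


def bin_genes(snr: pd.Series, mean_counts: pd.Series, bin_size: int = 1000) -> BiasProfile:
    """Bin genes by ascending mean normalized count.

    Consecutive chunks of ``bin_size`` genes form the bins (the last bin may
    be smaller); ties in mean count are broken by gene identifier so the
    profile is deterministic.  SNR quantiles are computed over defined
    (non-missing) SNRs only.
    """
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    df = pd.DataFrame({"snr": snr, "mean_count": mean_counts})
    if df["mean_count"].isna().any():
        raise ValueError("mean_counts contains missing values")
    df = (
        df.assign(_gid=df.index.astype(str))
        .sort_values(["mean_count", "_gid"], kind="mergesort")
        .drop(columns="_gid")
    )
    n = len(df)
    if n < bin_size:
        warnings.warn(
            f"only {n} genes for bin_size={bin_size}; producing a single bin",
            stacklevel=2,
        )
    bins = np.arange(n) // bin_size + 1
    assignment = pd.Series(bins, index=df.index, name="bin_index")
    rows = []
    for b, chunk in df.groupby(bins):
        vals = chunk["snr"].dropna().to_numpy()
        qs = (
            np.quantile(vals, SNR_QUANTILES)
            if vals.size
            else np.full(len(SNR_QUANTILES), np.nan)
        )
        rows.append(
            {
                "bin_index": int(b),
                "n_genes": len(chunk),
                "count_low": float(chunk["mean_count"].iloc[0]),
                "count_high": float(chunk["mean_count"].iloc[-1]),
                **{f"snr_q{int(q * 100):02d}": v for q, v in zip(SNR_QUANTILES, qs)},
                "snr_spread": float(qs[3] - qs[1]) if vals.size else np.nan,
                "de_proportion": np.nan,
            }
        )
    return BiasProfile(pd.DataFrame(rows), assignment)


def de_proportion_per_bin(profile: BiasProfile, de_calls: pd.Series) -> BiasProfile:
    """Fill the per-bin fraction of genes called DE (e.g. fdr_q < 0.05)."""
    calls = pd.Series(de_calls)
    if not calls.index.equals(profile.assignment.index):
        try:
            calls = calls.loc[profile.assignment.index]
        except KeyError as exc:
            raise ValueError("de_calls must cover every binned gene") from exc
    prop = calls.astype(float).groupby(profile.assignment).mean()
    table = profile.table.copy()
    table["de_proportion"] = table["bin_index"].map(prop).to_numpy()
    return replace(profile, table=table)


def bias_trend(
    profile: BiasProfile, channel: str = "de_proportion", skip_first: int = 0
) -> TrendResult:
    """Spearman correlation of bin index against a per-bin channel.

    ``skip_first`` drops that many initial (lowest-count) bins, which is
    useful because large-dispersion data keep a local bias in the first
    bins (the sqrt(mu) branch of the SNR bound) even when the global trend
    is flat.  A constant channel yields 0 with the degenerate flag set.
    """
    if channel not in {"de_proportion", "snr_spread"}:
        raise ValueError("channel must be 'de_proportion' or 'snr_spread'")
    table = profile.table.iloc[skip_first:]
    if len(table) < 3:
        raise ValueError("need at least 3 bins (after skipping) for a trend")
    y = table[channel].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"channel {channel!r} has missing values; fill the profile first")
    if np.allclose(y, y[0]):
        return TrendResult(0.0, True)
    rho = spearmanr(table["bin_index"].to_numpy(), y).statistic
    return TrendResult(float(rho), False)


def plot_profile(profile: BiasProfile, path=None):
    """Two-panel figure: SNR quantile band per bin and DE proportion bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = profile.table
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    x = t["bin_index"]
    axes[0].fill_between(x, t["snr_q05"], t["snr_q95"], alpha=0.25, label="5-95%")
    axes[0].fill_between(x, t["snr_q25"], t["snr_q75"], alpha=0.45, label="25-75%")
    axes[0].plot(x, t["snr_q50"], color="k", lw=1, label="median")
    axes[0].set(xlabel="count bin (ascending mean count)", ylabel="SNR")
    axes[0].legend(frameon=False, fontsize=8)
    axes[1].bar(x, t["de_proportion"], color="#88aacc")
    axes[1].set(xlabel="count bin", ylabel="DE proportion", ylim=(0, 1))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
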