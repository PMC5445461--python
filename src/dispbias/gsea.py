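"""Weighted Kolmogorov-Smirnov gene-set enrichment with permutation nulls.

Two null models are provided for the same running-sum enrichment score
(hits increment by |score|^p / sum over the set, misses decrement by
1/(N - set size); the ES is the extreme signed deviation of the running
sum):

* sample-permuting: group labels are permuted, gene SNR scores recomputed
  for every relabeling, and each set rescored against the permuted
  rankings;
* preranked (gene-permuting): the ranking is fixed and the null draws
  random sets of matching size.

Normalized scores (NES) divide the ES by the mean |null ES| of matching
sign for that set; nominal p-values are one-sided against the matching-sign
null; FDR q-values follow the pooled-null NES-ratio procedure (fraction of
all sign-matched null NES at least as extreme over the fraction of observed
NES at least as extreme, capped at 1).

The false-positive experiment simulates two-group NB data in which DE genes
are chosen at random -- so no gene set is truly enriched -- and counts the
sets reaching FDR significance per dispersion level, per mode.  Everything
is vectorized so thousands of permutations across a hundred sets run in
seconds.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from . import estimators, normalize, simdata

__all__ = [
    "enrichment_score",
    "preranked_gsea",
    "sample_permute_gsea",
    "false_positive_experiment",
]

_NULL_CHUNK_ROWS = 4000  # permutation draws held in memory at once


def enrichment_score(ranked_scores, set_membership, weight_exponent: float = 1.0) -> float:
    """Running-sum ES of one set against a ranked score list (reference form).

    ``ranked_scores`` must already be in ranking order (descending score);
    ``set_membership`` is a boolean per position.  With weight_exponent 0
    this is the classical (unweighted) KS statistic.
    """
    s = np.asarray(ranked_scores, dtype=float)
    m = np.asarray(set_membership, dtype=bool)
    if s.shape != m.shape or s.ndim != 1:
        raise ValueError("scores and membership must be aligned 1-D arrays")
    k = int(m.sum())
    if k == 0 or k == s.size:
        raise ValueError("set must be non-empty and a strict subset of the ranking")
    w = np.abs(s) ** weight_exponent
    hit_w = np.where(m, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member scores zero: fall back to equal hit weights
        hit_w = m.astype(float)
        total = float(k)
    run = np.cumsum(np.where(m, hit_w / total, -1.0 / (s.size - k)))
    hi, lo = float(run.max()), float(run.min())
    # magnitude ties (possible on the unweighted lattice) resolve to the
    # positive peak, robustly to float accumulation order
    return hi if hi + lo >= -1e-9 * max(hi, -lo, 1e-300) else lo


def _es_from_positions(pos: np.ndarray, w: np.ndarray, n_ranked: int) -> np.ndarray:
    """Batch ES from sorted hit positions (..., k) and aligned hit weights."""
    k = pos.shape[-1]
    total = w.sum(axis=-1, keepdims=True)
    w = np.where(total > 0, w, 1.0)
    total = np.where(total > 0, total, float(k))
    cw = np.cumsum(w, axis=-1) / total
    miss = (pos - np.arange(k)) / (n_ranked - k)
    run_after = cw - miss  # running sum just after each hit
    run_before = cw - w / total - miss  # just before each hit
    es_pos = run_after.max(axis=-1)
    es_neg = run_before.min(axis=-1)
    tol = 1e-9 * np.maximum(np.maximum(es_pos, -es_neg), 1e-300)
    return np.where(es_pos + es_neg >= -tol, es_pos, es_neg)


def _sample_subsets(rng: np.random.Generator, n_draws: int, n: int, k: int) -> np.ndarray:
    """Uniform random k-subsets of range(n), sorted, one per row.

    Uses whole-row rejection sampling (exact) when collisions are rare;
    falls back to key-sorting for large k/n.
    """
    if k > n:
        raise ValueError("k must not exceed n")
    if k * k > n:  # rejection would be slow: partial sort of random keys
        out = np.empty((n_draws, k), dtype=np.int64)
        done = 0
        while done < n_draws:
            block = min(_NULL_CHUNK_ROWS, n_draws - done)
            keys = rng.random((block, n))
            part = keys.argpartition(k - 1, axis=1)[:, :k] if k < n else keys.argsort(axis=1)
            out[done : done + block] = np.sort(part, axis=1)
            done += block
        return out
    pos = rng.integers(0, n, (n_draws, k))
    pos.sort(axis=1)
    bad = (pos[:, 1:] == pos[:, :-1]).any(axis=1) if k > 1 else np.zeros(n_draws, bool)
    while bad.any():
        redraw = rng.integers(0, n, (int(bad.sum()), k))
        redraw.sort(axis=1)
        pos[bad] = redraw
        bad_new = (pos[:, 1:] == pos[:, :-1]).any(axis=1)
        bad = bad_new
    return pos


def _rank_scores(scores: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Descending-score order with ties broken by gene identifier; genes with
    missing scores are dropped (they carry no ranking information)."""
    s = pd.Series(scores).astype(float)
    n_missing = int(s.isna().sum())
    if n_missing:
        warnings.warn(f"dropping {n_missing} genes with undefined scores", stacklevel=3)
        s = s.dropna()
    df = pd.DataFrame({"score": s, "gid": s.index.astype(str)})
    df = df.sort_values(["score", "gid"], ascending=[False, True], kind="mergesort")
    return df["gid"].to_numpy(), df["score"].to_numpy()


def _resolve_sets(sets: dict, universe_ids: np.ndarray) -> dict[str, np.ndarray]:
    """Map sets to integer positions in the ranked universe; drop emptied sets."""
    pos_of = {g: i for i, g in enumerate(universe_ids)}
    resolved = {}
    for name, members in sets.items():
        idx = np.array(sorted({pos_of[g] for g in members if g in pos_of}), dtype=int)
        if idx.size == 0:
            warnings.warn(f"gene set {name!r} has no genes in the ranked universe; skipped")
            continue
        if idx.size == universe_ids.size:
            raise ValueError(f"gene set {name!r} equals the whole universe")
        resolved[name] = idx
    if not resolved:
        raise ValueError("no usable gene sets after filtering to the ranked universe")
    return resolved


def _summarize(names, es_obs: np.ndarray, es_null: np.ndarray, sizes) -> pd.DataFrame:
    """NES, nominal p and pooled-null FDR q from per-set null ES matrices."""
    m, n_perm = es_null.shape
    pos_mean = np.array(
        [es_null[i][es_null[i] > 0].mean() if (es_null[i] > 0).any() else np.nan for i in range(m)]
    )
    neg_mean = np.array(
        [-es_null[i][es_null[i] < 0].mean() if (es_null[i] < 0).any() else np.nan for i in range(m)]
    )
    pos_mean = np.where(np.isnan(pos_mean), np.nanmean(pos_mean) if np.isfinite(np.nanmean(pos_mean)) else 1.0, pos_mean)
    neg_mean = np.where(np.isnan(neg_mean), np.nanmean(neg_mean) if np.isfinite(np.nanmean(neg_mean)) else 1.0, neg_mean)

    nes_obs = np.where(es_obs >= 0, es_obs / pos_mean, es_obs / neg_mean)
    nes_null = np.where(es_null >= 0, es_null / pos_mean[:, None], es_null / neg_mean[:, None])

    p_nom = np.empty(m)
    for i in range(m):
        if es_obs[i] >= 0:
            same = es_null[i][es_null[i] >= 0]
            p_nom[i] = (same >= es_obs[i]).mean() if same.size else 1.0
        else:
            same = es_null[i][es_null[i] < 0]
            p_nom[i] = (same <= es_obs[i]).mean() if same.size else 1.0

    flat = nes_null.ravel()
    flat_pos = flat[flat >= 0]
    flat_neg = flat[flat < 0]
    obs_pos = nes_obs[nes_obs >= 0]
    obs_neg = nes_obs[nes_obs < 0]
    q = np.empty(m)
    for i in range(m):
        v = nes_obs[i]
        if v >= 0:
            top = (flat_pos >= v).mean() if flat_pos.size else 1.0
            bottom = (obs_pos >= v).mean()
        else:
            top = (flat_neg <= v).mean() if flat_neg.size else 1.0
            bottom = (obs_neg <= v).mean()
        q[i] = min(1.0, top / bottom) if bottom > 0 else 1.0

    return pd.DataFrame(
        {
            "set_name": names,
            "size": sizes,
            "es": es_obs,
            "nes": nes_obs,
            "p_nominal": p_nom,
            "fdr_q": q,
        }
    ).set_index("set_name")


def _observed_es(ranked_w: np.ndarray, idx_sets: dict, n_ranked: int) -> np.ndarray:
    out = np.empty(len(idx_sets))
    for i, idx in enumerate(idx_sets.values()):
        out[i] = _es_from_positions(idx[None, :], ranked_w[idx][None, :], n_ranked)[0]
    return out


def preranked_gsea(
    gene_scores: pd.Series,
    sets: dict,
    n_perm: int = 1000,
    seed=0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA: fixed ranking, null from random same-size gene sets.

    ``gene_scores`` is a per-gene score Series (index: gene ids); ``sets``
    maps set names to gene-id lists.  Returns one row per set with es, nes,
    p_nominal and fdr_q.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = simdata._as_rng(seed)
    ranked_ids, ranked_scores = _rank_scores(gene_scores)
    n = ranked_ids.size
    ranked_w = np.abs(ranked_scores) ** weight_exponent
    idx_sets = _resolve_sets(sets, ranked_ids)
    es_obs = _observed_es(ranked_w, idx_sets, n)

    # independent null draws per set
    sizes = np.array([idx.size for idx in idx_sets.values()])
    es_null = np.empty((len(idx_sets), n_perm))
    for i, k in enumerate(sizes):
        pos = _sample_subsets(rng, n_perm, n, int(k))
        es_null[i] = _es_from_positions(pos, ranked_w[pos], n)
    return _summarize(list(idx_sets), es_obs, es_null, sizes)


def _snr_matrix(x: np.ndarray, member1: np.ndarray) -> np.ndarray:
    """SNR per gene for each group-1 indicator column (genes x perms)."""
    n1 = member1[:, 0].sum()
    n2 = member1.shape[0] - n1
    sum1 = x @ member1
    sum2 = x.sum(axis=1, keepdims=True) - sum1
    sq1 = (x**2) @ member1
    sq2 = (x**2).sum(axis=1, keepdims=True) - sq1
    m1, m2 = sum1 / n1, sum2 / n2
    v1 = np.maximum(sq1 - n1 * m1**2, 0.0) / (n1 - 1)
    v2 = np.maximum(sq2 - n2 * m2**2, 0.0) / (n2 - 1)
    denom = np.sqrt(v1) + np.sqrt(v2)
    with np.errstate(invalid="ignore", divide="ignore"):
        snr = np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), 0.0)
    return snr


def sample_permute_gsea(
    norm_counts: pd.DataFrame,
    group,
    sets: dict,
    n_perm: int = 1000,
    seed=0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Sample-permuting GSEA with the SNR gene score.

    The observed ranking uses the true group labels; the null relabels
    samples (preserving group sizes), recomputes every gene's SNR and
    rescores each set against the permuted ranking.  If fewer distinct
    relabelings than ``n_perm`` exist they are enumerated exhaustively.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = simdata._as_rng(seed)
    _, mask1, _ = estimators._two_groups(norm_counts.columns, group)
    n_samples = norm_counts.shape[1]
    n1 = int(mask1.sum())

    snr_obs = estimators.snr_scores(norm_counts, group)["snr"]
    ranked_ids, ranked_scores = _rank_scores(snr_obs)
    n = ranked_ids.size
    ranked_w = np.abs(ranked_scores) ** weight_exponent
    idx_sets = _resolve_sets(sets, ranked_ids)
    es_obs = _observed_es(ranked_w, idx_sets, n)

    # genes ordered as in the ranking universe (sorted by observed rank)
    x = norm_counts.loc[ranked_ids].to_numpy(dtype=float)

    total = comb(n_samples, n1)
    if total <= n_perm:
        warnings.warn(
            f"only {total} distinct relabelings exist; using all of them "
            f"instead of {n_perm} random permutations"
        )
        subsets = list(combinations(range(n_samples), n1))
    else:
        subsets = [rng.choice(n_samples, size=n1, replace=False) for _ in range(n_perm)]
    member1 = np.zeros((n_samples, len(subsets)))
    for j, sub in enumerate(subsets):
        member1[list(sub), j] = 1.0

    snr_perm = _snr_matrix(x, member1)  # (genes, perms), NaN-free
    neg = -snr_perm
    order = np.argsort(neg, axis=0, kind="stable")  # ties -> gene-id order
    inv = np.empty_like(order)
    np.put_along_axis(inv, order, np.arange(n)[:, None], axis=0)

    es_null = np.empty((len(idx_sets), len(subsets)))
    w_all = np.abs(snr_perm) ** weight_exponent
    for i, idx in enumerate(idx_sets.values()):
        raw_pos = inv[idx, :].T  # (perms, k)
        ordidx = np.argsort(raw_pos, axis=1)
        pos = np.take_along_axis(raw_pos, ordidx, axis=1)
        w = np.take_along_axis(w_all[idx, :].T, ordidx, axis=1)
        es_null[i] = _es_from_positions(pos, w, n)
    sizes = np.array([idx.size for idx in idx_sets.values()])
    return _summarize(list(idx_sets), es_obs, es_null, sizes)


def false_positive_experiment(
    dispersions,
    de_fractions,
    modes=("sample", "preranked"),
    n_repeats: int = 10,
    fdr_threshold: float = 0.05,
    seed: int = 0,
    *,
    n_genes: int = 10_000,
    n_samples_per_group: tuple[int, int] = (10, 10),
    n_sets: int = 100,
    fold_change: float = 2.0,
    n_perm: int = 1000,
) -> pd.DataFrame:
    """Count falsely significant gene sets across a dispersion grid.

    For every (dispersion, de_fraction) cell and repeat: simulate NB counts
    with randomly chosen DE genes (half up, half down, fixed fold change),
    normalize, partition the genes into ``n_sets`` disjoint random sets, and
    run each requested GSEA mode on the same dataset.  Since DE genes are
    random, every set called significant (fdr_q < threshold) is a false
    positive.  Repeats use seeds root_seed + repeat so they are independent
    but reproducible.
    """
    modes = list(modes)
    for mode in modes:
        if mode not in {"sample", "preranked"}:
            raise ValueError(f"unknown GSEA mode {mode!r}")
    counts = {
        (d, f, mode): [] for d in dispersions for f in de_fractions for mode in modes
    }
    for r in range(n_repeats):
        for di, d in enumerate(dispersions):
            for fi, f in enumerate(de_fractions):
                cell_rng = np.random.default_rng([seed + r, di, fi])
                sim_seed, set_seed, samp_seed, pre_seed = cell_rng.integers(
                    2**31, size=4
                )
                cfg = simdata.SimConfig(
                    n_genes=n_genes,
                    n_samples_per_group=n_samples_per_group,
                    dispersion=float(d),
                    de_fraction=float(f),
                    fc_range=(fold_change, fold_change),
                    seed=int(sim_seed),
                )
                cm, _ = simdata.simulate_dataset(cfg)
                norm, _ = normalize.median_ratio_normalize(cm)
                sets = simdata.make_gene_sets(cm.gene_ids, n_sets, int(set_seed))
                for mode in modes:
                    if mode == "sample":
                        res = sample_permute_gsea(
                            norm, cm.group, sets, n_perm=n_perm, seed=int(samp_seed)
                        )
                    else:
                        snr = estimators.snr_scores(norm, cm.group)["snr"]
                        res = preranked_gsea(
                            snr, sets, n_perm=n_perm, seed=int(pre_seed)
                        )
                    counts[(d, f, mode)].append(int((res["fdr_q"] < fdr_threshold).sum()))
    rows = []
    for (d, f, mode), vals in counts.items():
        arr = np.asarray(vals, dtype=float)
        rows.append(
            {
                "dispersion": d,
                "de_fraction": f,
                "mode": mode,
                "mean_significant": arr.mean(),
                "sd_significant": arr.std(ddof=1) if arr.size > 1 else 0.0,
                "n_repeats": arr.size,
            }
        )
    return pd.DataFrame(rows)
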