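"""Per-gene SNR / T / naive NB LRT scores and dispersion estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dispbias as db
from dispbias import theory


def _frame(g1_rows, g2_rows, index=None):
    """Build a genes x samples frame from per-group row lists."""
    data = np.column_stack([np.asarray(g1_rows, float), np.asarray(g2_rows, float)])
    n1 = np.asarray(g1_rows).shape[1]
    n2 = np.asarray(g2_rows).shape[1]
    cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    frame = pd.DataFrame(data, columns=cols, index=index)
    group = pd.Series(["A"] * n1 + ["B"] * n2, index=cols)
    return frame, group


class TestSnr:
    def test_hand_example(self):
        frame, group = _frame([[1, 2, 3]], [[4, 5, 6]])
        s = db.snr_scores(frame, group)
        assert s.loc[0, "mean_g1"] == 2 and s.loc[0, "mean_g2"] == 5
        assert s.loc[0, "sd_g1"] == 1 and s.loc[0, "sd_g2"] == 1
        assert s.loc[0, "snr"] == pytest.approx(-1.5)

    def test_equal_groups_zero(self):
        frame, group = _frame([[1, 2, 3]], [[1, 2, 3]])
        assert db.snr_scores(frame, group).loc[0, "snr"] == 0.0

    def test_constant_gene_undefined(self):
        frame, group = _frame([[5, 5, 5]], [[5, 5, 5]])
        assert np.isnan(db.snr_scores(frame, group).loc[0, "snr"])

    def test_sd_floor_defines_constant_contrast(self):
        frame, group = _frame([[5, 5, 5]], [[10, 10, 10]])
        assert np.isnan(db.snr_scores(frame, group).loc[0, "snr"])
        floored = db.snr_scores(frame, group, sd_floor=True)
        assert floored.loc[0, "snr"] == pytest.approx(-5 / (1.0 + 2.0))

    def test_group_swap_antisymmetry_and_scaling_invariance(self):
        rng = np.random.default_rng(0)
        frame, group = _frame(rng.poisson(50, (20, 4)), rng.poisson(80, (20, 3)))
        s = db.snr_scores(frame, group)["snr"]
        rev = list(frame.columns[4:]) + list(frame.columns[:4])  # B first
        swapped = db.snr_scores(frame[rev], group[rev])["snr"]
        assert np.allclose(s, -swapped, equal_nan=True)
        scaled = db.snr_scores(frame * 7.3, group)["snr"]
        assert np.allclose(s, scaled, equal_nan=True)

    def test_small_group_rejected(self):
        frame, group = _frame([[1, 2]], [[3]])
        with pytest.raises(ValueError):
            db.snr_scores(frame, group)

    def test_snr_respects_theory_bound_at_large_replicates(self):
        # sample SNR from 1000 replicates/group stays within the population
        # bound min(1/sqrt(alpha), sqrt(mu1)) up to sampling slack
        for mu, fold, alpha in [(100, 2, 0.1), (50, 4, 0.3), (200, 1.5, 0.01)]:
            truth = pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(200)],
                    "base_mean": np.full(200, float(mu) * fold),
                    "fold_change": np.full(200, float(fold)),
                    "direction": ["down"] * 200,  # group2 = mu, group1 = mu*fold
                    "is_de": [True] * 200,
                    "dispersion": np.full(200, alpha),
                }
            )
            cm = db.simulate_counts(truth, (1000, 1000), seed=7)
            s = db.snr_scores(cm.counts.astype(float), cm.group)["snr"]
            bound = theory.snr_upper_bound(mu * fold, alpha)
            assert np.abs(s).max() <= bound * 1.10


class TestWelchT:
    def test_hand_example(self):
        frame, group = _frame([[1, 2, 3]], [[4, 5, 6]])
        t = db.t_scores(frame, group).loc[0, "t_stat"]
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-12)  # ~ -3.674

    def test_equal_groups_zero_and_scaling_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(40, (10, 5)).astype(float)
        frame, group = _frame(x, x[:, :4] + rng.poisson(5, (10, 4)))
        t = db.t_scores(frame, group)["t_stat"]
        t_scaled = db.t_scores(frame * 11.0, group)["t_stat"]
        assert np.allclose(t, t_scaled, equal_nan=True)
        same, g2 = _frame([[1, 2, 3]], [[1, 2, 3]])
        assert db.t_scores(same, g2).loc[0, "t_stat"] == 0.0


class TestDispersionMoment:
    def test_formula_evaluation(self):
        # both groups with sample mean 10, variance 30 -> (30-10)/100 = 0.2
        s = np.sqrt(30.0)
        row = [10 - s, 10.0, 10 + s]
        frame, group = _frame([row], [row])
        est = db.dispersion_mom(frame, group)
        assert est.loc[0, "alpha_mom"] == pytest.approx(0.2, rel=1e-12)

    def test_underdispersion_clamped_to_zero(self):
        frame, group = _frame([[10, 10, 11]], [[10, 11, 10]])
        assert db.dispersion_mom(frame, group).loc[0, "alpha_mom"] == 0.0

    def test_all_zero_gene_missing(self):
        frame, group = _frame([[0, 0, 0]], [[0, 0, 0]])
        assert np.isnan(db.dispersion_mom(frame, group).loc[0, "alpha_mom"])

    def test_monte_carlo_recovery(self):
        cm, _ = db.simulate_dataset(
            db.SimConfig(n_genes=10_000, n_samples_per_group=(50, 50), dispersion=0.1,
                         de_fraction=0.0, seed=13)
        )
        est = db.dispersion_mom(cm.counts, cm.group)
        assert 0.085 < est["alpha_mom"].median() < 0.115


class TestDispersionMle:
    def test_poisson_data_hits_lower_bound(self):
        cm, _ = db.simulate_dataset(
            db.SimConfig(n_genes=2000, n_samples_per_group=(10, 10), dispersion=0.0,
                         de_fraction=0.0, seed=19)
        )
        est = db.dispersion_mle(cm.counts, cm.group)
        assert (est["alpha_mle"] < 1e-3).mean() >= 0.90

    def test_recovery_at_moderate_dispersion(self):
        cm, _ = db.simulate_dataset(
            db.SimConfig(n_genes=3000, n_samples_per_group=(10, 10), dispersion=0.3,
                         de_fraction=0.0, seed=19)
        )
        est = db.dispersion_mle(cm.counts, cm.group)
        assert abs(est["alpha_mle"].median() - 0.3) / 0.3 < 0.2

    def test_single_sample_group_rejected(self):
        frame, _ = _frame([[1, 2]], [[3, 4]])
        group = pd.Series(["A", "A", "A", "B"], index=frame.columns)
        with pytest.raises(ValueError):
            db.dispersion_mle(frame, group)

    def test_estimates_nonnegative(self, small_dataset):
        cm, _ = small_dataset
        est = db.dispersion_mle(cm.counts, cm.group)
        assert (est["alpha_mle"].dropna() >= 0).all()


class TestNbLrt:
    def test_identical_groups_null_statistic(self):
        frame, group = _frame([[3, 9, 5, 7]], [[3, 9, 5, 7]])
        res = db.nb_lrt(frame.astype(int), group)
        assert res.loc[0, "lrt_stat"] == pytest.approx(0.0, abs=1e-6)
        assert res.loc[0, "p_value"] == pytest.approx(1.0, abs=1e-3)

    def test_all_zero_gene(self):
        frame, group = _frame([[0, 0, 0], [5, 6, 7]], [[0, 0, 0], [9, 8, 7]])
        res = db.nb_lrt(frame.astype(int), group)
        assert res.iloc[0]["lrt_stat"] == 0.0 and res.iloc[0]["p_value"] == 1.0

    def test_agrees_with_poisson_glm_oracle_at_zero_dispersion(self):
        # on Poisson-simulated null genes whose fitted dispersion sits at the
        # lower bound, the NB LRT reduces to the Poisson GLM likelihood ratio
        import statsmodels.api as sm

        cm, _ = db.simulate_dataset(
            db.SimConfig(n_genes=500, n_samples_per_group=(5, 5), dispersion=0.0,
                         de_fraction=0.0, seed=37)
        )
        res = db.nb_lrt(cm.counts, cm.group)
        x = cm.counts.to_numpy(dtype=float)
        design = np.column_stack([np.ones(10), np.r_[np.zeros(5), np.ones(5)]])
        oracle = np.empty(len(x))
        for i, y in enumerate(x):
            full = sm.GLM(y, design, family=sm.families.Poisson()).fit()
            null = sm.GLM(y, design[:, :1], family=sm.families.Poisson()).fit()
            oracle[i] = 2 * (full.llf - null.llf)
        at_bound = res["dispersion_mle"].to_numpy() < 1e-6
        assert at_bound.sum() > 200
        assert np.corrcoef(res["lrt_stat"][at_bound], oracle[at_bound])[0, 1] > 0.99

    def test_power_concentrates_on_true_de_genes(self):
        cm, truth = db.simulate_dataset(
            db.SimConfig(n_genes=3000, n_samples_per_group=(7, 7), dispersion=0.01,
                         de_fraction=0.3, fc_range=(4.0, 4.0), seed=41)
        )
        norm, f = db.median_ratio_normalize(cm)
        res = db.nb_lrt(cm.counts, cm.group, f.to_numpy())
        sig = res["fdr_q"] < 0.05
        de = truth.set_index("gene_id")["is_de"]
        assert sig[de].mean() > sig[~de].mean()
        assert sig[de].mean() > 0.5


class TestBhFdr:
    def test_step_up_hand_example(self):
        q = db.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_degenerate_inputs(self):
        assert db.bh_fdr([0.123]) == pytest.approx([0.123])
        assert np.allclose(db.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            db.bh_fdr([0.5, 1.5])

    def test_nan_propagates_without_affecting_others(self):
        q = db.bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], db.bh_fdr([0.01, 0.04]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_qvalues_bounded_and_monotone_in_p_rank(self, pvals):
        q = db.bh_fdr(pvals)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
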