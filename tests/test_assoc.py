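"""Trend tests, interaction and stratified-effect analyses, regression planes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protmed.assoc import (
    cochran_armitage,
    interaction_model,
    quartile_table,
    regression_plane,
    spearman_trend,
    stratified_effect,
)
from protmed.data_model import assign_quartiles
from protmed.simulate import SimulationConfig, simulate_trial
from oracles import score_test_oracle


class TestSpearmanTrend:
    def test_monotone_values_rho_one(self):
        q = pd.Series([1] * 5 + [2] * 5 + [3] * 5 + [4] * 5)
        values = 10.0 * q  # monotone with the same tie structure
        res = spearman_trend(values, q)
        assert res.statistic == pytest.approx(1.0)
        # strictly increasing values: near-perfect, highly significant trend
        res2 = spearman_trend(pd.Series(np.arange(20, dtype=float)), q)
        assert res2.statistic > 0.9 and res2.p < 1e-6

    def test_reversed_order_flips_sign(self, rng):
        q = pd.Series(rng.integers(1, 5, 200))
        values = pd.Series(rng.normal(size=200) + 0.3 * q)
        r1 = spearman_trend(values, q)
        r2 = spearman_trend(values, 5 - q)
        assert r2.statistic == pytest.approx(-r1.statistic)

    def test_null_p_uniform(self):
        ps = []
        for seed in range(500):
            g = np.random.default_rng(seed)
            q = pd.Series(np.repeat([1, 2, 3, 4], 25))
            values = pd.Series(g.normal(size=100))
            ps.append(spearman_trend(values, q).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_input_flagged(self):
        q = pd.Series(np.repeat([1, 2, 3, 4], 5))
        res = spearman_trend(pd.Series(np.ones(20)), q)
        assert res.flagged == "constant input"


class TestCochranArmitage:
    def test_equal_proportions_z_zero(self):
        res = cochran_armitage([[10, 10, 10, 10], [30, 30, 30, 30]])
        assert res.statistic == pytest.approx(0.0)

    def test_matches_score_test_oracle(self):
        """Trend p agrees with the brute-force score-test oracle to 2 s.f."""
        tables = [
            [[10, 20, 30, 40], [40, 30, 20, 10]],
            [[3, 5, 8], [12, 12, 12]],
            [[2, 4, 5, 7], [10, 10, 10, 10]],
            [[6, 5, 9, 10], [15, 15, 15, 15]],
        ]
        for tab in tables:
            scores = list(range(1, len(tab[0]) + 1))
            ours = cochran_armitage(tab).p
            oracle = score_test_oracle(tab, scores)
            assert ours == pytest.approx(oracle, rel=0.01)

    def test_random_tables_match_oracle(self):
        g = np.random.default_rng(15)
        for _ in range(50):
            k = int(g.integers(3, 6))
            nj = g.integers(8, 30, k)
            x = np.array([g.integers(1, n) for n in nj])
            tab = [x, nj - x]
            ours = cochran_armitage(tab).p
            oracle = score_test_oracle(tab, np.arange(1, k + 1))
            assert ours == pytest.approx(oracle, rel=0.01)

    def test_reversed_scores_flip_sign(self):
        tab = [[10, 20, 30, 40], [40, 30, 20, 10]]
        r1 = cochran_armitage(tab, scores=[1, 2, 3, 4])
        r2 = cochran_armitage(tab, scores=[4, 3, 2, 1])
        assert r2.statistic == pytest.approx(-r1.statistic)

    def test_count_scaling_direction(self):
        """Multiplying all counts by m scales Z by sqrt(m); p decreases."""
        tab = np.array([[6, 8, 10, 12], [12, 10, 8, 6]])
        r1 = cochran_armitage(tab)
        r4 = cochran_armitage(4 * tab)
        assert r4.statistic == pytest.approx(2 * r1.statistic, rel=1e-9)
        assert r4.p < r1.p

    def test_null_p_uniform(self):
        ps = []
        for seed in range(500):
            g = np.random.default_rng(1000 + seed)
            x = g.binomial(60, 0.4, 4)
            ps.append(cochran_armitage([x, 60 - x]).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_column_dropped(self):
        res = cochran_armitage([[5, 0, 10], [10, 0, 5]])
        full = cochran_armitage([[5, 10], [10, 5]])
        assert res.statistic == pytest.approx(full.statistic)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cochran_armitage([[1, 2]])
        with pytest.raises(ValueError):
            cochran_armitage([[1.5, 2], [3, 4]])


class TestInteractionAndStratified:
    def test_interaction_recovery(self):
        """A planted treatment x protein interaction is recovered within 3 SE."""
        g = np.random.default_rng(2)
        n = 500
        cfg = SimulationConfig(n_subjects=n, n_proteins=4,
                               mediators={"P001": (0.3, -0.05)},
                               direct_effect=-0.05, seed=40)
        ds, _ = simulate_trial(cfg)
        # inject a known interaction on the outcome fold-change
        pfc = ds.fold_change("P001", "v1")
        fc = ds.fold_change("picp", "v1") + 0.4 * ds.arm * (pfc - pfc.mean())
        ds.table["picp__v1"] = ds.value("picp", "baseline") * fc
        est, p, fit = interaction_model(ds, "P001", "v1")
        assert est == pytest.approx(0.4, abs=3 * fit.bse["arm:pfc"])
        assert p < 0.05

    def test_single_arm_refused(self, small_dataset):
        ds = small_dataset.subset(small_dataset.subject_ids)
        ds.table["arm"] = 1
        with pytest.raises(ValueError, match="constant"):
            interaction_model(ds, "P001", "v1")

    def test_stratified_median_split_sizes(self, small_dataset):
        res = stratified_effect(small_dataset, "P001", "v1")
        assert res.below["n"] + res.above["n"] == small_dataset.n_subjects
        assert abs(res.below["n"] - res.above["n"]) <= 1
        for stratum in (res.below, res.above):
            assert "effect" in stratum
            lo, hi = stratum["ci"]
            assert lo <= stratum["effect"] <= hi

    def test_effect_only_above_median(self):
        """Treatment moves the outcome only in the high-baseline stratum."""
        hits = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            cfg = SimulationConfig(n_subjects=600, n_proteins=4,
                                   mediators={"P001": (0.0, 0.0)},
                                   direct_effect=0.0, seed=seed)
            ds, _ = simulate_trial(cfg)
            base = ds.value("P001", "baseline")
            high = (base > base.median()).astype(float)
            fc = ds.fold_change("picp", "v1") * np.exp(-0.15 * ds.arm * high)
            ds.table["picp__v1"] = ds.value("picp", "baseline") * fc
            res = stratified_effect(ds, "P001", "v1", scale="log")
            lo_b, hi_b = res.below["ci"]
            lo_a, hi_a = res.above["ci"]
            if lo_b < 0 < hi_b and hi_a < 0:
                hits += 1
        assert hits >= 8


class TestRegressionPlane:
    def test_exact_linear_form(self, rng):
        n = 200
        fca = pd.Series(rng.normal(1, 0.2, n))
        fcb = pd.Series(rng.normal(1, 0.2, n))
        baselines = pd.DataFrame({"b1": rng.normal(size=n)})
        y = 0.5 * fca - 0.5 * fcb
        fit, grid = regression_plane(y, fca, fcb, baselines)
        assert fit.params["fc_a"] == pytest.approx(0.5, abs=1e-8)
        assert fit.params["fc_b"] == pytest.approx(-0.5, abs=1e-8)
        assert fit.rsquared == pytest.approx(1.0)
        # grid corners equal the linear form with baselines at their means
        corner = grid.iloc[0]
        expected = (fit.params["const"] + 0.5 * corner["fc_a"] - 0.5 * corner["fc_b"]
                    + fit.params["b1"] * baselines["b1"].mean())
        assert corner["predicted"] == pytest.approx(expected)

    def test_recovery_on_generator(self, small_dataset):
        ds = small_dataset
        y = ds.fold_change("picp", "v1")
        fca = ds.fold_change("P001", "v1")
        fcb = ds.fold_change("P003", "v1")
        baselines = pd.DataFrame({
            "picp_bl": ds.value("picp", "baseline"),
            "a_bl": ds.value("P001", "baseline"),
            "b_bl": ds.value("P003", "baseline"),
        })
        fit, _ = regression_plane(y, fca, fcb, baselines)
        # mediator fold-changes predict the outcome fold-change
        assert fit.f_pvalue < 0.01


def test_quartile_table_structure(small_dataset):
    tab = quartile_table(small_dataset, "v1", ["age", "bmi"], ["sex", "diabetes"])
    assert set(tab.index) == {"age", "bmi", "sex", "diabetes"}
    assert {"Q1", "Q2", "Q3", "Q4", "p_trend", "p_bh"} <= set(tab.columns)
    assert tab["p_trend"].dropna().between(0, 1).all()
    q = assign_quartiles(small_dataset.fold_change("picp", "v1"))
    assert sum(q.sizes) == small_dataset.n_subjects
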