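"""Signature score, mediation decomposition, screening and LOO losses."""

import numpy as np
import pandas as pd
import pytest

from protmed.mediation import (
    build_signature_score,
    counterfactual_acme,
    loo_proportion_loss,
    mediate,
    mediation_analysis,
    mediation_inputs,
    screen_candidates,
    total_effect_regression,
)
from protmed.simulate import SimulationConfig, simulate_trial


class TestSignatureScore:
    def test_single_candidate_affine(self, rng):
        fc = pd.DataFrame({"m1": rng.normal(1, 0.2, 100)})
        y = pd.Series(rng.normal(size=100))
        sig = build_signature_score(fc, y)
        a, b = sig.weights["intercept"], sig.weights["m1"]
        assert np.allclose(sig.score, a + b * fc["m1"])

    def test_orthogonal_candidates_univariate_slopes(self):
        g = np.random.default_rng(5)
        # columns orthogonal to each other AND to the intercept
        raw = np.column_stack([np.ones(120), g.normal(size=(120, 3))])
        q, _ = np.linalg.qr(raw)
        fc = pd.DataFrame(q[:, 1:], columns=["m1", "m2", "m3"])
        y = pd.Series(g.normal(size=120))
        sig = build_signature_score(fc, y)
        for c in fc.columns:
            uni = np.sum(fc[c] * (y - y.mean())) / np.sum(fc[c] ** 2)
            assert sig.weights[c] == pytest.approx(uni, rel=1e-6)

    def test_score_r2_equals_regression_r2(self, rng):
        fc = pd.DataFrame(rng.normal(size=(150, 4)), columns=list("abcd"))
        y = pd.Series(fc["a"] - fc["b"] + rng.normal(0, 1, 150))
        sig = build_signature_score(fc, y)
        ss_res = np.sum((y - sig.score) ** 2)
        r2_score_def = 1 - ss_res / np.sum((y - y.mean()) ** 2)
        r_corr = np.corrcoef(sig.score, y)[0, 1] ** 2
        assert r2_score_def == pytest.approx(r_corr, rel=1e-8)

    def test_collinear_column_dropped(self, rng):
        fc = pd.DataFrame(rng.normal(size=(80, 2)), columns=["m1", "m2"])
        fc["m3"] = fc["m1"] + fc["m2"]
        y = pd.Series(rng.normal(size=80))
        sig = build_signature_score(fc, y)
        assert sig.dropped == ["m3"]

    def test_p_ge_n_refused(self, rng):
        fc = pd.DataFrame(rng.normal(size=(5, 6)))
        with pytest.raises(ValueError, match="p=6"):
            build_signature_score(fc, pd.Series(rng.normal(size=5)))


class TestMediate:
    @pytest.fixture(scope="class")
    def fitted(self):
        cfg = SimulationConfig(
            n_subjects=600, n_proteins=4, mediators={"P001": (0.5, 0.6)},
            direct_effect=0.3, seed=31,
        )
        ds, truth = simulate_trial(cfg)
        fc, arm, y, cov = mediation_inputs(ds, ["P001"], "v1", scale="log")
        sig = build_signature_score(fc, y)
        return arm, sig.score, y, cov, truth

    def test_decomposition_identity(self, fitted):
        arm, score, y, cov, _ = fitted
        res = mediate(arm, score, y, covariates=cov, n_boot=50, seed=1)
        assert res.te == pytest.approx(res.acme + res.ade, abs=1e-10)

    def test_te_equals_total_effect_regression(self, fitted):
        arm, score, y, cov, _ = fitted
        res = mediate(arm, score, y, covariates=cov, n_boot=0)
        assert res.te == pytest.approx(
            total_effect_regression(arm, y, cov), abs=1e-10
        )

    def test_acme_equals_counterfactual_prediction(self, fitted):
        arm, score, y, cov, _ = fitted
        res = mediate(arm, score, y, covariates=cov, n_boot=0)
        assert res.acme == pytest.approx(
            counterfactual_acme(arm, score, y, cov), abs=1e-12
        )

    def test_cis_contain_point_estimates(self, fitted):
        arm, score, y, cov, _ = fitted
        res = mediate(arm, score, y, covariates=cov, n_boot=200, seed=2)
        for name, value in [("acme", res.acme), ("ade", res.ade), ("te", res.te)]:
            lo, hi = res.ci[name]
            assert lo <= value <= hi

    def test_seed_fixes_bootstrap(self, fitted):
        arm, score, y, cov, _ = fitted
        r1 = mediate(arm, score, y, covariates=cov, n_boot=100, seed=9)
        r2 = mediate(arm, score, y, covariates=cov, n_boot=100, seed=9)
        assert r1.ci == r2.ci

    def test_null_mediator_acme_coverage(self):
        """Outcome generated independent of the mediator: the 95% ACME CI
        covers 0 at close to the nominal rate across seeds."""
        covered = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            n = 800
            arm = g.integers(0, 2, n).astype(float)
            score = 0.5 * arm + g.normal(0, 1, n)
            y = 0.3 * arm + g.normal(0, 1, n)  # beta2 = 0 by construction
            res = mediate(arm, score, y, n_boot=200, seed=seed)
            lo, hi = res.ci["acme"]
            covered += lo < 0 < hi
            assert abs(res.acme) < 0.15
        assert covered >= 17

    def test_nonbinary_treatment_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            mediate(rng.normal(size=50), rng.normal(size=50), rng.normal(size=50),
                    n_boot=0)


class TestScreening:
    def test_planted_mediator_selected_noise_not(self):
        cfg = SimulationConfig(
            n_subjects=500, n_proteins=8, mediators={"P001": (0.5, -0.05)},
            direct_effect=-0.05, seed=21,
        )
        ds, _ = simulate_trial(cfg)
        screen = screen_candidates(ds, ["P001", "P006", "P007"], alpha=0.05)
        assert bool(screen.loc["P001", "selected"])
        assert screen.loc["P001", "reason"].startswith("effect")

    def test_type_i_rate_near_alpha(self):
        """Across many noise proteins, criterion-1 selection rate ~ alpha."""
        cfg = SimulationConfig(
            n_subjects=300, n_proteins=60, mediators={"P001": (0.5, -0.05)},
            direct_effect=-0.05, seed=77,
        )
        ds, _ = simulate_trial(cfg)
        noise = [p for p in ds.schema.proteins if p != "P001"]
        screen = screen_candidates(ds, noise, alpha=0.05)
        rate = (screen["arm_p"] < 0.05).mean()
        assert rate < 0.15

    def test_zero_variance_protein_skipped(self, small_dataset):
        ds = small_dataset.subset(small_dataset.subject_ids)
        for v in ds.schema.visits:
            ds.table[f"P009__{v}"] = 5.0
        screen = screen_candidates(ds, ["P009"])
        assert bool(screen.loc["P009", "skipped"])


class TestLOO:
    def test_null_mediator_loss_near_zero_and_ranking(self):
        cfg = SimulationConfig(
            n_subjects=800, n_proteins=6,
            mediators={"P001": (0.5, 0.6), "P002": (0.4, 0.3), "P003": (0.0, 0.0)},
            direct_effect=0.3, seed=13,
        )
        ds, _ = simulate_trial(cfg)
        fc, arm, y, cov = mediation_inputs(ds, ["P001", "P002", "P003"], "v1",
                                           scale="log")
        loo = loo_proportion_loss(fc, arm, y, covariates=cov, n_boot=150, seed=4)
        # largest a*b product attains the top loss; null mediator CI covers 0
        assert loo.index[0] == "P001"
        assert loo.loc["P003", "ci_lo"] < 0 < loo.loc["P003", "ci_hi"]
        assert abs(loo.loc["P003", "loss"]) < 0.1

    def test_duplicated_mediator_loss_compensated(self):
        """Twin mediators: removing one is compensated by the other."""
        g = np.random.default_rng(6)
        n = 600
        arm = g.integers(0, 2, n).astype(float)
        m = 0.5 * arm + g.normal(0, 0.5, n)
        y = 0.3 * arm + 0.6 * m + g.normal(0, 0.5, n)
        fc = pd.DataFrame({"m1": m, "m2": m + g.normal(0, 1e-6, n), "m3": g.normal(size=n)})
        loo = loo_proportion_loss(fc, arm, pd.Series(y), n_boot=0)
        assert abs(loo.loc["m1", "loss"]) < 0.05
        assert abs(loo.loc["m2", "loss"]) < 0.05

    def test_requires_two_mediators(self, rng):
        fc = pd.DataFrame({"m1": rng.normal(size=30)})
        with pytest.raises(ValueError):
            loo_proportion_loss(fc, np.zeros(30), rng.normal(size=30), n_boot=0)


def test_mediation_analysis_end_to_end(small_dataset):
    sig, res = mediation_analysis(
        small_dataset, ["P001", "P002"], "v1", scale="log", n_boot=50, seed=0
    )
    assert np.isfinite(res.acme) and res.n_boot == 50
    assert set(sig.weights.index) == {"intercept", "P001", "P002"}
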