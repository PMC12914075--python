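"""Subject-specific biomarker slopes and slope-on-slope regression.

Each biomarker's three-visit trajectory is fitted with a linear
mixed-effects model (random intercept and random slope for time, REML);
the subject-specific slope is the fixed time slope plus the subject's best
linear unbiased predictor (BLUP). Outcome slopes are then regressed on two
protein slopes with covariate adjustment, a joint (omnibus) F-test for the
two protein-slope terms, and an always-computed robust (M-estimation)
refit with a divergence flag. Time is coded in months; slopes are
per-month.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from protmed.data_model import TrialDataset

log = logging.getLogger(__name__)


def _per_subject_ols(df: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-subject OLS slope and its sampling variance (NaN when <3 points)."""
    slopes, variances = {}, {}
    for sid, g in df.groupby("subject", sort=False):
        t = g["time"].to_numpy(float)
        v = g["value"].to_numpy(float)
        ok = np.isfinite(t) & np.isfinite(v)
        t, v = t[ok], v[ok]
        if len(t) < 2 or np.ptp(t) == 0:
            continue
        tc = t - t.mean()
        sxx = (tc ** 2).sum()
        b = (tc * v).sum() / sxx
        slopes[sid] = b
        if len(t) > 2:
            resid = v - v.mean() - b * tc
            variances[sid] = float((resid ** 2).sum() / (len(t) - 2) / sxx)
    return pd.Series(slopes), pd.Series(variances)


def _two_stage_slopes(df: pd.DataFrame) -> pd.Series:
    """Empirical-Bayes shrinkage of per-subject OLS slopes (fallback fit)."""
    b, v = _per_subject_ols(df)
    mu = b.mean()
    tau2 = max(b.var(ddof=1) - (v.mean() if len(v) else 0.0), 0.0)
    lam = tau2 / (tau2 + v.reindex(b.index).fillna(v.mean() if len(v) else 0.0))
    lam = lam.fillna(1.0)
    return mu + lam * (b - mu)


def fit_random_slopes(
    long: pd.DataFrame,
    subject: str = "subject",
    time: str = "time",
    value: str = "value",
    method: str = "auto",
) -> pd.Series:
    """Predicted subject-specific slopes from a random-intercept/slope model.

    ``long`` holds one row per subject-visit. ``method`` is ``"auto"``
    (REML mixed model, independent-random-effects then two-stage fallback
    on failure) or ``"two_stage"``. Returns slopes (units/month) indexed by
    subject.
    """
    df = long.rename(columns={subject: "subject", time: "time", value: "value"})
    df = df.dropna(subset=["time", "value"])
    if df["subject"].nunique() < 20:
        raise ValueError("need at least 20 subjects")
    if method == "two_stage":
        return _two_stage_slopes(df)

    for re_formula in ("~time", "0 + time"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM.from_formula(
                    "value ~ time", df, groups=df["subject"],
                    re_formula="~time" if re_formula == "~time" else "~0 + time",
                )
                fit = model.fit(reml=True)
            fe = float(fit.params["time"])
            re = fit.random_effects
            slopes = pd.Series(
                {sid: fe + float(eff.get("time", 0.0)) for sid, eff in re.items()}
            )
            if slopes.notna().all() and np.isfinite(slopes).all():
                if re_formula != "~time":
                    log.warning("random-effects covariance singular; used independent slopes")
                return slopes
        except Exception as exc:  # noqa: BLE001 - any solver failure falls through
            log.warning("mixed model failed (%s); trying fallback", exc)
    log.warning("mixed model unusable; falling back to two-stage shrinkage")
    return _two_stage_slopes(df)


def dataset_long(dataset: TrialDataset, biomarker: str) -> pd.DataFrame:
    """Long-format (subject, time, value) records for one biomarker."""
    s = dataset.schema
    frames = []
    for v in s.visits:
        col = s.column(biomarker, v)
        if col not in dataset.table.columns:
            continue
        frames.append(pd.DataFrame({
            "subject": dataset.subject_ids,
            "time": s.visit_times[v],
            "value": dataset.table[col].to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


def slope_table(dataset: TrialDataset, biomarkers: list[str], method: str = "auto") -> pd.DataFrame:
    """Subject x biomarker table of predicted random slopes (per month)."""
    out = {}
    for b in biomarkers:
        out[b] = fit_random_slopes(dataset_long(dataset, b), method=method)
    return pd.DataFrame(out)


@dataclass
class SlopeRegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    omnibus_f: float
    omnibus_p: float
    robust_params: pd.Series | None
    robust_diverged: bool
    grid: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)
    n: int = 0


def robust_refit(X: pd.DataFrame, y: pd.Series) -> pd.Series | None:
    """M-estimation refit (Huber loss); ``None`` on non-convergence."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rfit = sm.RLM(y, sm.add_constant(X), M=sm.robust.norms.HuberT()).fit()
        return rfit.params
    except Exception as exc:  # noqa: BLE001
        log.warning("robust refit failed: %s", exc)
        return None


def regress_slopes(
    outcome_slopes: pd.Series,
    slope_a: pd.Series,
    slope_b: pd.Series,
    covariates: pd.DataFrame | None = None,
    grid_size: int = 20,
) -> SlopeRegressionResult:
    """OLS of an outcome slope on two protein slopes with adjustment.

    Adjusts for the supplied covariates (age, sex, arm, eGFR by
    convention); reports the joint F-test for the two protein-slope
    coefficients, a robust refit with a divergence flag (flagged when any
    protein-slope coefficient moves by more than one OLS standard error),
    a prediction grid with covariates held at their sample means, and
    model-adequacy diagnostics.
    """
    d = pd.DataFrame({"y": outcome_slopes, "slope_a": slope_a, "slope_b": slope_b})
    if covariates is not None:
        d = d.join(covariates)
    d = d.dropna()
    y = d.pop("y")
    X = sm.add_constant(d)
    if len(d) - X.shape[1] <= 0:
        raise ValueError("not enough observations for the requested model")
    fit = sm.OLS(y, X).fit()
    contrast = np.zeros((2, X.shape[1]))
    contrast[0, list(X.columns).index("slope_a")] = 1
    contrast[1, list(X.columns).index("slope_b")] = 1
    ftest = fit.f_test(contrast)

    robust = robust_refit(d, y)
    diverged = False
    if robust is not None:
        for term in ("slope_a", "slope_b"):
            if abs(robust[term] - fit.params[term]) > fit.bse[term]:
                diverged = True

    ga = np.linspace(d["slope_a"].min(), d["slope_a"].max(), grid_size)
    gb = np.linspace(d["slope_b"].min(), d["slope_b"].max(), grid_size)
    aa, bb = np.meshgrid(ga, gb)
    gX = pd.DataFrame({"slope_a": aa.ravel(), "slope_b": bb.ravel()})
    for c in d.columns:
        if c not in ("slope_a", "slope_b"):
            gX[c] = d[c].mean()
    gX = sm.add_constant(gX[list(d.columns)], has_constant="add")
    grid = pd.DataFrame({
        "slope_a": aa.ravel(), "slope_b": bb.ravel(),
        "predicted": fit.predict(gX[list(X.columns)]),
    })

    infl = fit.get_influence()
    resid = fit.resid
    diagnostics = {
        "residual_sd": float(resid.std(ddof=X.shape[1])),
        "resid_fitted_corr": float(np.corrcoef(fit.fittedvalues, resid)[0, 1]),
        "normality_jb": float(stats.jarque_bera(resid).statistic),
        "max_cooks_distance": float(np.max(infl.cooks_distance[0])),
    }
    return SlopeRegressionResult(
        params=fit.params, bse=fit.bse, pvalues=fit.pvalues,
        omnibus_f=float(ftest.fvalue), omnibus_p=float(ftest.pvalue),
        robust_params=robust, robust_diverged=diverged,
        grid=grid, diagnostics=diagnostics, n=len(d),
    )
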