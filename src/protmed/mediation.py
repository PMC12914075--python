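"""Multi-mediator causal mediation through a linear signature score.

Candidate mediator fold-changes are combined by ordinary least squares into
a single signature score; the treatment effect on the outcome fold-change
is then decomposed with the linear two-model estimator:

    mediator model:  score   ~ treatment + pretreatment covariates  (alpha1)
    outcome model:   outcome ~ treatment + score + covariates       (beta1, beta2)

    ACME = alpha1 * beta2,  ADE = beta1,  TE = ACME + ADE,
    mediated proportion = ACME / TE.

Inference is by nonparametric bootstrap of subjects with percentile
confidence intervals. The contribution of each mediator is measured by the
leave-one-out mediated-proportion loss: refit the score without that
mediator, rerun the mediation, and subtract the reduced proportion from
the full one (paired within each bootstrap resample).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from protmed.data_model import TrialDataset

log = logging.getLogger(__name__)

TE_TOL = 1e-8


# ---------------------------------------------------------------------------
# signature score
# ---------------------------------------------------------------------------

@dataclass
class SignatureScore:
    """Fitted linear combination of candidate mediator fold-changes."""

    weights: pd.Series          # index: ["intercept", *candidates]
    score: pd.Series            # fitted linear predictor on the fitting sample
    dropped: list[str] = field(default_factory=list)

    def predict(self, fc: pd.DataFrame) -> pd.Series:
        cols = [c for c in self.weights.index if c != "intercept"]
        return self.weights["intercept"] + fc[cols] @ self.weights[cols]


def build_signature_score(fc: pd.DataFrame, y: pd.Series) -> SignatureScore:
    """OLS of the outcome fold-change on all candidate fold-changes.

    Exactly collinear columns are dropped (logged); p >= n is refused
    because the design targets p << n.
    """
    fc = fc.dropna()
    y = y.loc[fc.index]
    n, p = fc.shape
    if p >= n:
        raise ValueError(f"p={p} >= n={n}: signature regression is not identified")
    cols = list(fc.columns)
    dropped = []
    X = np.column_stack([np.ones(n), fc.to_numpy()])
    while np.linalg.matrix_rank(X) < X.shape[1]:
        # drop the last column involved in the exact collinearity
        for j in range(len(cols) - 1, -1, -1):
            trial = [c for c in cols if c != cols[j]]
            Xt = np.column_stack([np.ones(n), fc[trial].to_numpy()])
            if np.linalg.matrix_rank(Xt) == Xt.shape[1] or len(trial) == 0:
                dropped.append(cols[j])
                cols = trial
                X = Xt
                break
    if dropped:
        log.warning("signature score: dropped collinear columns %s", dropped)
    beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
    weights = pd.Series(beta, index=["intercept", *cols])
    score = pd.Series(X @ beta, index=fc.index, name="signature_score")
    return SignatureScore(weights=weights, score=score, dropped=dropped)


# ---------------------------------------------------------------------------
# mediation estimator
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    acme: float
    ade: float
    te: float
    proportion: float
    ci: dict[str, tuple[float, float]]
    n_boot: int
    seed: int
    unstable: bool = False      # |TE| below tolerance or sign mismatch

    def as_dict(self) -> dict:
        return {
            "acme": self.acme, "ade": self.ade, "te": self.te,
            "proportion": self.proportion,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n_boot": self.n_boot, "seed": self.seed, "unstable": self.unstable,
        }


def _design(arm: np.ndarray, Z: np.ndarray | None, extra: np.ndarray | None = None):
    n = arm.shape[0]
    cols = [np.ones(n), arm]
    if extra is not None:
        cols.append(extra)
    X = np.column_stack(cols if Z is None else cols + [Z])
    return X


def _point_estimates(arm, score, y, Z):
    Xm = _design(arm, Z)
    am, *_ = np.linalg.lstsq(Xm, score, rcond=None)
    Xo = _design(arm, Z, extra=score)
    bo, *_ = np.linalg.lstsq(Xo, y, rcond=None)
    alpha1 = am[1]
    beta1, beta2 = bo[1], bo[2]
    return alpha1 * beta2, beta1


def mediate(
    arm,
    score,
    y,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Decompose the treatment effect into ACME/ADE/TE via the score.

    ``covariates`` are the pretreatment covariates entering both models
    (baseline values of the mediators and of the outcome, by convention).
    ``n_boot = 0`` skips inference (point estimates only).
    """
    arm = np.asarray(arm, dtype=float)
    score_v = np.asarray(score, dtype=float)
    yv = np.asarray(y, dtype=float)
    Z = None if covariates is None else np.asarray(covariates, dtype=float)
    if set(np.unique(arm)) - {0.0, 1.0}:
        raise ValueError("treatment must be binary 0/1")

    acme, ade = _point_estimates(arm, score_v, yv, Z)
    te = acme + ade
    proportion = acme / te if abs(te) > TE_TOL else np.nan
    unstable = abs(te) <= TE_TOL or (np.isfinite(proportion) and not 0 <= proportion <= 1)

    ci: dict[str, tuple[float, float]] = {}
    if n_boot:
        rng = np.random.default_rng(seed)
        n = len(yv)
        stats = np.empty((n_boot, 4))
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            a, d = _point_estimates(arm[idx], score_v[idx], yv[idx],
                                    None if Z is None else Z[idx])
            t = a + d
            stats[b] = (a, d, t, a / t if abs(t) > TE_TOL else np.nan)
        for k, name in enumerate(("acme", "ade", "te", "proportion")):
            col = stats[:, k]
            col = col[np.isfinite(col)]
            ci[name] = (float(np.percentile(col, 2.5)), float(np.percentile(col, 97.5)))
    result = MediationResult(
        acme=float(acme), ade=float(ade), te=float(te),
        proportion=float(proportion), ci=ci, n_boot=n_boot, seed=seed,
        unstable=bool(unstable),
    )
    assert abs(result.acme + result.ade - result.te) < 1e-10
    return result


def counterfactual_acme(arm, score, y, covariates=None) -> float:
    """ACME via explicit potential-outcome prediction on the fitted models.

    Fits the same two linear models and computes
    ``E[Y(1, M(1))] - E[Y(1, M(0))]`` by predicting the mediator under each
    treatment and pushing both through the outcome model. For linear
    no-interaction models this equals the product of coefficients exactly;
    it serves as an independent route for cross-checking.
    """
    arm = np.asarray(arm, dtype=float)
    score = np.asarray(score, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = None if covariates is None else np.asarray(covariates, dtype=float)
    n = len(y)
    Xm = _design(arm, Z)
    am, *_ = np.linalg.lstsq(Xm, score, rcond=None)
    Xo = _design(arm, Z, extra=score)
    bo, *_ = np.linalg.lstsq(Xo, y, rcond=None)

    def m_hat(treat):
        return _design(np.full(n, float(treat)), Z) @ am

    def y_hat(treat, m):
        return _design(np.full(n, float(treat)), Z, extra=m) @ bo

    return float(np.mean(y_hat(1, m_hat(1)) - y_hat(1, m_hat(0))))


def total_effect_regression(arm, y, covariates=None) -> float:
    """Arm coefficient of the covariate-adjusted total-effect regression."""
    arm = np.asarray(arm, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = None if covariates is None else np.asarray(covariates, dtype=float)
    beta, *_ = np.linalg.lstsq(_design(arm, Z), y, rcond=None)
    return float(beta[1])


# ---------------------------------------------------------------------------
# leave-one-out mediated-proportion loss
# ---------------------------------------------------------------------------

def _signature_proportion(arm, F, y, Z, keep):
    """Refit score on columns ``keep`` and return the mediated proportion."""
    n = len(y)
    Xs = np.column_stack([np.ones(n), F[:, keep]])
    w, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    score = Xs @ w
    a, d = _point_estimates(arm, score, y, Z)
    t = a + d
    return a / t if abs(t) > TE_TOL else np.nan


def loo_proportion_loss(
    fc: pd.DataFrame,
    arm,
    y,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mediated-proportion loss of each mediator, ranked.

    For mediator j: ``loss_j = proportion(full score) - proportion(score
    refit without j)``. Within each bootstrap replicate the same subject
    resample feeds the full and every reduced model, so each loss is a
    paired difference. Returns a frame indexed by mediator with columns
    ``loss``, ``ci_lo``/``ci_hi`` (if ``n_boot``) and ``rank``.
    """
    if fc.shape[1] < 2:
        raise ValueError("need at least two candidate mediators")
    arm = np.asarray(arm, dtype=float)
    yv = np.asarray(y, dtype=float)
    F = fc.to_numpy(dtype=float)
    Z = None if covariates is None else np.asarray(covariates, dtype=float)
    m = F.shape[1]
    all_cols = np.arange(m)

    def losses(idx):
        Zi = None if Z is None else Z[idx]
        full = _signature_proportion(arm[idx], F[idx], yv[idx], Zi, all_cols)
        out = np.empty(m)
        for j in range(m):
            red = _signature_proportion(
                arm[idx], F[idx], yv[idx], Zi, np.delete(all_cols, j)
            )
            out[j] = full - red
        return out

    n = len(yv)
    point = losses(np.arange(n))
    result = pd.DataFrame({"loss": point}, index=fc.columns)
    if n_boot:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, m))
        for b in range(n_boot):
            boot[b] = losses(rng.integers(0, n, n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN replicates under tiny TE
            result["ci_lo"] = np.nanpercentile(boot, 2.5, axis=0)
            result["ci_hi"] = np.nanpercentile(boot, 97.5, axis=0)
    result["rank"] = result["loss"].rank(ascending=False, method="first").astype(int)
    return result.sort_values("loss", ascending=False)


# ---------------------------------------------------------------------------
# candidate screening and dataset-level glue
# ---------------------------------------------------------------------------

def screen_candidates(
    dataset: TrialDataset,
    proteins: list[str] | None = None,
    alpha: float = 0.05,
    scale: str = "raw",
) -> pd.DataFrame:
    """Screen proteins for treatment effect and treatment-slope modification.

    Criterion 1 (expression): treatment effect on the protein's log2
    change, adjusting its baseline level and the eGFR fold-change; fitted
    as a mixed model with subject random intercepts across the two
    follow-up visits (plain OLS when only one follow-up exists).
    Criterion 2 (interaction): treatment x protein-fold-change interaction
    on the outcome fold-change, adjusting eGFR fold-change and the
    baseline outcome and protein. Selection requires either criterion at
    level ``alpha``.
    """
    s = dataset.schema
    proteins = list(proteins) if proteins is not None else list(s.proteins)
    y = _outcome_fc(dataset, s.follow_ups[-1], scale)
    egfr_fc = {v: np.log(dataset.fold_change("egfr", v)) for v in s.follow_ups}
    rows = []
    for p in proteins:
        base = dataset.value(p, s.baseline)
        if all(dataset.value(p, v).equals(base) for v in s.follow_ups) or base.nunique() <= 1:
            rows.append({"protein": p, "skipped": True})
            log.warning("screen: protein %s skipped (zero variance)", p)
            continue
        try:
            eff, eff_p = _treatment_effect_on_protein(dataset, p, egfr_fc)
            inter, inter_p = _interaction_on_outcome(dataset, p, y, egfr_fc[s.follow_ups[-1]])
        except np.linalg.LinAlgError:
            rows.append({"protein": p, "skipped": True})
            log.warning("screen: protein %s skipped (singular design)", p)
            continue
        reason = []
        if eff_p < alpha:
            reason.append("effect")
        if inter_p < alpha:
            reason.append("interaction")
        rows.append({
            "protein": p, "skipped": False,
            "arm_effect": eff, "arm_p": eff_p,
            "interaction": inter, "interaction_p": inter_p,
            "selected": bool(reason), "reason": "+".join(reason),
        })
    return pd.DataFrame(rows).set_index("protein")


def _treatment_effect_on_protein(dataset, protein, egfr_fc):
    s = dataset.schema
    frames = []
    for v in s.follow_ups:
        d = pd.DataFrame({
            "dnpx": dataset.value(protein, v) - dataset.value(protein, s.baseline),
            "arm": dataset.arm.astype(float),
            "base": dataset.value(protein, s.baseline),
            "egfr_fc": egfr_fc[v],
            "subject": dataset.subject_ids,
        })
        frames.append(d)
    long = pd.concat(frames).dropna()
    if len(s.follow_ups) > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(
                "dnpx ~ arm + base + egfr_fc", long, groups=long["subject"]
            ).fit(reml=True)
        return float(fit.params["arm"]), float(fit.pvalues["arm"])
    fit = smf.ols("dnpx ~ arm + base + egfr_fc", long).fit()
    return float(fit.params["arm"]), float(fit.pvalues["arm"])


def _interaction_on_outcome(dataset, protein, y, egfr_fc):
    s = dataset.schema
    v = s.follow_ups[-1]
    d = pd.DataFrame({
        "y": y,
        "arm": dataset.arm.astype(float),
        "pfc": dataset.fold_change(protein, v),
        "egfr_fc": egfr_fc,
        "picp_bl": dataset.value(s.outcome, s.baseline),
        "p_bl": dataset.value(protein, s.baseline),
    }).dropna()
    fit = smf.ols("y ~ arm * pfc + egfr_fc + picp_bl + p_bl", d).fit()
    return float(fit.params["arm:pfc"]), float(fit.pvalues["arm:pfc"])


def _outcome_fc(dataset, visit, scale):
    fc = dataset.fold_change(dataset.schema.outcome, visit)
    return np.log(fc) if scale == "log" else fc


def mediation_inputs(
    dataset: TrialDataset,
    candidates: list[str],
    visit: str,
    scale: str = "raw",
    include_egfr_fc: bool = False,
):
    """Assemble (fc, arm, y, covariates) for the signature/mediation stage.

    On the ``log`` analysis scale candidate mediators enter as log2 NPX
    changes and the outcome as the log fold-change (the scale on which the
    synthetic generator's structural model is exact); on the default
    ``raw`` scale both are plain fold-changes. Pretreatment covariates are
    the baseline outcome and the baseline values of every candidate.
    """
    s = dataset.schema
    if scale == "log":
        fc = pd.DataFrame({
            c: dataset.value(c, visit) - dataset.value(c, s.baseline) for c in candidates
        })
    else:
        fc = pd.DataFrame({c: dataset.fold_change(c, visit) for c in candidates})
    cov = pd.DataFrame({f"{c}__bl": dataset.value(c, s.baseline) for c in candidates})
    cov[f"{s.outcome}__bl"] = dataset.value(s.outcome, s.baseline)
    if include_egfr_fc:
        cov["egfr__fc"] = np.log(dataset.fold_change("egfr", visit))
    y = _outcome_fc(dataset, visit, scale)
    keep = fc.notna().all(axis=1) & cov.notna().all(axis=1) & y.notna()
    return fc.loc[keep], dataset.arm.loc[keep].astype(float), y.loc[keep], cov.loc[keep]


def mediation_analysis(
    dataset: TrialDataset,
    candidates: list[str],
    visit: str,
    scale: str = "raw",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[SignatureScore, MediationResult]:
    """Signature score + mediation decomposition for one follow-up visit."""
    fc, arm, y, cov = mediation_inputs(dataset, candidates, visit, scale)
    sig = build_signature_score(fc, y)
    res = mediate(arm, sig.score, y, covariates=cov, n_boot=n_boot, seed=seed)
    return sig, res
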