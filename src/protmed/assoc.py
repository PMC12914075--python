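"""Quartile trend tests, interaction and stratified-effect analyses.

Trend across ordered fold-change quartiles uses Spearman rank correlation
for continuous variables and the Cochran-Armitage trend-in-proportions
test for binary ones (equally spaced scores by default, two-sided p from
the normal reference). Treatment-modification analyses follow the trial
convention: outcome fold-change regressed on treatment, protein
fold-change, their interaction, eGFR fold-change and the relevant
baselines; stratified effects split at the baseline median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from protmed.data_model import TrialDataset, assign_quartiles

log = logging.getLogger(__name__)


def percent_of(count: int, total: int) -> float:
    """Percentage at the reporting precision used in summary tables."""
    return round(100.0 * count / total, 1)


@dataclass
class TrendResult:
    variable: str
    test: str                   # "spearman" | "cochran_armitage"
    statistic: float
    p: float
    flagged: str = ""


def spearman_trend(values: pd.Series, groups: pd.Series, name: str = "") -> TrendResult:
    """Rank correlation of a continuous variable with the group index 1..k."""
    d = pd.DataFrame({"v": values, "g": pd.Series(groups).astype("float")}).dropna()
    if d["g"].nunique() < 3:
        raise ValueError("need at least 3 quartile groups represented")
    if d["v"].nunique() == 1:
        return TrendResult(name, "spearman", np.nan, np.nan, flagged="constant input")
    rho, p = stats.spearmanr(d["v"], d["g"])
    return TrendResult(name, "spearman", float(rho), float(p))


def cochran_armitage(counts, scores=None, name: str = "") -> TrendResult:
    """Cochran-Armitage trend test on a 2 x k table of counts.

    Row 0 holds successes, row 1 failures per ordered group. ``scores``
    default to 1..k. Empty columns are dropped with a warning. The
    statistic is the standardized score-test Z; p is two-sided normal.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
        raise ValueError("counts must be a 2 x k table with k >= 2")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    s = np.arange(1, counts.shape[1] + 1, dtype=float) if scores is None else np.asarray(scores, float)
    keep = counts.sum(axis=0) > 0
    if not keep.all():
        log.warning("cochran_armitage: dropping %d empty column(s)", (~keep).sum())
        counts, s = counts[:, keep], s[keep]
    x = counts[0]
    nj = counts.sum(axis=0)
    N = nj.sum()
    pbar = x.sum() / N
    num = float((s * x).sum() - pbar * (s * nj).sum())
    var = pbar * (1 - pbar) * ((s * s * nj).sum() - (s * nj).sum() ** 2 / N)
    if var <= 0:
        return TrendResult(name, "cochran_armitage", 0.0, 1.0, flagged="degenerate table")
    z = num / np.sqrt(var)
    return TrendResult(name, "cochran_armitage", float(z), float(2 * stats.norm.sf(abs(z))))


def interaction_model(
    dataset: TrialDataset, protein: str, visit: str, scale: str = "raw"
):
    """Treatment x protein-fold-change interaction on the outcome fold-change.

    OLS of the outcome fold-change on treatment, the protein fold-change,
    their interaction, eGFR fold-change, and the baseline outcome and
    protein values. Returns ``(estimate, p, fitted model)``.
    """
    s = dataset.schema
    if dataset.arm.nunique() < 2:
        raise ValueError("treatment arm is constant; interaction is not identified")
    fc = dataset.fold_change(s.outcome, visit)
    d = pd.DataFrame({
        "y": np.log(fc) if scale == "log" else fc,
        "arm": dataset.arm.astype(float),
        "pfc": dataset.fold_change(protein, visit),
        "egfr_fc": np.log(dataset.fold_change("egfr", visit)),
        "out_bl": dataset.value(s.outcome, s.baseline),
        "p_bl": dataset.value(protein, s.baseline),
    }).dropna()
    fit = smf.ols("y ~ arm * pfc + egfr_fc + out_bl + p_bl", d).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("singular design in interaction model")
    return float(fit.params["arm:pfc"]), float(fit.pvalues["arm:pfc"]), fit


@dataclass
class StratifiedEffect:
    variable: str
    median: float
    below: dict                  # {"effect", "ci", "n"} or {"missing": reason}
    above: dict
    interaction_p: float


def stratified_effect(
    dataset: TrialDataset,
    baseline_variable: str,
    visit: str,
    scale: str = "raw",
) -> StratifiedEffect:
    """Adjusted treatment effect below/above the baseline median of a variable.

    The pooled model supplies the treatment x (above-median) interaction p;
    per-stratum models give the adjusted treatment effect with 95% CI. A
    stratum missing one of the arms is reported effect-missing.
    """
    s = dataset.schema
    base = dataset.value(baseline_variable, s.baseline)
    med = float(base.median())
    fc = dataset.fold_change(s.outcome, visit)
    d = pd.DataFrame({
        "y": np.log(fc) if scale == "log" else fc,
        "arm": dataset.arm.astype(float),
        "base": base,
        "high": (base > med).astype(float),
        "out_bl": dataset.value(s.outcome, s.baseline),
        "egfr_fc": np.log(dataset.fold_change("egfr", visit)),
    }).dropna()
    if d["high"].nunique() < 2:
        raise ValueError("median split produced an empty stratum")
    pooled = smf.ols("y ~ arm * high + base + out_bl + egfr_fc", d).fit()
    inter_p = float(pooled.pvalues["arm:high"])

    def stratum(g: pd.DataFrame) -> dict:
        if g["arm"].nunique() < 2:
            return {"missing": "an arm is absent in this stratum", "n": len(g)}
        fit = smf.ols("y ~ arm + base + out_bl + egfr_fc", g).fit()
        lo, hi = fit.conf_int().loc["arm"]
        return {"effect": float(fit.params["arm"]), "ci": (float(lo), float(hi)), "n": len(g)}

    return StratifiedEffect(
        variable=baseline_variable, median=med,
        below=stratum(d[d["high"] == 0]), above=stratum(d[d["high"] == 1]),
        interaction_p=inter_p,
    )


def regression_plane(
    outcome_fc: pd.Series,
    fc_a: pd.Series,
    fc_b: pd.Series,
    baselines: pd.DataFrame,
    grid_size: int = 20,
):
    """Adjusted two-predictor regression plane for 3-D surface plots.

    OLS of the outcome fold-change on two protein fold-changes, adjusting
    the supplied baseline columns; the grid spans the observed predictor
    ranges with baselines held at their means. Returns ``(fit, grid)``.
    """
    d = pd.DataFrame({"y": outcome_fc, "fc_a": fc_a, "fc_b": fc_b}).join(baselines).dropna()
    y = d.pop("y")
    X = sm.add_constant(d)
    fit = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("singular design in regression plane")
    ga = np.linspace(d["fc_a"].min(), d["fc_a"].max(), grid_size)
    gb = np.linspace(d["fc_b"].min(), d["fc_b"].max(), grid_size)
    aa, bb = np.meshgrid(ga, gb)
    gX = pd.DataFrame({"fc_a": aa.ravel(), "fc_b": bb.ravel()})
    for c in d.columns:
        if c not in ("fc_a", "fc_b"):
            gX[c] = d[c].mean()
    gX = sm.add_constant(gX[list(d.columns)], has_constant="add")
    grid = pd.DataFrame({
        "fc_a": aa.ravel(), "fc_b": bb.ravel(),
        "predicted": fit.predict(gX[list(X.columns)]),
    })
    return fit, grid


def quartile_table(
    dataset: TrialDataset,
    visit: str,
    continuous: list[str],
    binary: list[str],
) -> pd.DataFrame:
    """Baseline-characteristics summary by outcome fold-change quartile.

    Continuous variables as median (IQR) with a Spearman p-trend; binary
    variables as n (%) with a Cochran-Armitage p-trend. Trend p-values are
    reported unadjusted, with a Benjamini-Hochberg column alongside.
    """
    s = dataset.schema
    q = assign_quartiles(dataset.fold_change(s.outcome, visit)).groups
    rows = []
    for v in continuous:
        base = dataset.value(v, s.baseline)
        tr = spearman_trend(base, q, name=v)
        row = {"variable": v, "type": "continuous", "p_trend": tr.p}
        for g in sorted(q.dropna().unique()):
            vals = base[q == g].dropna()
            row[f"Q{g}"] = (
                f"{vals.median():.1f} ({vals.quantile(.25):.1f}-{vals.quantile(.75):.1f})"
            )
        rows.append(row)
    for v in binary:
        base = dataset.value(v, s.baseline)
        groups = sorted(q.dropna().unique())
        tab = np.array([
            [(base[q == g] == 1).sum() for g in groups],
            [(base[q == g] == 0).sum() for g in groups],
        ])
        tr = cochran_armitage(tab, name=v)
        row = {"variable": v, "type": "binary", "p_trend": tr.p}
        for i, g in enumerate(groups):
            n1, n0 = tab[0, i], tab[1, i]
            row[f"Q{g}"] = f"{n1} ({percent_of(n1, n1 + n0)}%)"
        rows.append(row)
    out = pd.DataFrame(rows).set_index("variable")
    out["p_bh"] = multipletests(out["p_trend"].fillna(1.0), method="fdr_bh")[1]
    return out
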