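"""Synthetic randomized-trial generator with closed-form mediation ground truth.

The generator emulates a two-arm trial in which treatment lowers a serum
fibrosis biomarker (the outcome, stored as a concentration in ug/L) partly
through a configurable subset of mediator proteins on a log2 NPX panel,
measured at baseline and two follow-up visits. The structural model is
linear on the analysis scale (log outcome fold-change, log2 NPX change),
so the mediation decomposition has an exact closed form:

    ACME = sum_j a_j * b_j,   ADE = c,   TE = ACME + ADE,
    mediated proportion = ACME / TE,

where ``a_j`` is the treatment effect on mediator j's log2 change and
``b_j`` its coefficient in the outcome equation. Subject-specific random
slopes drive three-visit trajectories, and designated protein slopes are
coupled (coefficients ``kappa``) to echocardiographic slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from protmed.data_model import TrialDataset, TrialSchema


def _default_mediators() -> dict[str, tuple[float, float]]:
    # name -> (a_j: log2-NPX units, b_j: log-outcome per log2-NPX)
    # Signs mix increases and decreases; every product a_j*b_j is negative,
    # matching a treatment that lowers the outcome partly through the panel.
    return {
        "P001": (0.50, -0.040),
        "P002": (0.40, -0.050),
        "P003": (-0.35, 0.040),
        "P004": (0.30, -0.030),
        "P005": (-0.25, 0.060),
    }


@dataclass
class SimulationConfig:
    """Stated world of the synthetic trial; defaults mirror the target design
    (488 subjects, 276 NPX proteins, visits at 0/1/9 months)."""

    n_subjects: int = 488
    n_proteins: int = 276
    visit_times: tuple[float, ...] = (0.0, 1.0, 9.0)  # months
    mediators: dict[str, tuple[float, float]] = field(default_factory=_default_mediators)
    direct_effect: float = -0.052          # c, log-outcome units
    visit2_effect_scale: float = 1.0       # persistent treatment effect by default
    # covariate coefficients entering both mediator and outcome equations
    cov_effects_mediator: dict[str, float] = field(
        default_factory=lambda: {"age10": 0.05, "sex": -0.04, "egfr_fc": 0.30}
    )
    cov_effects_outcome: dict[str, float] = field(
        default_factory=lambda: {"age10": -0.01, "sex": 0.02, "egfr_fc": 0.15}
    )
    npx_baseline_sd: float = 1.0
    npx_change_sd: float = 0.25            # within-visit noise on log2 changes
    outcome_baseline_sd: float = 0.28      # log-scale dispersion of baseline outcome
    outcome_noise_sd: float = 0.10         # log fold-change noise
    protein_slope_sd: float = 0.03         # per-month subject random slope, log2/mo
    echo_slope_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"lavi": 0.15, "ea_ratio": 0.015}
    )
    echo_meas_sd: dict[str, float] = field(
        default_factory=lambda: {"lavi": 1.5, "ea_ratio": 0.05}
    )
    # echo variable -> {protein: kappa} coupling of slopes
    slope_coupling: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "lavi": {"P003": 6.0, "P001": -4.0},
            "ea_ratio": {"P003": 0.5, "P001": -0.35},
        }
    )
    arm_effect_egfr_fc: float = -0.02      # mild renal effect, makes adjustment real
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < len(self.mediators):
            raise ValueError("n_proteins must be >= number of mediators")
        for name, sd in [
            ("npx_baseline_sd", self.npx_baseline_sd),
            ("npx_change_sd", self.npx_change_sd),
            ("outcome_noise_sd", self.outcome_noise_sd),
            ("protein_slope_sd", self.protein_slope_sd),
        ]:
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def protein_names(self) -> list[str]:
        named = list(self.mediators)
        extra = [f"P{i:03d}" for i in range(1, self.n_proteins + 1)]
        extra = [p for p in extra if p not in self.mediators]
        return (named + extra)[: self.n_proteins]


@dataclass
class GroundTruth:
    """Realized coefficients and the closed-form mediation decomposition."""

    a: dict[str, float]
    b: dict[str, float]
    direct_effect: float
    acme: float
    ade: float
    te: float
    proportion: float | None
    protein_slopes: pd.DataFrame | None = None   # subjects x proteins, per month
    echo_slopes: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "acme": self.acme,
            "ade": self.ade,
            "te": self.te,
            "proportion": self.proportion,
        }


def true_mediation(config: SimulationConfig) -> GroundTruth:
    """Closed-form ACME/ADE/TE/proportion implied by the config alone."""
    a = {m: ab[0] for m, ab in config.mediators.items()}
    b = {m: ab[1] for m, ab in config.mediators.items()}
    acme = float(sum(a[m] * b[m] for m in a))
    ade = float(config.direct_effect)
    te = acme + ade
    proportion = None if te == 0 else acme / te
    return GroundTruth(a=a, b=b, direct_effect=ade, acme=acme, ade=ade, te=te,
                       proportion=proportion)


def simulate_trial(config: SimulationConfig) -> tuple[TrialDataset, GroundTruth]:
    """Draw one trial realization and its ground truth.

    See the module docstring for the structural model. Outcome fold-changes
    are generated on the log scale and exponentiated for storage, so the
    linear mediation decomposition is exact on the log analysis scale.
    """
    truth = true_mediation(config)
    if truth.te == 0 and truth.acme != 0:
        raise ValueError(
            "degenerate config: TE = 0 with nonzero ACME makes the mediated "
            "proportion undefined; adjust direct_effect or mediator coefficients"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    times = np.asarray(config.visit_times)
    visits = ("baseline", "v1", "v2")
    fu_times = times[1:]
    proteins = config.protein_names
    med_names = list(config.mediators)

    ids = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="subject_id")
    arm = np.zeros(n, dtype=int)
    arm[rng.permutation(n)[: n // 2]] = 1

    # clinical covariates (baseline distributions mirror an elderly
    # at-risk-of-heart-failure population)
    age = rng.normal(73, 6.5, n)
    sex = (rng.random(n) < 0.74).astype(int)      # 1 = male
    smoker = (rng.random(n) < 0.08).astype(int)
    diabetes = (rng.random(n) < 0.40).astype(int)
    cad = (rng.random(n) < 0.72).astype(int)
    qrs = rng.normal(95, 14, n)
    clinical_bl = {
        "age": age, "sex": sex, "smoker": smoker, "diabetes": diabetes,
        "cad": cad, "qrs": qrs,
        "bmi": rng.normal(28.5, 4.0, n),
        "sbp": rng.normal(140, 15, n),
        "dbp": rng.normal(78, 9, n),
        "sodium": rng.normal(139.5, 1.8, n),
        "potassium": rng.normal(4.3, 0.35, n),
        "egfr": rng.normal(74, 16, n),
        # 0-10 symptom scale, kept >= 1 so ratio fold-changes stay defined
        "breathlessness": np.clip(rng.normal(5, 1.8, n), 1, 10),
    }

    cols: dict[str, np.ndarray] = {"arm": arm}
    for v, vals in clinical_bl.items():
        cols[f"{v}__baseline"] = vals

    # longitudinal clinical variables: mild multiplicative drift; eGFR carries
    # a small treatment effect so that eGFR-fold-change adjustment matters
    egfr_log_fc = {}
    for visit in ("v1", "v2"):
        for v in ("bmi", "sbp", "dbp", "sodium", "potassium", "breathlessness"):
            cols[f"{v}__{visit}"] = clinical_bl[v] * np.exp(rng.normal(0, 0.03, n))
        lfc = config.arm_effect_egfr_fc * arm + rng.normal(0, 0.08, n)
        egfr_log_fc[visit] = lfc
        cols[f"egfr__{visit}"] = clinical_bl["egfr"] * np.exp(lfc)

    age10 = (age - age.mean()) / 10.0
    gm = config.cov_effects_mediator
    go = config.cov_effects_outcome

    # NPX panel: baseline levels, subject random slopes, per-visit changes
    mu = rng.normal(5.0, 1.0, len(proteins))
    baseline_npx = mu[None, :] + rng.normal(0, config.npx_baseline_sd, (n, len(proteins)))
    slopes = rng.normal(0, config.protein_slope_sd, (n, len(proteins)))
    npx = {p: {"baseline": baseline_npx[:, i]} for i, p in enumerate(proteins)}
    delta = {}  # (visit, mediator) -> realized log2 change
    d_scale = {"v1": 1.0, "v2": config.visit2_effect_scale}
    for k, visit in enumerate(("v1", "v2")):
        t = fu_times[k]
        cov_term = gm["age10"] * age10 + gm["sex"] * sex + gm["egfr_fc"] * egfr_log_fc[visit]
        for i, p in enumerate(proteins):
            ch = slopes[:, i] * t + rng.normal(0, config.npx_change_sd, n)
            if p in config.mediators:
                ch = ch + config.mediators[p][0] * d_scale[visit] * arm + cov_term
                delta[(visit, p)] = ch
            npx[p][visit] = baseline_npx[:, i] + ch
    for p in proteins:
        for visit in visits:
            cols[f"{p}__{visit}"] = npx[p][visit]

    # outcome concentration: log-linear SEM on the fold-change
    log_y0 = np.log(80.0) + 0.05 * age10 + rng.normal(0, config.outcome_baseline_sd, n)
    cols["picp__baseline"] = np.exp(log_y0)
    for visit in ("v1", "v2"):
        lfc = (
            config.direct_effect * d_scale[visit] * arm
            + sum(config.mediators[m][1] * delta[(visit, m)] for m in med_names)
            + go["age10"] * age10 + go["sex"] * sex + go["egfr_fc"] * egfr_log_fc[visit]
            + rng.normal(0, config.outcome_noise_sd, n)
        )
        cols[f"picp__{visit}"] = np.exp(log_y0 + lfc)

    # echo variables: slopes coupled to designated protein random slopes
    echo_base = {"lavi": rng.normal(31, 7, n), "ea_ratio": rng.normal(0.85, 0.2, n)}
    pidx = {p: i for i, p in enumerate(proteins)}
    echo_slope = {}
    for e, coupling in config.slope_coupling.items():
        sl = rng.normal(0, config.echo_slope_noise_sd[e], n)
        for p, kappa in coupling.items():
            if p in pidx:  # coupling to proteins outside a reduced panel is ignored
                sl = sl + kappa * slopes[:, pidx[p]]
        echo_slope[e] = sl
        for k, visit in enumerate(visits):
            noise = rng.normal(0, config.echo_meas_sd[e], n) if k else 0.0
            cols[f"{e}__{visit}"] = echo_base[e] + sl * times[k] + noise

    schema = TrialSchema(
        visits=visits,
        visit_times=dict(zip(visits, map(float, times))),
        proteins=tuple(proteins),
        echo=tuple(config.slope_coupling),
    )
    table = pd.DataFrame(cols, index=ids)
    dataset = TrialDataset(table=table, schema=schema)

    # per-month least-squares slope of each noiseless protein trajectory
    tc = times - times.mean()
    w = {v: tc[k + 1] / (tc ** 2).sum() for k, v in enumerate(("v1", "v2"))}
    step = {p: config.mediators[p][0] * arm for p in med_names}
    true_sl = {}
    for i, p in enumerate(proteins):
        sl = slopes[:, i].copy()
        if p in med_names:
            sl = sl + (w["v1"] * d_scale["v1"] + w["v2"] * d_scale["v2"]) * step[p]
        true_sl[p] = sl
    truth.protein_slopes = pd.DataFrame(true_sl, index=ids)
    truth.echo_slopes = pd.DataFrame(echo_slope, index=ids)
    return dataset, truth
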