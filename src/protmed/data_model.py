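"""Core data types and conventions for wide-format longitudinal trial tables.

A trial table has one row per subject and columns ``<variable>__<visit>``
plus ``subject_id`` and ``arm`` (1 = active treatment, 0 = control).
Protein abundances are Olink-style NPX values (log2 relative
quantification), so their fold-change is ``2**(final - baseline)``;
concentrations (the outcome biomarker, clinical measures) use the plain
ratio ``final / baseline``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: clinical covariates used only at baseline (binary or slowly varying)
DEFAULT_STATIC_CLINICAL = ("age", "sex", "smoker", "diabetes", "cad", "qrs")
#: clinical covariates entering as baseline value and fold-change
DEFAULT_LONGITUDINAL_CLINICAL = (
    "bmi", "sbp", "dbp", "sodium", "potassium", "egfr", "breathlessness",
)


@dataclass(frozen=True)
class TrialSchema:
    """Declares variable roles and the visit structure of a trial table."""

    visits: tuple[str, ...] = ("baseline", "v1", "v2")
    visit_times: dict[str, float] = field(
        default_factory=lambda: {"baseline": 0.0, "v1": 1.0, "v2": 9.0}
    )
    outcome: str = "picp"
    proteins: tuple[str, ...] = ()
    clinical_static: tuple[str, ...] = DEFAULT_STATIC_CLINICAL
    clinical_longitudinal: tuple[str, ...] = DEFAULT_LONGITUDINAL_CLINICAL
    echo: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        times = [self.visit_times[v] for v in self.visits]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("visit times must be strictly increasing")

    @property
    def baseline(self) -> str:
        return self.visits[0]

    @property
    def follow_ups(self) -> tuple[str, ...]:
        return self.visits[1:]

    def column(self, variable: str, visit: str) -> str:
        return f"{variable}__{visit}"


@dataclass
class TrialDataset:
    """Per-subject arm, covariates and per-visit measurements (wide format).

    ``table`` is indexed by subject id and holds ``arm`` plus the
    ``<variable>__<visit>`` measurement columns. ``load_log`` records cells
    that failed numeric parsing during loading.
    """

    table: pd.DataFrame
    schema: TrialSchema
    load_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> pd.Index:
        return self.table.index

    @property
    def arm(self) -> pd.Series:
        return self.table["arm"]

    def value(self, variable: str, visit: str) -> pd.Series:
        col = self.schema.column(variable, visit)
        if col not in self.table.columns:
            raise KeyError(f"column {col!r} not present")
        return self.table[col]

    def npx(self, visit: str) -> pd.DataFrame:
        cols = {p: self.schema.column(p, visit) for p in self.schema.proteins}
        out = self.table[list(cols.values())].copy()
        out.columns = list(cols)
        return out

    def fold_change(self, variable: str, visit: str) -> pd.Series:
        """Fold-change of ``variable`` at ``visit`` relative to baseline.

        NPX proteins use ``2**(final-baseline)``; everything else the
        final/baseline ratio.
        """
        base = self.value(variable, self.schema.baseline)
        final = self.value(variable, visit)
        if variable in self.schema.proteins:
            return npx_fold_change(base, final).rename(f"{variable}__fc")
        return (final / base).rename(f"{variable}__fc")

    def npx_fold_changes(self, visit: str) -> pd.DataFrame:
        base = self.npx(self.schema.baseline)
        final = self.npx(visit)
        return npx_fold_change(base, final)

    # -- validation and I/O ------------------------------------------------
    def validate(self) -> None:
        bad = self.table.index[~self.table["arm"].isin([0, 1])]
        if len(bad):
            raise ValueError(f"arm must be 0 or 1; violated by subject {bad[0]!r}")
        out_bl = self.schema.column(self.schema.outcome, self.schema.baseline)
        if out_bl not in self.table.columns:
            raise ValueError(f"missing mandatory column {out_bl!r}")
        npx_cols = [
            self.schema.column(p, v)
            for p in self.schema.proteins
            for v in self.schema.visits
            if self.schema.column(p, v) in self.table.columns
        ]
        if npx_cols:
            vals = self.table[npx_cols].to_numpy(float)
            if np.isinf(vals).any():
                raise ValueError("NPX values must be finite where present")

    def to_csv(self, path, sep: str = ",") -> None:
        out = self.table.reset_index()
        out.to_csv(path, sep=sep, index=False)

    def subset(self, ids) -> "TrialDataset":
        return replace(self, table=self.table.loc[ids], load_log=[])


def load_trial_table(path, schema: TrialSchema, sep: str | None = None) -> TrialDataset:
    """Read a wide delimited trial table and validate it against ``schema``.

    Unparseable numeric cells become missing and are reported in the
    dataset's ``load_log``; missing mandatory columns raise immediately.
    When the schema's final visit is entirely absent from the file, the
    last follow-up visit that is present stands in for it (the
    "last visit" convention for subjects without a month-9 sample).
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("subject_id", "arm"):
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    out_bl = schema.column(schema.outcome, schema.baseline)
    if out_bl not in raw.columns:
        raise ValueError(f"missing mandatory column {out_bl!r}")

    # last-available-follow-up fallback for the final visit
    final = schema.visits[-1]
    if not any(c.endswith(f"__{final}") for c in raw.columns):
        present = [v for v in schema.follow_ups if any(c.endswith(f"__{v}") for c in raw.columns)]
        if not present:
            raise ValueError("no follow-up visit columns present")
        sub = present[-1]
        log.warning("visit %r absent; treating %r as the final visit", final, sub)
        raw = raw.rename(
            columns={c: c.replace(f"__{sub}", f"__{final}") for c in raw.columns if c.endswith(f"__{sub}")}
        )

    table = raw.set_index("subject_id")
    load_log: list[str] = []
    parsed = {}
    for col in table.columns:
        num = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[num.isna() & table[col].notna()]
        load_log.extend(f"{col}: unparseable value for subject {s}" for s in bad)
        parsed[col] = num
    table = pd.DataFrame(parsed, index=table.index)
    table["arm"] = table["arm"].astype("Int64")
    return TrialDataset(table=table, schema=schema, load_log=load_log)


def npx_fold_change(npx_baseline, npx_final):
    """Fold-change of an NPX (log2) pair: ``2**(final - baseline)``.

    Accepts scalars, Series or DataFrames; missing inputs give missing
    outputs (never 0).
    """
    if np.isscalar(npx_baseline) and np.isscalar(npx_final):
        if not (math.isfinite(npx_baseline) and math.isfinite(npx_final)):
            return float("nan")
        return float(2.0 ** (npx_final - npx_baseline))
    return 2.0 ** (npx_final - npx_baseline)


@dataclass
class QuartileAssignment:
    """Ordered-group assignment by ranked value, remainder to the lowest groups."""

    groups: pd.Series          # 1..n_groups, <NA> for missing input
    cuts: list[float]          # boundary values between consecutive groups
    sizes: list[int]
    degenerate: bool = False


def assign_quartiles(values: pd.Series, n_groups: int = 4) -> QuartileAssignment:
    """Rank subjects ascending and split into contiguous, near-equal groups.

    Group sizes differ by at most one; any remainder goes to the lowest
    groups first (n=481 -> 121/120/120/120). Ties are broken by stable
    subject order. All-identical input yields a single flagged group.
    """
    values = pd.Series(values)
    ok = values.dropna()
    if len(ok) < n_groups:
        raise ValueError(f"need at least {n_groups} non-missing values")
    groups = pd.Series(pd.NA, index=values.index, dtype="Int64")
    if ok.nunique() == 1:
        groups.loc[ok.index] = 1
        return QuartileAssignment(groups, [], [len(ok)], degenerate=True)
    n = len(ok)
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if g < rem else 0) for g in range(n_groups)]
    order = np.argsort(ok.to_numpy(), kind="stable")
    bounds = np.cumsum(sizes)
    labels = np.empty(n, dtype=int)
    start = 0
    for g, stop in enumerate(bounds, start=1):
        labels[order[start:stop]] = g
        start = stop
    groups.loc[ok.index] = labels
    sorted_vals = ok.to_numpy()[order]
    cuts = [float(sorted_vals[b - 1]) for b in bounds[:-1]]
    return QuartileAssignment(groups, cuts, sizes)


@dataclass
class FeatureMatrix:
    """Subjects x named features, min-max scaled on a reference partition.

    ``tags`` maps each column to ``(kind, source)`` where kind is
    ``"baseline"`` or ``"fold_change"``. Scaling parameters come from the
    reference (training) rows only; values scaled outside [0, 1] on other
    rows are preserved, never clipped.
    """

    X: pd.DataFrame
    y: pd.Series
    tags: dict[str, tuple[str, str]]
    reference_ids: pd.Index
    scale_min: pd.Series
    scale_range: pd.Series
    excluded_ids: list = field(default_factory=list)


def build_feature_matrix(
    dataset: TrialDataset,
    visit: str,
    reference_ids=None,
    include_proteins: bool = True,
) -> FeatureMatrix:
    """Assemble the predictor roster for one baseline/follow-up visit pair.

    Columns: per-protein baseline NPX and NPX fold-change, baseline
    outcome, static clinical baselines, and baseline + fold-change of the
    longitudinal clinical variables. Target is the outcome fold-change.
    Complete cases only; exclusions are recorded.
    """
    s = dataset.schema
    cols: dict[str, pd.Series] = {}
    tags: dict[str, tuple[str, str]] = {}

    if include_proteins:
        base = dataset.npx(s.baseline)
        fc = dataset.npx_fold_changes(visit)
        for p in s.proteins:
            cols[f"{p}__bl"] = base[p]
            tags[f"{p}__bl"] = ("baseline", p)
            cols[f"{p}__fc"] = fc[p]
            tags[f"{p}__fc"] = ("fold_change", p)

    cols[f"{s.outcome}__bl"] = dataset.value(s.outcome, s.baseline)
    tags[f"{s.outcome}__bl"] = ("baseline", s.outcome)

    for v in s.clinical_static:
        if s.column(v, s.baseline) in dataset.table.columns:
            cols[f"{v}__bl"] = dataset.value(v, s.baseline)
            tags[f"{v}__bl"] = ("baseline", v)
    for v in s.clinical_longitudinal:
        if s.column(v, s.baseline) in dataset.table.columns:
            cols[f"{v}__bl"] = dataset.value(v, s.baseline)
            tags[f"{v}__bl"] = ("baseline", v)
            if s.column(v, visit) in dataset.table.columns:
                cols[f"{v}__fc"] = dataset.fold_change(v, visit)
                tags[f"{v}__fc"] = ("fold_change", v)

    X = pd.DataFrame(cols, index=dataset.subject_ids)
    y = dataset.fold_change(s.outcome, visit).rename(f"{s.outcome}__fc")
    keep = X.notna().all(axis=1) & y.notna()
    excluded = list(X.index[~keep])
    if excluded:
        log.info("feature matrix: excluding %d incomplete subjects", len(excluded))
    X, y = X.loc[keep], y.loc[keep]

    if reference_ids is None:
        reference_ids = X.index
    else:
        reference_ids = pd.Index(reference_ids).intersection(X.index)
    ref = X.loc[reference_ids]
    lo = ref.min(axis=0)
    rng = ref.max(axis=0) - lo
    flat = rng == 0
    if flat.any():
        log.warning("zero-variance feature(s) scaled to 0: %s", list(rng.index[flat]))
    safe = rng.replace(0, 1.0)
    Xs = (X - lo) / safe
    Xs.loc[:, flat] = 0.0
    return FeatureMatrix(
        X=Xs, y=y, tags=tags, reference_ids=reference_ids,
        scale_min=lo, scale_range=rng, excluded_ids=excluded,
    )
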