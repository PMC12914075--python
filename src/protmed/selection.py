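"""Consensus feature selection across four regression learners.

Four learner families (elastic-net penalized linear regression, random
forest, gradient boosting, small feed-forward network) are tuned by 3-fold
cross-validated grid search on an 80/20 train/test split, permutation
importance (mean RMSE increase under column shuffling) is computed per
learner, and features are retained when they fall in the top decile of at
least ``min_models`` learners; a final intersection keeps features
supported at both follow-up visits.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.neural_network import MLPRegressor

from protmed.data_model import TrialDataset, assign_quartiles

log = logging.getLogger(__name__)

LEARNER_FAMILIES = ("elastic_net", "random_forest", "gradient_boosting", "neural_net")


@dataclass
class LearnerSpec:
    """One learner family with its hyperparameter grid and CV settings."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in LEARNER_FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def make_estimator(self):
        if self.family == "elastic_net":
            return ElasticNet(max_iter=20_000)
        if self.family == "random_forest":
            return RandomForestRegressor(n_estimators=200, random_state=self.seed, n_jobs=1)
        if self.family == "gradient_boosting":
            return HistGradientBoostingRegressor(random_state=self.seed)
        return MLPRegressor(
            hidden_layer_sizes=(32,), max_iter=600, random_state=self.seed,
            learning_rate_init=0.01,
        )


def default_learners(seed: int = 0) -> dict[str, LearnerSpec]:
    """The four-learner roster with compact default grids."""
    return {
        "elastic_net": LearnerSpec(
            "elastic_net",
            {"alpha": [0.001, 0.01, 0.1], "l1_ratio": [0.2, 0.5, 0.9]},
            seed=seed,
        ),
        "random_forest": LearnerSpec(
            "random_forest",
            {"max_features": ["sqrt", 0.3], "min_samples_leaf": [2, 5]},
            seed=seed,
        ),
        "gradient_boosting": LearnerSpec(
            "gradient_boosting",
            {"learning_rate": [0.05, 0.1], "max_depth": [2, 3]},
            seed=seed,
        ),
        "neural_net": LearnerSpec(
            "neural_net",
            {"hidden_layer_sizes": [(32,), (16, 16)], "alpha": [1e-4, 1e-3]},
            seed=seed,
        ),
    }


def split_train_test(
    dataset: TrialDataset, visit: str, fraction: float = 0.8, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Disjoint, exhaustive train/test split of subjects.

    Stratified jointly by arm and by outcome fold-change quartile so both
    partitions are balanced; strata too small to split are merged (arm
    only, then unstratified) with a logged warning.
    """
    if dataset.n_subjects < 10:
        raise ValueError("need at least 10 subjects to split")
    fc = dataset.fold_change(dataset.schema.outcome, visit)
    q = assign_quartiles(fc).groups.astype("float").fillna(0).astype(int)
    arm = dataset.arm.astype(int)
    for labels in (arm.astype(str) + ":" + q.astype(str), arm.astype(str), None):
        if labels is not None and labels.value_counts().min() < 2:
            log.warning("stratum too small; merging strata")
            continue
        ids = dataset.subject_ids.to_numpy()
        train, test = train_test_split(
            ids, train_size=fraction, random_state=seed,
            stratify=None if labels is None else labels.to_numpy(),
        )
        return pd.Index(train), pd.Index(test)
    raise AssertionError("unreachable")


@dataclass
class FitReport:
    family: str
    best_params: dict
    cv_rmse: float
    rmse_train: float
    r2_train: float
    rmse_test: float | None = None
    r2_test: float | None = None


def fit_learner(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    spec: LearnerSpec,
    X_test: pd.DataFrame | None = None,
    y_test: pd.Series | None = None,
):
    """Grid-search the learner by mean CV RMSE; report train/test RMSE and R2.

    Grid points that fail to converge or error out are scored as +inf RMSE
    rather than aborting the search.
    """
    cv = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(
        spec.make_estimator(),
        spec.grid,
        scoring="neg_root_mean_squared_error",
        cv=cv,
        error_score=-np.inf,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X_train.to_numpy(), y_train.to_numpy())
    model = search.best_estimator_
    pred_tr = model.predict(X_train.to_numpy())
    report = FitReport(
        family=spec.family,
        best_params=search.best_params_,
        cv_rmse=float(-search.best_score_),
        rmse_train=float(np.sqrt(mean_squared_error(y_train, pred_tr))),
        r2_train=float(r2_score(y_train, pred_tr)),
    )
    if X_test is not None and len(X_test):
        pred_te = model.predict(X_test.to_numpy())
        report.rmse_test = float(np.sqrt(mean_squared_error(y_test, pred_te)))
        report.r2_test = float(r2_score(y_test, pred_te))
    return model, report


def permutation_importance(
    model,
    X: pd.DataFrame,
    y: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    chunk: int = 50,
) -> pd.DataFrame:
    """Permutation importance: mean RMSE increase when one column is shuffled.

    Importance of feature f = mean over ``n_perm`` independent shuffles of
    (RMSE with f permuted - baseline RMSE); negative values are permitted.
    Permuted copies are stacked and predicted in batches of ``chunk``
    shuffles per call, which keeps the 1000-permutation contract tractable
    for tree ensembles. Returns a frame indexed by feature with columns
    ``importance``, ``se`` and ``n_perm``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    Xv = np.ascontiguousarray(X.to_numpy(dtype=float))
    yv = y.to_numpy(dtype=float)
    n, p = Xv.shape
    base_rmse = float(np.sqrt(mean_squared_error(yv, model.predict(Xv))))
    rows = {}
    for j, name in enumerate(X.columns):
        deltas = np.empty(n_perm)
        done = 0
        while done < n_perm:
            c = min(chunk, n_perm - done)
            stacked = np.broadcast_to(Xv, (c, n, p)).copy()
            perms = rng.permuted(np.broadcast_to(np.arange(n), (c, n)), axis=1)
            stacked[:, :, j] = Xv[perms, j]
            preds = model.predict(stacked.reshape(c * n, p)).reshape(c, n)
            err = preds - yv[None, :]
            deltas[done:done + c] = np.sqrt(np.mean(err * err, axis=1)) - base_rmse
            done += c
        rows[name] = (deltas.mean(), deltas.std(ddof=1) / math.sqrt(n_perm) if n_perm > 1 else np.nan)
    out = pd.DataFrame(rows, index=["importance", "se"]).T
    out["n_perm"] = n_perm
    return out


def top_decile(importance: pd.Series | pd.DataFrame, fraction: float = 0.10):
    """The ceil(fraction * p) most important features.

    Ties break by importance then feature name; an all-equal table is
    flagged tie-degenerate (first features by name).
    """
    if isinstance(importance, pd.DataFrame):
        importance = importance["importance"]
    if len(importance) < 10:
        raise ValueError("need at least 10 features")
    k = math.ceil(fraction * len(importance))
    order = sorted(importance.items(), key=lambda kv: (-kv[1], kv[0]))
    degenerate = importance.nunique() == 1
    if degenerate:
        log.warning("top_decile: all importances equal; selection is tie-degenerate")
    return set(name for name, _ in order[:k])


@dataclass
class ConsensusSet:
    """Features supported by at least ``min_models`` learners."""

    support: pd.Series            # feature -> number of supporting learners
    members: dict[str, set]       # learner -> its top-decile set
    min_models: int = 2

    @property
    def features(self) -> set:
        return set(self.support.index)


def consensus(learner_sets: dict[str, set], min_models: int = 2) -> ConsensusSet:
    """Union of features appearing in >= min_models per-learner top-decile sets."""
    if len(learner_sets) < 2:
        raise ValueError("need at least two learner sets")
    counts: dict[str, int] = {}
    for s in learner_sets.values():
        for f in s:
            counts[f] = counts.get(f, 0) + 1
    kept = {f: c for f, c in counts.items() if c >= min_models}
    support = pd.Series(kept, dtype=int).sort_values(ascending=False)
    return ConsensusSet(support=support, members=learner_sets, min_models=min_models)


def cross_timepoint_intersection(first: ConsensusSet, second: ConsensusSet) -> ConsensusSet:
    """Features present in the consensus of both follow-up visits."""
    common = first.features & second.features
    support = pd.concat(
        [first.support.loc[sorted(common)], second.support.loc[sorted(common)]], axis=1
    ).min(axis=1).astype(int) if common else pd.Series(dtype=int)
    members = {f"v1:{k}": v for k, v in first.members.items()}
    members.update({f"v2:{k}": v for k, v in second.members.items()})
    return ConsensusSet(support=support, members=members,
                        min_models=max(first.min_models, second.min_models))


def select_features(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame | None = None,
    y_test: pd.Series | None = None,
    learners: dict[str, LearnerSpec] | None = None,
    n_perm: int = 1000,
    fraction: float = 0.10,
    min_models: int = 2,
    seed: int = 0,
    importance_on: str = "train",
):
    """Fit all learners, compute importances, and form the consensus set.

    ``importance_on`` selects the partition on which permutation RMSE
    increases are evaluated ("train" by default; "test" is cheaper and
    leakage-free). Returns ``(ConsensusSet, {family: importance frame},
    {family: FitReport})``.
    """
    learners = learners or default_learners(seed)
    if importance_on == "test" and X_test is None:
        raise ValueError("importance_on='test' requires a test partition")
    Xi, yi = (X_test, y_test) if importance_on == "test" else (X_train, y_train)
    importances, reports, sets = {}, {}, {}
    for i, (name, spec) in enumerate(learners.items()):
        model, rep = fit_learner(X_train, y_train, spec, X_test, y_test)
        imp = permutation_importance(model, Xi, yi, n_perm=n_perm, seed=seed + 31 * i)
        importances[name] = imp
        reports[name] = rep
        sets[name] = top_decile(imp, fraction)
    return consensus(sets, min_models), importances, reports
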