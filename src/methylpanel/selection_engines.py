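"""Feature selection: recursive elimination around tree learners, and LASSO.

Five selectors are run on the same (complete, imputed) cohort:

* random forest with recursive feature elimination, optimized either for
  cross-validated accuracy or for specificity (``rf`` x criterion);
* gradient-boosted trees with the same elimination loop (``bt`` x
  criterion);
* L1-penalized logistic regression with the one-standard-error penalty
  rule (``lasso``).

The elimination loop (per iteration): tune hyperparameters by exhaustive
grid search under stratified k-fold cross-validation with the training
portion of each fold down-sampled to the minority class size; retrain on
the whole cohort at the tuned settings; compute feature importance —
permutation importance (mean decrease in accuracy) for forests,
normalized total split gain for boosted trees; drop the least important
feature (for boosted trees, all features left unused by the model drop
together); repeat until no feature is left.  The feature set of the
iteration with the best criterion value is selected, ties resolved towards
fewer features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble import _forest
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .data_model import MethylationDataset

__all__ = [
    "ForestGrid",
    "BoostGrid",
    "default_grid",
    "CVMetrics",
    "RFEIterationRecord",
    "SelectionResult",
    "make_learner",
    "cv_evaluate",
    "tune",
    "importance_rf",
    "importance_bt",
    "rfe",
    "selection_from_trace",
    "lasso_select",
]

CRITERIA = ("accuracy", "specificity")


@dataclass(frozen=True)
class ForestGrid:
    """Candidate features-tried-per-split values and a fixed tree count."""

    mtry: tuple[int, ...] = (1, 2, 3, 5, 8)
    n_trees: int = 500

    def points(self) -> list[dict]:
        # ascending so that grid-search ties resolve to the smaller model
        return [{"mtry": m, "n_trees": self.n_trees} for m in sorted(self.mtry)]


@dataclass(frozen=True)
class BoostGrid:
    """Candidate boosting-round counts and tree depths, fixed learning rate."""

    rounds: tuple[int, ...] = (6, 10, 25, 50, 100)
    depth: tuple[int, ...] = (1, 2, 4, 6)
    learning_rate: float = 0.3

    def points(self) -> list[dict]:
        return [
            {"rounds": r, "depth": d, "learning_rate": self.learning_rate}
            for r in sorted(self.rounds)
            for d in sorted(self.depth)
        ]


def default_grid(method: str):
    if method == "rf":
        return ForestGrid()
    if method == "bt":
        return BoostGrid()
    raise ValueError(f"no hyperparameter grid for method {method!r}")


class CVMetrics(NamedTuple):
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RFEIterationRecord:
    """One elimination step: the feature set evaluated and what was dropped."""

    iteration: int
    features: tuple[str, ...]
    hyperparams: dict
    accuracy: float
    sensitivity: float
    specificity: float
    importances: dict[str, float]
    eliminated: tuple[str, ...]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one selector run."""

    method: str  # rf | bt | lasso
    criterion: str  # accuracy | specificity | not_applicable
    trace: tuple[RFEIterationRecord, ...]
    selected: frozenset[str]
    metric_value: float
    details: dict = field(default_factory=dict)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def make_learner(method: str, hyperparams: Mapping, seed: int, n_features: int | None = None):
    """Instantiate the underlying classifier for a method + hyperparameters."""
    if method == "rf":
        mtry = int(hyperparams["mtry"])
        if n_features is not None:
            mtry = min(mtry, n_features)
        return RandomForestClassifier(
            n_estimators=int(hyperparams.get("n_trees", 500)),
            max_features=mtry,
            random_state=seed,
            n_jobs=1,
        )
    if method == "bt":
        return XGBClassifier(
            n_estimators=int(hyperparams["rounds"]),
            max_depth=int(hyperparams["depth"]),
            learning_rate=float(hyperparams.get("learning_rate", 0.3)),
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
            verbosity=0,
        )
    if method == "lasso":
        # unpenalized logistic fit on an already-selected feature set
        return LogisticRegression(C=np.inf, max_iter=2000, random_state=seed)
    raise ValueError(f"unknown method {method!r}")


def _downsample(train_idx: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Subsample the majority class of a training fold to the minority size."""
    pos = train_idx[y[train_idx] == 1]
    neg = train_idx[y[train_idx] == 0]
    if len(pos) > len(neg):
        pos = rng.choice(pos, size=len(neg), replace=False)
    elif len(neg) > len(pos):
        neg = rng.choice(neg, size=len(pos), replace=False)
    out = np.concatenate([pos, neg])
    out.sort()
    return out


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> CVMetrics:
    acc = float((y_pred == y_true).mean())
    sens = float((y_pred[y_true == 1] == 1).mean()) if (y_true == 1).any() else np.nan
    spec = float((y_pred[y_true == 0] == 0).mean()) if (y_true == 0).any() else np.nan
    return CVMetrics(acc, sens, spec)


def cv_evaluate(
    method: str,
    X: pd.DataFrame,
    y: np.ndarray,
    hyperparams: Mapping,
    k: int = 10,
    seed: int = 0,
) -> CVMetrics:
    """Stratified k-fold CV with within-fold training down-sampling.

    The majority class of each fold's *training* portion is down-sampled to
    the minority size before fitting; the held-out fold keeps its natural
    composition.  Held-out predictions are pooled over folds into a single
    confusion table (every sample contributes exactly once), which keeps
    the specificity estimate stable even when folds hold few controls.
    Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs at least k={k} samples (have {counts[1]} cases, {counts[0]} controls)"
        )
    ss = np.random.SeedSequence(seed)
    split_seed, ds_seed, fit_seed = (_seed_int(c) for c in ss.spawn(3))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=split_seed)
    rng = np.random.default_rng(ds_seed)
    Xv = X.to_numpy()
    pred = np.empty_like(y)
    for fold, (train_idx, test_idx) in enumerate(skf.split(Xv, y)):
        tr = _downsample(train_idx, y, rng)
        model = make_learner(method, hyperparams, seed=fit_seed + fold, n_features=X.shape[1])
        model.fit(Xv[tr], y[tr])
        pred[test_idx] = model.predict(Xv[test_idx])
    return _fold_metrics(y, pred)


def tune(
    method: str,
    X: pd.DataFrame,
    y: np.ndarray,
    grid,
    criterion: str,
    k: int = 10,
    seed: int = 0,
) -> tuple[dict, CVMetrics]:
    """Exhaustive grid evaluation; argmax of the criterion.

    Every grid point is scored with the identical CV partition so the
    comparison is paired; ties resolve to the smaller model (fewer rounds,
    then smaller depth / smaller mtry), which is the first point in the
    grid's ascending order.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    best: tuple[dict, CVMetrics] | None = None
    for params in grid.points():
        m = cv_evaluate(method, X, y, params, k=k, seed=seed)
        if best is None or getattr(m, criterion) > getattr(best[1], criterion):
            best = (params, m)
    assert best is not None, "empty hyperparameter grid"
    return best


def _oob_helper(fn, *args):
    # scikit-learn's bootstrap helpers grew a sample_weight argument; pass
    # None (uniform weights) where required
    try:
        return fn(*args, None)
    except TypeError:
        return fn(*args)


def importance_rf(
    model: RandomForestClassifier,
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    n_repeats: int = 1,
) -> pd.Series:
    """Mean decrease in accuracy, permuting each feature on out-of-bag samples.

    For every tree, the accuracy on its out-of-bag samples is compared with
    the accuracy after shuffling one feature among those samples
    (``n_repeats`` shuffles per tree); the importance of a feature is the
    mean drop over trees.  Out-of-bag evaluation matters: on the training
    rows an overfit forest memorizes noise features, and their apparent
    importance would mask genuinely predictive ones.
    """
    rng = np.random.default_rng(seed)
    Xv = np.asarray(X, dtype=float)
    n, p = Xv.shape
    n_bootstrap = _oob_helper(_forest._get_n_samples_bootstrap, n, model.max_samples)
    drops = np.zeros(p)
    counts = np.zeros(p)
    for tree in model.estimators_:
        oob = _oob_helper(
            _forest._generate_unsampled_indices, tree.random_state, n, n_bootstrap
        )
        if oob.size < 2:
            continue
        X_oob = Xv[oob]
        y_oob = y[oob]
        base = float((tree.predict(X_oob) == y_oob).mean())
        # one stacked predict per tree: p features x n_repeats blocks
        blocks = []
        for j in range(p):
            for _ in range(n_repeats):
                M = X_oob.copy()
                M[:, j] = X_oob[rng.permutation(oob.size), j]
                blocks.append(M)
        pred = tree.predict(np.vstack(blocks))
        m = oob.size
        for j in range(p):
            for r in range(n_repeats):
                b = (j * n_repeats + r) * m
                drops[j] += base - float((pred[b:b + m] == y_oob).mean())
            counts[j] += n_repeats
    imp = np.divide(drops, counts, out=np.zeros(p), where=counts > 0)
    return pd.Series(imp, index=X.columns)


def importance_bt(model: XGBClassifier, features: Sequence[str]) -> pd.Series:
    """Total split gain per feature, normalized to sum to 1.

    Features unused by any split score exactly 0.  If the model contains no
    split at all, every importance is 0.
    """
    booster = model.get_booster()
    raw = booster.get_score(importance_type="total_gain")
    imp = pd.Series(0.0, index=list(features))
    for k, v in raw.items():
        # xgboost reports "f<idx>" when fitted from a bare array
        name = list(features)[int(k[1:])] if k.startswith("f") and k[1:].isdigit() and k not in imp.index else k
        imp[name] = float(v)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return imp


def _select_from_trace(
    trace: Sequence[RFEIterationRecord], criterion: str
) -> tuple[frozenset[str], float]:
    best_val = -np.inf
    best_feats: tuple[str, ...] = ()
    for rec in trace:  # iterated largest set -> smallest: ">=" prefers fewer features on ties
        val = getattr(rec, criterion)
        if val >= best_val:
            best_val = val
            best_feats = rec.features
    return frozenset(best_feats), float(best_val)


def selection_from_trace(
    method: str,
    criterion: str,
    trace: Sequence[RFEIterationRecord],
    details: dict | None = None,
) -> SelectionResult:
    """Re-read an elimination trace under a different selection criterion.

    With a single-point hyperparameter grid the trace does not depend on
    the tuning criterion (tuning is degenerate), so both the accuracy- and
    the specificity-optimized selections can be derived from one loop.
    """
    selected, value = _select_from_trace(trace, criterion)
    return SelectionResult(
        method=method,
        criterion=criterion,
        trace=tuple(trace),
        selected=selected,
        metric_value=value,
        details=dict(details or {}),
    )


def rfe(
    ds: MethylationDataset,
    method: str,
    criterion: str,
    grid=None,
    features: Sequence[str] | None = None,
    k: int = 10,
    seed: int = 0,
    n_repeats: int = 1,
) -> SelectionResult:
    """Recursive feature elimination around a tree learner.

    See the module docstring for the loop.  The returned trace has strictly
    decreasing feature-set sizes, ending with the step that empties the set.
    """
    if method not in ("rf", "bt"):
        raise ValueError("rfe supports methods 'rf' and 'bt'")
    if grid is None:
        grid = default_grid(method)
    current = list(features) if features is not None else list(ds.cpg_names)
    if not current:
        raise ValueError("need at least one feature")
    y = ds.y
    root = np.random.SeedSequence(seed)
    trace: list[RFEIterationRecord] = []
    it = 0
    while current:
        cv_ss, fit_ss, imp_ss = root.spawn(3)
        X = ds.values[current]
        params, metrics = tune(method, X, y, grid, criterion, k=k, seed=_seed_int(cv_ss))
        model = make_learner(method, params, seed=_seed_int(fit_ss), n_features=len(current))
        model.fit(X.to_numpy(), y)
        if method == "rf":
            imp = importance_rf(model, X, y, seed=_seed_int(imp_ss), n_repeats=n_repeats)
            eliminated = (imp.index[int(np.argmin(imp.to_numpy()))],)
        else:
            imp = importance_bt(model, current)
            if (imp.to_numpy() == 0).any():
                # all features unused by the boosted model drop together
                eliminated = tuple(imp.index[imp.to_numpy() == 0])
            else:
                eliminated = (imp.index[int(np.argmin(imp.to_numpy()))],)
        trace.append(
            RFEIterationRecord(
                iteration=it,
                features=tuple(current),
                hyperparams=dict(params),
                accuracy=metrics.accuracy,
                sensitivity=metrics.sensitivity,
                specificity=metrics.specificity,
                importances={f: float(v) for f, v in imp.items()},
                eliminated=eliminated,
            )
        )
        drop = set(eliminated)
        current = [f for f in current if f not in drop]
        it += 1
    selected, value = _select_from_trace(trace, criterion)
    return SelectionResult(
        method=method,
        criterion=criterion,
        trace=tuple(trace),
        selected=selected,
        metric_value=value,
        details={"k": k, "seed": seed, "grid": repr(grid)},
    )


# -- L1-penalized logistic selection ---------------------------------------

def _l1_logistic(Xs: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # glmnet-style objective (1/n) sum nll + lam * ||beta||_1  <=>  C = 1/(n*lam)
    model = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (len(y) * lam),
        solver="liblinear",
        intercept_scaling=1000.0,  # keep the intercept effectively unpenalized
        max_iter=5000,
        tol=1e-7,
        random_state=0,
    )
    model.fit(Xs, y)
    return model


def _deviance(model: LogisticRegression, Xs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(model.predict_proba(Xs)[:, 1], 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_select(
    ds: MethylationDataset,
    features: Sequence[str] | None = None,
    k: int = 10,
    seed: int = 0,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 1e-3,
) -> SelectionResult:
    """L1-penalized logistic selection with the one-standard-error rule.

    Features are standardized; a descending penalty path from the smallest
    penalty that zeroes every coefficient (``lambda_max``) is scored by
    k-fold cross-validated binomial deviance.  The chosen penalty is the
    *largest* one whose mean CV deviance is within one standard error of
    the minimum; the selected features are those with a non-zero
    coefficient at that penalty in the full-data fit.
    """
    cols = list(features) if features is not None else list(ds.cpg_names)
    X = ds.values[cols].to_numpy()
    y = ds.y
    if y.all() or not y.any():
        raise ValueError("both classes are required")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    usable = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, usable] = (X[:, usable] - mu[usable]) / sd[usable]

    n = len(y)
    ybar = y.mean()
    lam_max = float(np.max(np.abs(Xs.T @ (y - ybar))) / n)
    lams = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31 - 1))
    fold_dev = np.empty((k, n_lambdas))
    for fi, (tr, te) in enumerate(skf.split(Xs, y)):
        for li, lam in enumerate(lams):
            m = _l1_logistic(Xs[tr], y[tr], lam)
            fold_dev[fi, li] = _deviance(m, Xs[te], y[te])
    mean_dev = fold_dev.mean(axis=0)
    se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(k)
    i_min = int(np.argmin(mean_dev))
    bound = mean_dev[i_min] + se_dev[i_min]
    # lams descend, so the first index within the bound is the largest penalty
    i_1se = int(np.argmax(mean_dev <= bound))
    final = _l1_logistic(Xs, y, float(lams[i_1se]))
    coef = final.coef_.ravel()
    selected = frozenset(c for c, b, ok in zip(cols, coef, usable) if ok and abs(b) > 1e-10)
    return SelectionResult(
        method="lasso",
        criterion="not_applicable",
        trace=(),
        selected=selected,
        metric_value=float(mean_dev[i_1se]),
        details={
            "lambda": float(lams[i_1se]),
            "lambda_max": lam_max,
            "cv_deviance_min": float(mean_dev[i_min]),
            "one_se_bound": float(bound),
            "k": k,
            "seed": seed,
        },
    )
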