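"""Object-oriented random-forest ecosystem classification on segment tables.

Segments (spectrally homogeneous image objects) are summarized by the
q25/q50/q75 of each candidate variable; segments containing an inventory
plot inherit that plot's bioregion cluster and form the training set.
Feature selection is two-step: recursive feature elimination with a random
forest over candidate subset sizes (cross-validated, optimising the
support-weighted F1), then greedy removal of collinear variables
(|Pearson r| above a threshold) in rank order.  The final model is
evaluated by stratified k-fold cross-validation (pooled out-of-fold
confusion matrix in row percentages, per-class / weighted / macro F1),
interrogated with permutation variable importance (with permutation
p-values) and partial dependence on the log-odds scale, and applied to the
unlabeled segments to map ecosystems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .errors import DataError

logger = logging.getLogger(__name__)

QUANTILE_SUFFIXES = ("q25", "q50", "q75")


@dataclass
class FitResult:
    confusion: pd.DataFrame      # true x predicted, row percentages
    per_class_f1: pd.Series
    f1: float                    # support-weighted aggregate
    macro_f1: float
    folds: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "confusion_pct": {str(k): v for k, v in
                              self.confusion.round(4).T.to_dict().items()},
            "per_class_f1": {str(k): float(v) for k, v in self.per_class_f1.items()},
            "f1": self.f1,
            "macro_f1": self.macro_f1,
            "folds": self.folds,
            "seed": self.seed,
        }


@dataclass
class RFESelection:
    best_size: int
    selected: list               # top-ranked variables at the best size
    ranking: list                # all variables, best first
    cv_scores: pd.Series         # subset size -> mean CV weighted F1


@dataclass
class ImportanceResult:
    overall: pd.DataFrame        # variable x (importance, p_value, mean_decrease_gini)
    per_class: pd.DataFrame      # (variable, cluster) x (importance, p_value)
    n_permutations: int
    gini_p_values: pd.Series | None = None


@dataclass
class PartialDependenceCurve:
    variable: str
    grid: np.ndarray
    log_odds: pd.DataFrame       # grid point x class


def default_forest(seed=None, n_estimators: int = 500) -> RandomForestClassifier:
    """Forest with the package's default hyperparameters (500 trees)."""
    return RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)


def compute_segment_quantiles(pixel_samples: pd.DataFrame) -> pd.DataFrame:
    """q25/q50/q75 per variable per segment from long-format pixel samples.

    ``pixel_samples`` has columns ``segment_id, variable, value``; quantiles
    use the linear-interpolation convention.  Returns one row per segment
    with ``<variable>_q25/_q50/_q75`` columns.
    """
    required = {"segment_id", "variable", "value"}
    if not required <= set(pixel_samples.columns):
        raise DataError(f"pixel table must have columns {sorted(required)}")
    if pixel_samples.empty:
        raise DataError("pixel table is empty")
    q = (
        pixel_samples.groupby(["segment_id", "variable"])["value"]
        .quantile([0.25, 0.50, 0.75])
        .unstack()
    )
    q.columns = ["q25", "q50", "q75"]
    wide = q.unstack("variable")
    wide.columns = [f"{var}_{stat}" for stat, var in wide.columns]
    if wide.isna().any().any():
        raise DataError("some segments are missing pixel samples for some variables")
    return wide.sort_index(axis=1).reset_index()


def feature_columns(segments: pd.DataFrame) -> list:
    return [c for c in segments.columns
            if any(c.endswith(f"_{s}") for s in QUANTILE_SUFFIXES)]


def label_segments(
    segments: pd.DataFrame,
    labels,
    min_cluster_size: int = 15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach plot cluster labels to segments; split train / prediction sets.

    A segment containing a plot adopts that plot's cluster.  Clusters with
    fewer than ``min_cluster_size`` labeled sites are excluded entirely
    from training.  Segments without a plot (or whose cluster was excluded)
    form the prediction set.
    """
    labels = pd.Series(labels)
    seg = segments.copy()
    if "plot_id" not in seg.columns:
        raise DataError("segment table has no plot_id column")
    seg["cluster"] = seg["plot_id"].map(labels)

    labeled = seg[seg["cluster"].notna()].copy()
    sizes = labeled["cluster"].value_counts()
    small = sizes.index[sizes < min_cluster_size].tolist()
    if small:
        logger.info("excluding %d cluster(s) below %d sites: %s",
                    len(small), min_cluster_size, sorted(map(str, small)))
    train = labeled[~labeled["cluster"].isin(small)].copy()
    if not train.empty:
        train["cluster"] = train["cluster"].astype(int)
    predict = seg[~seg.index.isin(train.index)].drop(columns=["cluster"])
    return train, predict


def _scores_by_size(X, y, ranking_fn, sizes, cv):
    """Mean validation weighted-F1 per subset size, features ranked per fold."""
    scores = {s: [] for s in sizes}
    for tr, va in cv.split(X, y):
        ranked = ranking_fn(X.iloc[tr], y[tr])
        for s in sizes:
            feats = ranked[:s]
            model = ranking_fn.model_factory()
            model.fit(X.iloc[tr][feats], y[tr])
            pred = model.predict(X.iloc[va][feats])
            scores[s].append(f1_score(y[va], pred, average="weighted", zero_division=0))
    return pd.Series({s: float(np.mean(v)) for s, v in scores.items()})


class _ImpurityRanker:
    """Rank features by random-forest impurity importance (descending)."""

    def __init__(self, seed, n_estimators):
        self.seed, self.n_estimators = seed, n_estimators

    def model_factory(self):
        return default_forest(seed=self.seed, n_estimators=self.n_estimators)

    def __call__(self, X, y):
        model = self.model_factory()
        model.fit(X, y)
        order = np.argsort(-model.feature_importances_, kind="stable")
        return [X.columns[i] for i in order]


def select_features_rfe(
    train: pd.DataFrame,
    subset_sizes=range(5, 31),
    folds: int = 5,
    seed: int | None = None,
    n_estimators: int = 200,
    features: list | None = None,
    label_col: str = "cluster",
) -> RFESelection:
    """Recursive feature elimination over candidate subset sizes.

    Within each cross-validation fold the candidates are ranked by
    random-forest impurity importance on the training part, and each subset
    size is scored on the validation part (nested evaluation); the size
    with the best mean weighted F1 wins (ties to the smaller size).  The
    returned ranking is refit on the full training table.
    """
    features = features or feature_columns(train)
    X = train[features]
    y = train[label_col].to_numpy()
    sizes = sorted({min(int(s), len(features)) for s in subset_sizes})
    if max(subset_sizes) > len(features):
        logger.warning("subset sizes clipped to the %d available features", len(features))

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ranker = _ImpurityRanker(seed, n_estimators)
    cv_scores = _scores_by_size(X, y, ranker, sizes, cv)
    best_size = int(min(s for s in sizes if cv_scores[s] >= cv_scores.max() - 1e-12))
    ranking = ranker(X, y)
    return RFESelection(
        best_size=best_size,
        selected=ranking[:best_size],
        ranking=ranking,
        cv_scores=cv_scores,
    )


def prune_collinear(
    train: pd.DataFrame,
    subset: list,
    r_threshold: float = 0.7,
) -> tuple[list, list]:
    """Greedy collinearity pruning in rank order.

    Scanning ``subset`` from best-ranked to worst, a variable is dropped if
    its absolute Pearson correlation with any already-kept variable exceeds
    ``r_threshold``.  Returns ``(kept, dropped_log)`` where each log entry
    is ``(dropped, kept_partner, r)``.
    """
    kept: list = []
    dropped: list = []
    corr = train[subset].corr().abs()
    for v in subset:
        partner = next((u for u in kept if corr.loc[v, u] > r_threshold), None)
        if partner is None:
            kept.append(v)
        else:
            dropped.append((v, partner, float(corr.loc[v, partner])))
    return kept, dropped


def scores_from_predictions(y_true, y_pred, folds: int = 0, seed=None) -> FitResult:
    """Confusion (row %), per-class / weighted / macro F1 from pooled predictions."""
    classes = np.unique(np.concatenate([np.asarray(y_true), np.asarray(y_pred)]))
    cm = confusion_matrix(y_true, y_pred, labels=classes).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    pct = 100.0 * cm / np.where(row_sums > 0, row_sums, 1.0)
    per_class = f1_score(y_true, y_pred, labels=classes, average=None, zero_division=0)
    return FitResult(
        confusion=pd.DataFrame(pct, index=classes, columns=classes),
        per_class_f1=pd.Series(per_class, index=classes),
        f1=float(f1_score(y_true, y_pred, average="weighted", zero_division=0)),
        macro_f1=float(np.mean(per_class)),
        folds=folds,
        seed=seed,
    )


def fit_evaluate(
    train: pd.DataFrame,
    features: list,
    folds: int = 10,
    seed: int | None = None,
    n_estimators: int = 500,
    label_col: str = "cluster",
) -> tuple[FitResult, RandomForestClassifier]:
    """Stratified k-fold CV evaluation plus a final model fit on all data."""
    y = train[label_col].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DataError("training table has a single class")
    min_count = int(counts.min())
    if min_count < folds:
        logger.warning("reducing folds from %d to %d (smallest class)", folds, min_count)
        folds = max(2, min_count)
    X = train[features]
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    model = default_forest(seed=seed, n_estimators=n_estimators)
    pred = cross_val_predict(model, X, y, cv=cv)
    result = scores_from_predictions(y, pred, folds=folds, seed=seed)
    model.fit(X, y)
    return result, model


def permutation_importance_scores(
    model,
    data: pd.DataFrame,
    features: list,
    n_permutations: int = 100,
    seed: int | None = None,
    label_col: str = "cluster",
    gini_refits: bool = False,
) -> ImportanceResult:
    """Permutation variable importance with permutation p-values.

    For each variable the column is shuffled ``n_permutations`` times; the
    importance is the mean accuracy drop (per class: the mean F1 drop) and
    the p-value is (1 + #{permuted score >= baseline score}) /
    (n_permutations + 1).  A variable the model ignores has importance ~0
    and a large p-value; a constant column changes nothing and gets p = 1.
    Impurity (mean decrease Gini) importance is read off the fitted model;
    with ``gini_refits`` its p-values come from response-permutation refits.
    """
    rng = np.random.default_rng(seed)
    X = data[features].reset_index(drop=True)
    y = data[label_col].to_numpy()
    classes = model.classes_

    base_pred = model.predict(X)
    base_acc = float(np.mean(base_pred == y))
    base_f1 = f1_score(y, base_pred, labels=classes, average=None, zero_division=0)

    overall_rows, class_rows = [], []
    gini = pd.Series(model.feature_importances_, index=features, name="mean_decrease_gini")
    for v in features:
        acc_drops = np.empty(n_permutations)
        ge_base = 0
        f1_drops = np.zeros((n_permutations, len(classes)))
        f1_ge = np.zeros(len(classes))
        col = X[v].to_numpy()
        Xp = X.copy()
        for b in range(n_permutations):
            Xp[v] = rng.permutation(col)
            pred = model.predict(Xp)
            acc = float(np.mean(pred == y))
            acc_drops[b] = base_acc - acc
            ge_base += acc >= base_acc
            f1b = f1_score(y, pred, labels=classes, average=None, zero_division=0)
            f1_drops[b] = base_f1 - f1b
            f1_ge += f1b >= base_f1
        overall_rows.append({
            "variable": v,
            "importance": float(acc_drops.mean()),
            "p_value": (1 + ge_base) / (n_permutations + 1),
            "mean_decrease_gini": float(gini[v]),
        })
        for ci, c in enumerate(classes):
            class_rows.append({
                "variable": v,
                "cluster": c,
                "importance": float(f1_drops[:, ci].mean()),
                "p_value": (1 + f1_ge[ci]) / (n_permutations + 1),
            })

    gini_p = None
    if gini_refits:
        null_gini = np.empty((n_permutations, len(features)))
        params = model.get_params()
        for b in range(n_permutations):
            null_model = RandomForestClassifier(**{**params, "random_state": int(rng.integers(2**31))})
            null_model.fit(X, rng.permutation(y))
            null_gini[b] = null_model.feature_importances_
        gini_p = pd.Series(
            (1 + (null_gini >= gini.to_numpy()).sum(axis=0)) / (n_permutations + 1),
            index=features, name="gini_p_value",
        )

    return ImportanceResult(
        overall=pd.DataFrame(overall_rows).set_index("variable"),
        per_class=pd.DataFrame(class_rows).set_index(["variable", "cluster"]),
        n_permutations=n_permutations,
        gini_p_values=gini_p,
    )


def partial_dependence(
    model,
    data: pd.DataFrame,
    variable: str,
    features: list,
    grid_size: int = 20,
    eps: float = 1e-6,
) -> PartialDependenceCurve:
    """Per-class partial dependence of predicted log-odds on one variable.

    The grid spans the observed range of the variable; at each grid value
    the variable is substituted for every row, class probabilities are
    averaged and converted to log-odds log(p / (1 - p)).
    """
    if variable not in features:
        raise DataError(f"variable {variable!r} is not a model feature")
    X = data[features].reset_index(drop=True)
    lo, hi = float(X[variable].min()), float(X[variable].max())
    grid = np.linspace(lo, hi, grid_size)
    curves = np.empty((grid_size, len(model.classes_)))
    Xg = X.copy()
    for gi, g in enumerate(grid):
        Xg[variable] = g
        curves[gi] = model.predict_proba(Xg).mean(axis=0)
    p = np.clip(curves, eps, 1 - eps)
    log_odds = np.log(p / (1 - p))
    return PartialDependenceCurve(
        variable=variable,
        grid=grid,
        log_odds=pd.DataFrame(log_odds, index=grid, columns=model.classes_),
    )


def predict_segments(model, prediction: pd.DataFrame, features: list) -> pd.DataFrame:
    """Hard ecosystem label plus class-probability vector per segment."""
    missing = [f for f in features if f not in prediction.columns]
    if missing:
        raise DataError(f"prediction table is missing feature columns {missing}")
    X = prediction[features]
    proba = model.predict_proba(X)
    out = pd.DataFrame({"segment_id": prediction["segment_id"].to_numpy(),
                        "ecosystem": model.predict(X)})
    for ci, c in enumerate(model.classes_):
        out[f"p_{c}"] = proba[:, ci]
    return out
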