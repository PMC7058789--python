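"""Cohort splitting and the three multi-class classifiers.

The cohort is split 70/30 with per-class stratification (training count =
nearest integer to 0.7 x class size).  Three classifier families are
supported, each tuned by stratified 4-fold cross-validation over its grid:

* kernel SVM (linear / laplacian / gaussian / ANOVA-RBF kernels, C = 1..10,
  one-vs-one pairwise voting, selection by mean CV misclassification);
* random forest (tree count and per-split candidate count ``mtry``,
  selection by mean out-of-bag error, OOB error recorded per tree count);
* single-hidden-layer neural network (sigmoid hidden units 10..15, weight
  decay 2..0.0625, softmax output, cross-entropy + L2 penalty minimized by
  L-BFGS from several seeded restarts, selection by mean CV accuracy).

Features are z-scored on training statistics for the SVM and the network;
the forest consumes raw features.  A thin statsmodels-style facade —
``SubtypeClassifier`` / ``SubtypeClassifierResults`` — wraps grid selection,
final training and evaluation for interactive use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._forest_utils import oob_indices
from .errors import InvalidArgumentError, StratificationError
from .evaluation import ConfusionMatrix, MetricsReport, confusion, metrics
from .rng import stream_seed, substream

__all__ = [
    "SplitPlan", "TrainedClassifier",
    "stratified_split", "kernel_eval", "train_svm", "train_rf", "train_ann",
    "cv_select", "default_svm_grid", "default_rf_grid", "default_ann_grid",
    "SubtypeClassifier", "SubtypeClassifierResults",
]


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    val_idx: np.ndarray
    ratio: float
    seed: int
    per_class: dict[str, tuple[int, int]]  # label -> (n_train, n_val)


def stratified_split(labels, ratio: float = 0.7, seed: int = 0) -> SplitPlan:
    """Seeded per-class split; training takes round(ratio * class size)."""
    labels = np.asarray(labels)
    if not 0.0 < ratio <= 1.0:
        raise InvalidArgumentError("ratio must lie in (0, 1]")
    train, val, per_class = [], [], {}
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise StratificationError(f"class {c!r} has fewer than 2 members")
        perm = substream(seed, "split", str(c)).permutation(idx)
        n_train = int(np.floor(ratio * idx.size + 0.5))  # nearest int, half up
        train.extend(perm[:n_train])
        val.extend(perm[n_train:])
        per_class[str(c)] = (n_train, idx.size - n_train)
    return SplitPlan(np.sort(np.array(train, dtype=int)),
                     np.sort(np.array(val, dtype=int)),
                     ratio, int(seed), per_class)


# ---------------------------------------------------------------------------
# kernels


def _gram(kind: str, A: np.ndarray, B: np.ndarray, sigma: float,
          degree: int = 1) -> np.ndarray:
    if kind == "linear":
        return A @ B.T
    if kind == "gaussian":
        return np.exp(-sigma * cdist(A, B, "sqeuclidean"))
    if kind == "laplacian":
        # Euclidean distance in the exponent (the L1 variant is a config
        # choice left to callers via kernel_eval)
        return np.exp(-sigma * cdist(A, B, "euclidean"))
    if kind == "anova_rbf":
        out = np.zeros((A.shape[0], B.shape[0]))
        for k in range(A.shape[1]):
            out += np.exp(-sigma * (A[:, k, None] - B[None, :, k]) ** 2)
        return out ** degree
    raise InvalidArgumentError(f"unknown kernel {kind!r}")


def kernel_eval(kind: str, params: dict, x, y) -> float:
    """Evaluate one kernel value k(x, y)."""
    x = np.asarray(x, dtype=np.float64).reshape(1, -1)
    y = np.asarray(y, dtype=np.float64).reshape(1, -1)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidArgumentError("kernel inputs must be finite")
    if x.shape != y.shape:
        raise InvalidArgumentError("x and y must have the same dimension")
    sigma = float(params.get("sigma", 1.0))
    degree = int(params.get("degree", 1))
    return float(_gram(kind, x, y, sigma, degree)[0, 0])


def _median_sigma(Xs: np.ndarray, kind: str) -> float:
    """Median-heuristic kernel scale on the training distances."""
    d = cdist(Xs, Xs, "euclidean")
    vals = d[np.triu_indices_from(d, k=1)]
    vals = vals[vals > 0]
    med = np.median(vals) if vals.size else 1.0
    if kind == "laplacian":
        return 1.0 / med
    return 1.0 / med ** 2


# ---------------------------------------------------------------------------
# trained-classifier container


@dataclass
class TrainedClassifier:
    kind: str                       # {svm, rf, ann}
    spec: dict
    classes_: np.ndarray
    mean_: np.ndarray | None        # training standardization statistics
    sd_: np.ndarray | None
    _predict_fn: Callable = field(repr=False)
    extra: dict = field(default_factory=dict)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            return X
        return (X - self.mean_) / self.sd_

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return self._predict_fn(self._standardize(X))


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


# ---------------------------------------------------------------------------
# SVM


def train_svm(X, y, kernel: str = "gaussian", C: float = 1.0,
              sigma: float | None = None, degree: int = 1,
              seed: int = 0) -> TrainedClassifier:
    """Soft-margin kernel SVM, one-vs-one voting across the class pairs."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("need at least two classes")
    mean, sd = _fit_scaler(X)
    Xs = (X - mean) / sd
    if sigma is None:
        sigma = _median_sigma(Xs, kernel)
    gram = _gram(kernel, Xs, Xs, sigma, degree)
    clf = SVC(C=C, kernel="precomputed", random_state=seed)
    clf.fit(gram, y)

    def _predict(Xnew_s: np.ndarray) -> np.ndarray:
        return clf.predict(_gram(kernel, Xnew_s, Xs, sigma, degree))

    return TrainedClassifier(
        kind="svm", spec={"kernel": kernel, "C": C, "sigma": sigma,
                          "degree": degree},
        classes_=clf.classes_, mean_=mean, sd_=sd, _predict_fn=_predict,
    )


# ---------------------------------------------------------------------------
# random forest


def _oob_trajectory(forest: RandomForestClassifier, X: np.ndarray,
                    y: np.ndarray) -> np.ndarray:
    """OOB misclassification rate after 1..n_trees trees (cumulative vote;
    vote ties resolve to the lowest-indexed class)."""
    n = X.shape[0]
    classes = forest.classes_
    class_idx = {c: i for i, c in enumerate(classes)}
    yi = np.array([class_idx[v] for v in y])
    votes = np.zeros((n, classes.size), dtype=np.int64)
    seen = np.zeros(n, dtype=bool)
    errs = np.empty(len(forest.estimators_))
    for t, tree in enumerate(forest.estimators_):
        oob = oob_indices(tree, n)
        if oob.size:
            pred = tree.predict(X[oob]).astype(int)
            votes[oob, pred] += 1
            seen[oob] = True
        if seen.any():
            current = votes[seen].argmax(axis=1)
            errs[t] = float(np.mean(current != yi[seen]))
        else:
            errs[t] = np.nan
    return errs


def train_rf(X, y, n_trees: int = 1000, mtry: int = 2, seed: int = 0,
             compute_trajectory: bool = True) -> TrainedClassifier:
    """Bagged decision forest with ``mtry`` candidate features per split."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if mtry > X.shape[1]:
        raise InvalidArgumentError(
            f"mtry={mtry} exceeds the {X.shape[1]} available features")
    forest = RandomForestClassifier(
        n_estimators=int(n_trees), max_features=int(mtry), n_jobs=1,
        random_state=stream_seed(seed, "rf"),
    ).fit(X, y)
    extra = {}
    if compute_trajectory:
        traj = _oob_trajectory(forest, X, y)
        extra["oob_trajectory"] = traj
        extra["oob_error"] = float(traj[-1])
    return TrainedClassifier(
        kind="rf", spec={"n_trees": int(n_trees), "mtry": int(mtry)},
        classes_=forest.classes_, mean_=None, sd_=None,
        _predict_fn=forest.predict, extra=extra,
    )


# ---------------------------------------------------------------------------
# neural network


def _ann_unpack(w: np.ndarray, p: int, h: int, c: int):
    i = 0
    W1 = w[i:i + p * h].reshape(p, h); i += p * h
    b1 = w[i:i + h]; i += h
    W2 = w[i:i + h * c].reshape(h, c); i += h * c
    b2 = w[i:i + c]
    return W1, b1, W2, b2


def _ann_loss_grad(w, X, Y, decay, p, h, c):
    W1, b1, W2, b2 = _ann_unpack(w, p, h, c)
    z1 = X @ W1 + b1
    hid = expit(z1)
    z2 = hid @ W2 + b2
    z2 -= z2.max(axis=1, keepdims=True)
    ez = np.exp(z2)
    prob = ez / ez.sum(axis=1, keepdims=True)
    loss = -np.sum(Y * np.log(np.maximum(prob, 1e-300))) + decay * np.sum(w * w)
    dz2 = prob - Y
    dW2 = hid.T @ dz2 + 2 * decay * W2
    db2 = dz2.sum(axis=0) + 2 * decay * b2
    dhid = dz2 @ W2.T
    dz1 = dhid * hid * (1.0 - hid)
    dW1 = X.T @ dz1 + 2 * decay * W1
    db1 = dz1.sum(axis=0) + 2 * decay * b1
    grad = np.concatenate([dW1.ravel(), db1, dW2.ravel(), db2])
    return loss, grad


def train_ann(X, y, hidden_units: int = 14, weight_decay: float = 1.0,
              seed: int = 0, restarts: int = 5,
              maxiter: int = 500) -> TrainedClassifier:
    """Single-hidden-layer network (sigmoid hidden, softmax output)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if hidden_units < 1 or weight_decay < 0:
        raise InvalidArgumentError("need hidden_units >= 1 and decay >= 0")
    classes = np.unique(y)
    mean, sd = _fit_scaler(X)
    Xs = (X - mean) / sd
    Y = (y[:, None] == classes[None, :]).astype(np.float64)
    p, h, c = Xs.shape[1], int(hidden_units), classes.size
    n_par = p * h + h + h * c + c

    best = None
    any_converged = False
    for r in range(restarts):
        rng = substream(seed, "ann", r)
        w0 = rng.uniform(-0.7, 0.7, n_par)
        res = minimize(_ann_loss_grad, w0, args=(Xs, Y, weight_decay, p, h, c),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        warnings.warn("no ANN restart reported convergence; keeping the "
                      "best-effort weights", RuntimeWarning)
    W1, b1, W2, b2 = _ann_unpack(best.x, p, h, c)

    def _predict(Xnew_s: np.ndarray) -> np.ndarray:
        hid = expit(Xnew_s @ W1 + b1)
        return classes[np.argmax(hid @ W2 + b2, axis=1)]

    def _proba(Xnew: np.ndarray) -> np.ndarray:
        Xn = (np.asarray(Xnew, dtype=np.float64) - mean) / sd
        z2 = expit(Xn @ W1 + b1) @ W2 + b2
        z2 -= z2.max(axis=1, keepdims=True)
        ez = np.exp(z2)
        return ez / ez.sum(axis=1, keepdims=True)

    return TrainedClassifier(
        kind="ann", spec={"hidden_units": h, "weight_decay": weight_decay},
        classes_=classes, mean_=mean, sd_=sd, _predict_fn=_predict,
        extra={"loss": float(best.fun), "converged": any_converged,
               "weights": best.x, "predict_proba": _proba,
               "weight_norm": float(np.linalg.norm(best.x))},
    )


# ---------------------------------------------------------------------------
# grid selection


def default_svm_grid() -> list[dict]:
    return [{"kernel": k, "C": c}
            for k in ("linear", "laplacian", "gaussian", "anova_rbf")
            for c in range(1, 11)]


def default_rf_grid(n_trees_options=(500, 1000), mtry_options=(1, 2, 3)
                    ) -> list[dict]:
    return [{"n_trees": t, "mtry": m}
            for t in n_trees_options for m in mtry_options]


def default_ann_grid() -> list[dict]:
    decays = sorted([2.0, 1.0, 0.5, 0.25, 0.125, 0.0625])
    return [{"hidden_units": u, "weight_decay": d}
            for u in range(10, 16) for d in decays]


_TRAINERS = {"svm": train_svm, "rf": train_rf, "ann": train_ann}


def _check_folds(y: np.ndarray, folds: int) -> None:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise StratificationError(
            f"smallest class ({counts.min()}) cannot fill {folds} folds")


def cv_select(model_kind: str, grid: list[dict], X, y, folds: int = 4,
              seed: int = 0, ann_restarts: int = 2,
              rf_cv_trees: int | None = None) -> tuple[dict, pd.DataFrame]:
    """Grid selection: SVM by mean CV error, ANN by mean CV accuracy, RF by
    OOB error (no outer folds).  Ties resolve to the first grid entry, with
    grids ordered smallest-C / fewest-units-smallest-decay / fewest-trees."""
    if model_kind not in _TRAINERS:
        raise InvalidArgumentError(f"unknown model kind {model_kind!r}")
    if folds < 2:
        raise InvalidArgumentError("folds must be >= 2")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    rows = []

    if model_kind == "rf":
        for g in grid:
            clf = train_rf(X, y, seed=seed, compute_trajectory=True, **g)
            rows.append({**g, "oob_error": clf.extra["oob_error"],
                         "score": clf.extra["oob_error"]})
        table = pd.DataFrame(rows)
        best = grid[int(table["score"].to_numpy().argmin())]
        return best, table

    _check_folds(y, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=stream_seed(seed, "cv-folds"))
    splits = list(skf.split(X, y))
    for g in grid:
        fold_scores = []
        for f, (tr, te) in enumerate(splits):
            if model_kind == "svm":
                clf = train_svm(X[tr], y[tr], seed=stream_seed(seed, "cv", f), **g)
                fold_scores.append(float(np.mean(clf.predict(X[te]) != y[te])))
            else:
                clf = train_ann(X[tr], y[tr], seed=stream_seed(seed, "cv", f),
                                restarts=ann_restarts, **g)
                fold_scores.append(float(np.mean(clf.predict(X[te]) == y[te])))
        row = {**g}
        for f, s in enumerate(fold_scores):
            row[f"fold{f}"] = s
        row["mean"] = float(np.mean(fold_scores))
        row["score"] = row["mean"]
        rows.append(row)
    table = pd.DataFrame(rows)
    scores = table["score"].to_numpy()
    best_i = int(scores.argmin()) if model_kind == "svm" else int(scores.argmax())
    return grid[best_i], table


# ---------------------------------------------------------------------------
# statsmodels-style facade


class SubtypeClassifier:
    """A subtype-classification model over a feature table.

    Parameters
    ----------
    X : DataFrame or array, cases x features (the selected feature set).
    y : array of class labels.
    kind : {'svm', 'rf', 'ann'}.
    grid : hyperparameter grid; ``None`` uses the family default.
    """

    def __init__(self, X, y, kind: str = "rf", grid: list[dict] | None = None,
                 folds: int = 4, seed: int = 0):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            self.X = X.to_numpy(dtype=np.float64)
        else:
            self.X = np.asarray(X, dtype=np.float64)
            self.feature_names = [f"x{i}" for i in range(self.X.shape[1])]
        self.y = np.asarray(y)
        if kind not in _TRAINERS:
            raise InvalidArgumentError(f"unknown model kind {kind!r}")
        self.kind = kind
        if grid is None:
            grid = {"svm": default_svm_grid, "rf": default_rf_grid,
                    "ann": default_ann_grid}[kind]()
        self.grid = grid
        self.folds = folds
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       features: list[str] | None = None, **kwargs
                       ) -> "SubtypeClassifier":
        feats = features or [c for c in df.columns if c != label_col]
        return cls(df[feats], df[label_col].to_numpy(), **kwargs)

    def fit(self, **cv_kwargs) -> "SubtypeClassifierResults":
        spec, cv_table = cv_select(self.kind, self.grid, self.X, self.y,
                                   folds=self.folds, seed=self.seed,
                                   **cv_kwargs)
        clf = _TRAINERS[self.kind](self.X, self.y, seed=self.seed, **spec)
        return SubtypeClassifierResults(self, spec, cv_table, clf)


class SubtypeClassifierResults:
    """Fitted classifier with its selected spec and CV table."""

    def __init__(self, model: SubtypeClassifier, spec: dict,
                 cv_table: pd.DataFrame, classifier: TrainedClassifier):
        self.model = model
        self.spec = spec
        self.cv_table = cv_table
        self.classifier = classifier

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.model.feature_names].to_numpy(dtype=np.float64)
        return self.classifier.predict(X)

    def evaluate(self, X, y, class_order=None
                 ) -> tuple[ConfusionMatrix, MetricsReport]:
        order = class_order or tuple(sorted(np.unique(self.model.y)))
        cm = confusion(list(np.asarray(y)), list(self.predict(X)), order)
        return cm, metrics(cm)

    def summary(self) -> str:
        cm, rep = self.evaluate(self.model.X, self.model.y)
        lines = [
            f"SubtypeClassifier ({self.model.kind.upper()})",
            f"  n = {len(self.model.y)}, features = {len(self.model.feature_names)}",
            f"  selected spec: {self.spec}",
            f"  grid points evaluated: {len(self.cv_table)}",
            f"  training overall accuracy: {rep.overall_accuracy:.4f}",
            "",
            rep.to_dataframe().to_string(),
        ]
        return "\n".join(lines)
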