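"""All-relevant feature selection against shuffled shadow attributes.

Each iteration shuffles every feature column independently to build
"shadow" attributes, fits a random forest on the combined
[originals | shadows] design, and scores a hit for every undecided original
whose importance exceeds the best shadow importance.  Hit counts are tested
against Binomial(iterations, 1/2) two-sidedly with Bonferroni correction:
features significantly above 1/2 are confirmed, significantly below are
rejected; decided features leave the testing pool and whatever is undecided
at the iteration cap stays tentative.  The full shadow ensemble stays in
the design throughout, so the importance bar remains the maximum over all
shadows even late in the run — with only a handful of shadows the race
becomes too easy and spuriously correlated noise gets confirmed.

Importance is the out-of-bag permutation importance as a Z-score: the mean
per-tree decrease in OOB accuracy when a column is permuted, divided by its
standard error over trees (the scaling used by classic random-forest
permutation importance).  Per-tree drops are computed with one batched
prediction per tree so the shadow race stays fast enough for resampling
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from ._forest_utils import oob_indices
from .errors import InvalidLabelsError
from .rng import stream_seed, substream

__all__ = ["BorutaResult", "boruta_select"]


@dataclass
class BorutaResult:
    status: dict[str, str]            # feature -> {confirmed, tentative, rejected}
    hits: dict[str, int]
    n_iterations: int
    alpha: float
    importance_history: dict[str, list[float]] = field(default_factory=dict)

    @property
    def confirmed(self) -> list[str]:
        return [f for f, s in self.status.items() if s == "confirmed"]

    @property
    def rejected(self) -> list[str]:
        return [f for f, s in self.status.items() if s == "rejected"]

    @property
    def tentative(self) -> list[str]:
        return [f for f, s in self.status.items() if s == "tentative"]


def _oob_permutation_importance(forest, X: np.ndarray, y: np.ndarray,
                                rng: np.random.Generator) -> np.ndarray:
    """Z-scored mean decrease in per-tree OOB accuracy under permutation."""
    n, p = X.shape
    # individual trees predict encoded class indices in forest.classes_ order
    class_idx = {c: i for i, c in enumerate(forest.classes_)}
    y_enc = np.array([class_idx[v] for v in y])
    drops = []
    for tree in forest.estimators_:
        oob = oob_indices(tree, n)
        if oob.size < 2:
            continue
        Xo, yo = X[oob], y_enc[oob]
        base = np.mean(tree.predict(Xo) == yo)
        perm = rng.permutation(oob.size)
        big = np.repeat(Xo[None, :, :], p, axis=0)
        for j in range(p):
            big[j, :, j] = Xo[perm, j]
        pred = tree.predict(big.reshape(p * oob.size, p))
        acc = (pred.reshape(p, oob.size) == yo[None, :]).mean(axis=1)
        drops.append(base - acc)
    D = np.asarray(drops)
    if D.shape[0] < 2:
        return D.sum(axis=0)
    sd = D.std(axis=0, ddof=1)
    sd = np.where(sd > 1e-12, sd, 1e-12)
    return D.mean(axis=0) / (sd / np.sqrt(D.shape[0]))


def boruta_select(
    X,
    feature_names: list[str] | None = None,
    y=None,
    alpha: float = 0.01,
    max_iter: int = 100,
    n_estimators: int = 100,
    seed: int = 0,
) -> BorutaResult:
    """Run the shadow-attribute selection on a feature matrix or DataFrame."""
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=np.float64)
    else:
        Xa = np.asarray(X, dtype=np.float64)
        names = (list(feature_names) if feature_names is not None
                 else [f"f{i}" for i in range(Xa.shape[1])])
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise InvalidLabelsError("need at least two classes")
    if Xa.shape[1] < 2:
        raise InvalidLabelsError("need at least two features")

    m = Xa.shape[1]
    status = {f: "tentative" for f in names}
    hits = {f: 0 for f in names}
    history: dict[str, list[float]] = {f: [] for f in names}
    undecided = list(names)
    rng = substream(seed, "boruta")
    n_done = 0

    for it in range(1, max_iter + 1):
        if not undecided:
            break
        # full design every iteration: all originals + fresh shadows of all
        shadows = Xa.copy()
        for j in range(m):
            shadows[:, j] = shadows[rng.permutation(len(shadows)), j]
        design = np.hstack([Xa, shadows])
        forest = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt", n_jobs=1,
            random_state=stream_seed(seed, "boruta-rf", it),
        ).fit(design, y)
        imp = _oob_permutation_importance(forest, design, y, rng)
        real_imp = imp[:m]
        shadow_max = imp[m:].max()
        for f, v in zip(names, real_imp):
            history[f].append(float(v))
            if status[f] == "tentative" and v > shadow_max:
                hits[f] += 1
        n_done = it

        # binomial decisions with Bonferroni over the original feature count
        thr = alpha / m
        still = []
        for f in undecided:
            p_hi = stats.binom.sf(hits[f] - 1, it, 0.5)
            p_lo = stats.binom.cdf(hits[f], it, 0.5)
            if p_hi < thr:
                status[f] = "confirmed"
            elif p_lo < thr:
                status[f] = "rejected"
            else:
                still.append(f)
        undecided = still

    return BorutaResult(status=status, hits=hits, n_iterations=n_done,
                        alpha=alpha, importance_history=history)
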