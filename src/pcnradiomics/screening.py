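"""Feature-space reduction: robustness, redundancy, significance, Boruta.

The stages run in a fixed order and each one only ever removes features, so
the survivor sets are nested:

1. robustness — ICC(2,1) (two-way random effects, absolute agreement,
   single measurement) of each feature across the three segmentations;
   keep features with ICC above 0.75;
2. redundancy — greedy Pearson pruning until no surviving pair has
   |r| > 0.75;
3. significance — Kruskal-Wallis across the three subtypes for radiomics
   features and continuous clinical factors, chi-squared / corrected
   chi-squared / Fisher for categorical clinical factors, at alpha = 0.05;
4. all-relevant selection — the shadow-attribute race (see ``boruta``) on
   the significant radiomics features joined with the significant clinical
   factors (categoricals integer-coded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .boruta import BorutaResult, boruta_select
from .errors import DegenerateTableError, InvalidArgumentError
from .rng import substream

__all__ = [
    "IccResult",
    "ScreeningConfig",
    "ScreeningReport",
    "icc_screen",
    "icc_2_1",
    "correlation_prune",
    "kruskal_wallis",
    "categorical_test",
    "screen_pipeline",
    "CONTINUOUS_CLINICAL",
    "CATEGORICAL_CLINICAL",
    "encode_clinical",
]

CONTINUOUS_CLINICAL = ("age", "max_diameter", "ca199", "cea", "alt", "ast",
                       "fbg", "platelet", "alb", "afp", "sf")
CATEGORICAL_CLINICAL = ("sex", "location", "blood_type", "calcification",
                        "abdominal_symptom", "smoking", "alcohol", "obesity",
                        "chronic_pancreatitis", "family_history")


@dataclass
class IccResult:
    feature: str
    estimate: float
    kept: bool


@dataclass(frozen=True)
class ScreeningConfig:
    icc_threshold: float = 0.75
    corr_threshold: float = 0.75
    alpha: float = 0.05
    boruta_alpha: float = 0.01
    boruta_max_iter: int = 100
    boruta_trees: int = 100
    seed: int = 0


@dataclass
class ScreeningReport:
    icc: dict[str, IccResult]
    robust: list[str]
    decorrelated: list[str]
    significant: list[str]
    feature_pvalues: dict[str, float]
    clinical_significant: list[str]
    clinical_tests: dict[str, tuple[str, float, float]]  # name -> (test, stat, p)
    boruta: BorutaResult | None
    selected: list[str]
    notes: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "robust": len(self.robust),
            "decorrelated": len(self.decorrelated),
            "significant": len(self.significant),
            "clinical_significant": len(self.clinical_significant),
            "selected": len(self.selected),
        }


# ---------------------------------------------------------------------------
# ICC


def icc_2_1(data: np.ndarray) -> float:
    """ICC(2,1) from the two-way ANOVA mean squares of an (n x k) array."""
    data = np.asarray(data, dtype=np.float64)
    n, k = data.shape
    grand = data.mean()
    row_m = data.mean(axis=1)
    col_m = data.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 0.0
    return float((msr - mse) / denom)


def icc_screen(tables: list[pd.DataFrame], threshold: float = 0.75
               ) -> dict[str, IccResult]:
    """Per-feature ICC(2,1) across k segmentations (rows = patients)."""
    if len(tables) < 2:
        raise InvalidArgumentError("need at least two feature tables")
    base = tables[0]
    for t in tables[1:]:
        if not (t.index.equals(base.index) and list(t.columns) == list(base.columns)):
            raise InvalidArgumentError("tables must share patients and features")
    out = {}
    for col in base.columns:
        data = np.column_stack([t[col].to_numpy(dtype=np.float64) for t in tables])
        est = icc_2_1(data)
        out[col] = IccResult(col, est, bool(est > threshold))
    return out


# ---------------------------------------------------------------------------
# correlation pruning


def correlation_prune(table: pd.DataFrame, threshold: float = 0.75
                      ) -> list[str]:
    """Greedy removal until every surviving pair satisfies |r| <= threshold.

    Repeatedly find the pair with the largest |r|; of that pair drop the
    feature with the larger mean absolute correlation to all remaining
    features (lexicographic name on ties).  Constant features have undefined
    correlation and are treated as uncorrelated (|r| = 0).
    """
    if table.shape[1] < 2:
        raise InvalidArgumentError("need at least two features to prune")
    cols = list(table.columns)
    X = table.to_numpy(dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(X, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)

    alive = list(range(len(cols)))
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= threshold:
            break
        a, b = np.unravel_index(np.argmax(sub), sub.shape)
        ia, ib = alive[a], alive[b]
        mean_a = corr[ia, alive].sum() / (len(alive) - 1)
        mean_b = corr[ib, alive].sum() / (len(alive) - 1)
        if mean_a > mean_b:
            drop = ia
        elif mean_b > mean_a:
            drop = ib
        else:
            drop = max(ia, ib, key=lambda i: cols[i])
        alive.remove(drop)
    return [cols[i] for i in alive]


# ---------------------------------------------------------------------------
# univariate tests


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Rank-based H test with tie correction; p from chi-square (k-1 df)."""
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if any(len(s) == 0 for s in samples):
        raise InvalidArgumentError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def _log_table_prob(table: np.ndarray) -> float:
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum()
                 - gammaln(n + 1) - gammaln(table + 1).sum())


def _fisher_rxc_montecarlo(table: np.ndarray, n_sim: int, rng) -> float:
    """Fisher-rule p for an r x c table by Monte Carlo over fixed margins."""
    obs = _log_table_prob(table)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0), seed=rng)
    sims = dist.rvs(n_sim)
    lp = np.array([_log_table_prob(t) for t in sims])
    hits = int(np.sum(lp <= obs + 1e-9))
    return (hits + 1) / (n_sim + 1)


def categorical_test(counts, seed: int = 0, n_sim: int = 9999
                     ) -> tuple[str, float, float]:
    """Choose and run the appropriate contingency-table test.

    Plain chi-square when all expected counts are >= 5; Fisher's exact test
    when any expected count is < 1 or (2x2 with any expected < 5 and total
    < 40); otherwise the continuity-corrected chi-square for 2x2 tables and
    plain chi-square for larger ones.  Fisher p-values for tables larger
    than 2x2 are Monte Carlo estimates over tables with the observed margins.
    Returns (test name, statistic, p).
    """
    table = np.asarray(counts, dtype=np.int64)
    if table.ndim != 2 or (table < 0).any():
        raise InvalidArgumentError("counts must be a non-negative 2D table")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise DegenerateTableError("contingency table has an empty row/column")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    is2x2 = table.shape == (2, 2)

    if (expected < 1).any() or (is2x2 and (expected < 5).any() and n < 40):
        if is2x2:
            res = stats.fisher_exact(table)
            return "fisher", float(res.statistic), float(res.pvalue)
        p = _fisher_rxc_montecarlo(table, n_sim, substream(seed, "fisher-mc"))
        return "fisher-mc", float("nan"), p
    if (expected >= 5).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return "chi-square", float(chi2), float(p)
    if is2x2:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        return "corrected-chi-square", float(chi2), float(p)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi-square", float(chi2), float(p)


# ---------------------------------------------------------------------------
# clinical encoding and the full screen


def encode_clinical(clinical: pd.DataFrame, columns) -> pd.DataFrame:
    """Integer-code the requested clinical columns for forest-based models."""
    out = pd.DataFrame(index=clinical.index)
    for c in columns:
        s = clinical[c]
        if s.dtype == bool or c in CATEGORICAL_CLINICAL:
            codes = pd.Categorical(s.astype(str),
                                   categories=sorted(s.astype(str).unique())).codes
            out[c] = codes.astype(np.float64)
        else:
            out[c] = s.astype(np.float64)
    return out


def screen_pipeline(
    tables: list[pd.DataFrame],
    clinical: pd.DataFrame,
    labels,
    config: ScreeningConfig = ScreeningConfig(),
) -> ScreeningReport:
    """Run all four screening stages in order and record survivors."""
    labels = np.asarray(labels)
    notes: list[str] = []
    icc = icc_screen(tables, config.icc_threshold)
    robust = [f for f, r in icc.items() if r.kept]

    base = tables[0]
    if len(robust) >= 2:
        decorrelated = correlation_prune(base[robust], config.corr_threshold)
    else:
        decorrelated = list(robust)

    feature_p = {}
    significant = []
    for f in decorrelated:
        _, p = kruskal_wallis(base[f].to_numpy(), labels)
        feature_p[f] = p
        if p < config.alpha:
            significant.append(f)

    clinical_tests = {}
    clinical_sig = []
    for c in CONTINUOUS_CLINICAL:
        if c not in clinical.columns:
            continue
        h, p = kruskal_wallis(clinical[c].to_numpy(dtype=np.float64), labels)
        clinical_tests[c] = ("kruskal-wallis", h, p)
        if p < config.alpha:
            clinical_sig.append(c)
    for c in CATEGORICAL_CLINICAL:
        if c not in clinical.columns:
            continue
        tab = pd.crosstab(clinical[c].astype(str), pd.Series(labels, index=clinical.index))
        tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2:
            clinical_tests[c] = ("degenerate", float("nan"), 1.0)
            notes.append(f"clinical factor {c} has a single observed category")
            continue
        name, stat, p = categorical_test(tab.to_numpy(), seed=config.seed)
        clinical_tests[c] = (name, stat, p)
        if p < config.alpha:
            clinical_sig.append(c)

    boruta_res = None
    selected: list[str] = []
    pool = significant + clinical_sig
    if len(pool) >= 2:
        design = pd.concat(
            [base[significant], encode_clinical(clinical, clinical_sig)], axis=1
        )
        boruta_res = boruta_select(
            design, y=labels, alpha=config.boruta_alpha,
            max_iter=config.boruta_max_iter,
            n_estimators=config.boruta_trees, seed=config.seed,
        )
        selected = boruta_res.confirmed
    else:
        notes.append("fewer than two significant features; Boruta skipped")

    return ScreeningReport(
        icc=icc, robust=robust, decorrelated=decorrelated,
        significant=significant, feature_pvalues=feature_p,
        clinical_significant=clinical_sig, clinical_tests=clinical_tests,
        boruta=boruta_res, selected=selected, notes=notes,
    )
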