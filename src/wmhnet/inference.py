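"""Group statistics: normality-gated two-sample tests with FDR control,
age-adjusted logistic effects, partial correlation with covariates, and
rater-reliability indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "PartialCorrelation",
    "ReliabilityStats",
    "AgeAdjustedEffect",
    "normality_gate",
    "compare_groups",
    "apply_fdr",
    "fdr_adjust",
    "chi_square_test",
    "age_adjusted_group_effect",
    "partial_correlation",
    "pearson_with_p",
    "rater_reliability",
    "run_group_analysis",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    """One metric's two-group test with distribution-appropriate summaries."""

    metric_name: str
    group_a_summary: str
    group_b_summary: str
    test_used: str
    statistic: float
    p_raw: float
    p_fdr: float | None = None
    significant: bool | None = None
    group_a_values: np.ndarray = field(default=None, repr=False)
    group_b_values: np.ndarray = field(default=None, repr=False)


@dataclass(frozen=True)
class PartialCorrelation:
    x_name: str
    y_name: str
    covariate_names: tuple[str, ...]
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.n - 2 - len(self.covariate_names) < 1:
            raise ValueError(
                f"n={self.n} leaves no degrees of freedom with {len(self.covariate_names)} covariates"
            )


@dataclass(frozen=True)
class ReliabilityStats:
    kappa: float
    cronbach_alpha: float
    degenerate: bool = False


@dataclass(frozen=True)
class AgeAdjustedEffect:
    coefficient: float
    p: float
    separation_flag: bool = False


def _as_1d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(arr).all():
        raise ValueError("input contains non-finite values")
    return arr


def normality_gate(sample_a, sample_b, alpha: float = ALPHA) -> str:
    """Choose ``t_test`` iff both samples pass Shapiro–Wilk at ``alpha``.

    Degenerate (constant) samples, for which the normality test is
    undefined, route to the nonparametric branch.
    """
    a, b = _as_1d(sample_a), _as_1d(sample_b)
    if min(a.size, b.size) < 3:
        raise ValueError("normality gate needs at least 3 observations per group")
    for sample in (a, b):
        if np.ptp(sample) == 0:
            return "mann_whitney_u"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stats.shapiro(sample).pvalue <= alpha:
                return "mann_whitney_u"
    return "t_test"


def _summary(sample: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{sample.mean():.3f} ± {sample.std(ddof=1):.3f}"
    q1, med, q3 = np.percentile(sample, [25, 50, 75])
    return f"{med:.3f} ({q3 - q1:.3f})"


def compare_groups(values_a, values_b, metric_name: str = "") -> GroupComparison:
    """Two-sided Welch t-test or Mann–Whitney U, per the normality gate."""
    a, b = _as_1d(values_a), _as_1d(values_b)
    test = normality_gate(a, b)
    if test == "t_test":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        metric_name=metric_name,
        group_a_summary=_summary(a, test == "t_test"),
        group_b_summary=_summary(b, test == "t_test"),
        test_used=test,
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        group_a_values=a,
        group_b_values=b,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def apply_fdr(comparisons: list[GroupComparison], alpha: float = ALPHA) -> list[GroupComparison]:
    """Fill ``p_fdr`` and ``significant`` across one family of comparisons."""
    adjusted = fdr_adjust([c.p_raw for c in comparisons])
    for comp, p_adj in zip(comparisons, adjusted):
        comp.p_fdr = float(p_adj)
        comp.significant = bool(p_adj < alpha)
    return comparisons


def chi_square_test(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("contingency table must hold nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def age_adjusted_group_effect(metric_values, group_labels, age) -> AgeAdjustedEffect:
    """Logistic regression of group membership on {metric, age}; returns the
    metric's coefficient and Wald p.  Perfect separation is flagged, not raised.
    """
    import statsmodels.api as sm

    y = pd.Series(group_labels).astype("category").cat.codes.to_numpy()
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two groups")
    metric = _as_1d(metric_values)
    age_arr = _as_1d(age)
    if metric.size < 10:
        raise ValueError("need at least 10 observations")
    x = sm.add_constant(np.column_stack([metric, age_arr]), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        except Exception:
            return AgeAdjustedEffect(float("nan"), float("nan"), separation_flag=True)
    coef, p = float(fit.params[1]), float(fit.pvalues[1])
    flagged = not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e4
    return AgeAdjustedEffect(coef, p, separation_flag=flagged)


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_correlation(
    x,
    y,
    covariates=None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: tuple[str, ...] | None = None,
) -> PartialCorrelation:
    """Pearson correlation of the OLS residuals of x and y on the covariates.

    p-value from t = r * sqrt(df / (1 - r^2)) with df = n - 2 - k.
    """
    x, y = _as_1d(x), _as_1d(y)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match n")
    k = cov.shape[1]
    names = tuple(covariate_names) if covariate_names else tuple(f"c{i + 1}" for i in range(k))
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix (with intercept) is rank deficient")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("residual with zero variance; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clip = min(abs(r), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * stats.t.sf(t, df))
    return PartialCorrelation(x_name, y_name, names, r, p, n)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-based p-value."""
    x, y = _as_1d(x), _as_1d(y)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def rater_reliability(ratings_a, ratings_b) -> ReliabilityStats:
    """Cohen's kappa from the raters' cross-tabulation plus Cronbach's alpha
    over the two-column item matrix.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.size != b.size or a.size == 0:
        raise ValueError("rating vectors must be nonempty and equal length")
    cats = np.unique(np.concatenate([a, b]))
    if cats.size == 1:
        return ReliabilityStats(float("nan"), float("nan"), degenerate=True)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((cats.size, cats.size))
    for ai, bi in zip(a, b):
        table[idx[ai], idx[bi]] += 1
    n = table.sum()
    po = np.trace(table) / n
    pe = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    kappa = 1.0 if pe == 1.0 else (po - pe) / (1.0 - pe)

    items = np.column_stack([a.astype(float), b.astype(float)])
    k = items.shape[1]
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        alpha = float("nan")
    else:
        alpha = k / (k - 1) * (1.0 - items.var(axis=0, ddof=1).sum() / total_var)
    return ReliabilityStats(float(kappa), float(alpha))


def _comparison_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metric": [c.metric_name for c in comparisons],
            "group_a": [c.group_a_summary for c in comparisons],
            "group_b": [c.group_b_summary for c in comparisons],
            "test": [c.test_used for c in comparisons],
            "statistic": [c.statistic for c in comparisons],
            "p_raw": [c.p_raw for c in comparisons],
            "p_fdr": [c.p_fdr for c in comparisons],
            "significant": [c.significant for c in comparisons],
        }
    )


def run_group_analysis(
    subjects: pd.DataFrame,
    global_summaries: pd.DataFrame,
    nodal_e: pd.DataFrame,
    nodal_eloc: pd.DataFrame,
    alpha: float = ALPHA,
) -> dict[str, pd.DataFrame]:
    """Full statistical layer over per-subject network metrics.

    Parameters
    ----------
    subjects
        Subjects table indexed by subject_id with at least ``group``,
        ``wmh_volume_ml``, ``age``, ``sex``, ``education_years``, ``moca``,
        ``mmse`` columns.
    global_summaries
        subject x metric table of across-threshold global summaries
        (gamma, lambda_, sigma, cp, lp, eglob, eloc).
    nodal_e, nodal_eloc
        subject x node tables of across-threshold nodal efficiency means.

    Returns tables: ``global`` (one row per global metric, FDR over that
    family), ``nodal`` (one row per node, FDR over nodes), ``volume``
    (lesion volume vs per-node local efficiency), and ``cognition``
    (partial correlations of FDR-significant nodes' efficiency with MoCA
    and MMSE, controlling age, sex, education).
    """
    required = ["group", "wmh_volume_ml", "age", "sex", "education_years", "moca", "mmse"]
    missing = [c for c in required if c not in subjects.columns]
    if missing:
        raise ValueError(f"subjects table missing columns: {missing}")
    from wmhnet.metrics import GLOBAL_METRICS

    missing_metrics = [m for m in GLOBAL_METRICS if m not in global_summaries.columns]
    if missing_metrics:
        raise ValueError(f"global summaries missing columns: {missing_metrics}")
    subjects = subjects.loc[global_summaries.index]
    is_a = (subjects["group"] == "A").to_numpy()
    is_b = (subjects["group"] == "B").to_numpy()
    if not (is_a.any() and is_b.any()):
        raise ValueError("both groups must be present")

    global_comps = [
        compare_groups(global_summaries.loc[is_a, m], global_summaries.loc[is_b, m], m)
        for m in GLOBAL_METRICS
    ]
    apply_fdr(global_comps, alpha)

    nodal_comps = [
        compare_groups(nodal_e.loc[is_a, node], nodal_e.loc[is_b, node], node)
        for node in nodal_e.columns
    ]
    apply_fdr(nodal_comps, alpha)

    volume = pd.DataFrame(
        [
            {"node": node, **dict(zip(("r", "p"), pearson_with_p(subjects["wmh_volume_ml"], nodal_eloc[node])))}
            for node in nodal_eloc.columns
        ]
    )

    sex_codes = subjects["sex"].astype("category").cat.codes.to_numpy(dtype=float)
    covariates = np.column_stack(
        [subjects["age"].to_numpy(dtype=float), sex_codes, subjects["education_years"].to_numpy(dtype=float)]
    )
    cov_names = ("age", "sex", "education_years")
    cognition_rows = []
    for comp in nodal_comps:
        if not comp.significant:
            continue
        node = comp.metric_name
        for score in ("moca", "mmse"):
            pc = partial_correlation(
                nodal_e[node],
                subjects[score],
                covariates,
                x_name=node,
                y_name=score,
                covariate_names=cov_names,
            )
            cognition_rows.append({"node": node, "score": score, "r": pc.r, "p": pc.p, "n": pc.n})
    cognition = pd.DataFrame(cognition_rows, columns=["node", "score", "r", "p", "n"])

    return {
        "global": _comparison_frame(global_comps),
        "nodal": _comparison_frame(nodal_comps),
        "volume": volume,
        "cognition": cognition,
    }
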