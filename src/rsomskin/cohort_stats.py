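"""Cohort statistics over per-subject biomarker tables.

Grouping follows the study's clinical taxonomy — healthy; diabetic with no
complications (NC); low-score (LN, NDS or NSS 1–5) and high-score (HN, NDS or
NSS > 5) neuropathy; neuropathy stratified by atherosclerosis (NnA vs NA).
Two-sample comparisons use an unpaired t test when both groups pass
Shapiro–Wilk normality (α = 0.05) and a Mann–Whitney U test otherwise, with
the conventional star annotation (* p<0.05, ** p<0.01, *** p<0.001).
Spearman correlations, covariate-adjusted logistic regression and a
single-threshold SVN classifier round out the analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("healthy", "NC", "LN", "HN", "NnA", "NA")
DEFAULT_COVARIATES = ("age", "duration_y", "hba1c", "bmi")

#: Mann–Whitney: exact null distribution up to this product of sample sizes
MW_EXACT_MAX_PRODUCT = 64


def stars(p: float) -> str:
    """Significance annotation: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def assign_group(diabetic: bool, nds: int | None = None, nss: int | None = None,
                 ascvd: bool = False) -> str:
    """Primary group of one subject: healthy / NC / LN / HN.

    HN (NDS > 5 or NSS > 5) takes precedence over LN (NDS 1–5 or NSS 1–5)
    when both disjunctions hold.  Diabetic subjects need both neuropathy
    scores; a diabetic subject with ASCVD but no neuropathy falls outside the
    study taxonomy and is rejected.
    """
    if not diabetic:
        return "healthy"
    if nds is None or nss is None:
        raise ValueError("diabetic subjects require NDS and NSS scores")
    if not (0 <= nds <= 10 and 0 <= nss <= 10):
        raise ValueError(f"scores out of range: NDS={nds}, NSS={nss}")
    if nds > 5 or nss > 5:
        return "HN"
    if 1 <= nds <= 5 or 1 <= nss <= 5:
        return "LN"
    if ascvd:
        raise ValueError("diabetic subject with ASCVD but no neuropathy has no group")
    return "NC"


def atherosclerosis_stratum(group: str, ascvd: bool) -> str | None:
    """NnA/NA stratification among neuropathic subjects; None otherwise."""
    if group in ("LN", "HN", "NA"):
        return "NA" if ascvd else "NnA"
    return None


# ---------------------------------------------------------------------------
# two-sample comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    test: str            # "unpaired t" or "Mann-Whitney U"
    statistic: float
    p_value: float
    star: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


def mannwhitney_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (statistic, p): exact null distribution when
    n₁·n₂ ≤ 64 and there are no cross-sample ties, normal approximation with
    tie and continuity correction otherwise."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) * len(b) <= MW_EXACT_MAX_PRODUCT and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups(a, b, test: str = "auto", alpha_normality: float = 0.05
                   ) -> GroupComparison:
    """Two-sample comparison with a normality-gated test choice.

    ``test="auto"`` runs Shapiro–Wilk on both groups and picks the unpaired
    t test when both pass at ``alpha_normality``, the Mann–Whitney U test
    otherwise; ``"t"``/``"mannwhitney"`` force the choice.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")

    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate constant samples: identical → p = 1, else complete separation
        if a[0] == b[0]:
            stat, p, name = 0.0, 1.0, "unpaired t"
        else:
            stat, p = mannwhitney_p(a, b)
            name = "Mann-Whitney U"
    else:
        if test == "auto":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normal = all(
                    np.ptp(x) > 0 and stats.shapiro(x).pvalue > alpha_normality
                    for x in (a, b)
                )
            test = "t" if normal else "mannwhitney"
        if test == "t":
            res = stats.ttest_ind(a, b, equal_var=True)
            stat, p, name = float(res.statistic), float(res.pvalue), "unpaired t"
        elif test == "mannwhitney":
            stat, p = mannwhitney_p(a, b)
            name = "Mann-Whitney U"
        else:
            raise ValueError(f"unknown test {test!r}")

    return GroupComparison(
        test=name, statistic=stat, p_value=p, star=stars(p),
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)) if len(b) > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# correlations and adjusted regression
# ---------------------------------------------------------------------------

def spearman_correlations(table: pd.DataFrame,
                          x_cols=DEFAULT_COVARIATES,
                          y_cols=("tbv_pct", "svn")) -> pd.DataFrame:
    """Spearman rank correlation (tie-corrected) of each covariate against each
    vascular biomarker; constant columns yield missing rho/p."""
    rows = []
    for x in x_cols:
        for y in y_cols:
            sub = table[[x, y]].dropna()
            if len(sub) < 5:
                raise ValueError(f"need >= 5 paired observations for {x} vs {y}")
            if sub[x].nunique() == 1 or sub[y].nunique() == 1:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(sub[x], sub[y])
            rows.append({"x": x, "y": y, "n": len(sub),
                         "rho": rho, "p_value": p,
                         "star": stars(p) if np.isfinite(p) else ""})
    return pd.DataFrame(rows)


def adjusted_logistic(table: pd.DataFrame, outcome: pd.Series | np.ndarray,
                      biomarker: str,
                      covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Covariate-adjusted logistic regression of a binary outcome on one
    biomarker: maximum-likelihood fit, per-term estimate, SE and Wald p.

    Constant covariates are dropped with a warning; (quasi-)perfect separation
    raises with an explicit diagnostic rather than diverging silently.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    terms = [biomarker] + [c for c in covariates if c in table.columns]
    X = table[terms].astype(float).copy()
    for c in list(X.columns):
        if X[c].nunique() <= 1:
            warnings.warn(f"dropping constant covariate {c!r}")
            X = X.drop(columns=c)
    if biomarker not in X.columns:
        raise ValueError(f"biomarker {biomarker!r} is constant")
    X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationWarning, Exception) as exc:  # noqa: BLE001
            if "eparation" in str(type(exc).__name__) + str(exc):
                raise ValueError(
                    f"perfect separation fitting outcome on {biomarker!r}; "
                    "coefficients are unbounded"
                ) from exc
            raise
    out = pd.DataFrame({
        "term": fit.params.index,
        "estimate": fit.params.values,
        "std_err": fit.bse.values,
        "z": fit.tvalues.values,
        "p_value": fit.pvalues.values,
    })
    out["star"] = [stars(p) for p in out["p_value"]]
    return out


# ---------------------------------------------------------------------------
# threshold classifier / ROC
# ---------------------------------------------------------------------------

def rank_auc(values, labels) -> float:
    """AUC via the rank (Mann–Whitney U) identity with tie correction.

    ``labels`` are 1 for the positive (diabetic) class; the classifier calls
    *low* values positive, so AUC = P(value⁺ < value⁻) + ½·P(tie).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(v)  # midranks handle ties
    # U for the positive class on -values == n1*n0 - U on +values
    u_pos_high = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float((n1 * n0 - u_pos_high) / (n1 * n0))


def threshold_roc(values, labels) -> dict:
    """Single-threshold classifier on a biomarker where *lower* means diabetic.

    Returns AUC (rank identity), the accuracy-maximizing threshold, and the
    accuracy/sensitivity/specificity at that threshold (predict diabetic when
    value < threshold).  Percent quantities are on the 0–100 scale.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    auc = rank_auc(v, y)

    uniq = np.unique(v)
    candidates = np.concatenate([[uniq[0] - 1.0],
                                 (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else [],
                                 [uniq[-1] + 1.0]])
    best = None
    for thr in candidates:
        pred = (v < thr).astype(int)
        tp = int(np.sum((pred == 1) & (y == 1)))
        tn = int(np.sum((pred == 0) & (y == 0)))
        acc = (tp + tn) / len(y)
        if best is None or acc > best["accuracy"] / 100.0 + 1e-12:
            best = {
                "auc": auc,
                "best_threshold": float(thr),
                "accuracy": 100.0 * acc,
                "sensitivity": 100.0 * tp / n1,
                "specificity": 100.0 * tn / n0,
            }
    return best


def gaussian_auc(mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float
                 ) -> float:
    """Closed-form AUC Φ(Δµ/√(σ₁²+σ₂²)) for two normal classes (low = positive)."""
    delta = mean_neg - mean_pos
    return float(stats.norm.cdf(delta / np.hypot(sd_pos, sd_neg)))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_groups(table: pd.DataFrame, by: str = "group",
                     columns=None) -> pd.DataFrame:
    """Per-group mean ± SD table (sample SD, ddof=1; single-subject groups
    report SD 0 by convention)."""
    if table.empty:
        raise ValueError("empty table")
    if columns is None:
        columns = [c for c in table.columns
                   if c != by and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for g, sub in table.groupby(by, sort=False):
        row = {by: g, "n": len(sub)}
        for c in columns:
            vals = sub[c].dropna()
            row[f"{c}_mean"] = vals.mean()
            row[f"{c}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
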