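"""Two-group diagnostics for cohort feature tables.

For each histogram feature the soft and hard groups are compared with a
normality-gated two-sample test (Shapiro-Wilk at alpha = 0.05 on both
groups: both normal -> Welch t-test, otherwise Mann-Whitney U, both
two-sided).  Features that differ significantly go on to ROC analysis: the
empirical AUC (trapezoidal, equal to the tie-corrected Mann-Whitney
statistic), a DeLong 95% CI, and the operating point maximizing the Youden
index J = sensitivity + specificity - 1.  Pairs of significant features are
compared with DeLong's test for correlated AUCs.  Interobserver agreement
uses ICC(2,1) (two-way random effects, absolute agreement, single measure)
with Bland-Altman bias and limits of agreement.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = [
    "GroupComparison", "DiagnosticResult", "DeLongResult", "AgreementResult",
    "CohortAnalysis", "compare_groups", "auc_mann_whitney", "roc_analysis",
    "delong_test", "delong_components", "auc_variance",
    "interobserver_agreement", "icc_band", "analyze_cohort",
]

ICC_BANDS = (("poor", 0.21), ("fair", 0.41), ("moderate", 0.61),
             ("good", 0.81), ("excellent", np.inf))


@dataclass(frozen=True)
class GroupComparison:
    feature_name: str
    test_used: str            # "t-test" | "mann-whitney"
    p_value: float
    group_summaries: dict     # per class: mean, sd, median, iqr
    shapiro_p: dict
    flagged: bool = False


@dataclass(frozen=True)
class DiagnosticResult:
    feature_name: str
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    accuracy: float
    ppv: float
    npv: float
    orientation: str          # "higher-is-hard" | "lower-is-hard"
    flagged: bool = False


@dataclass(frozen=True)
class DeLongResult:
    feature_a: str
    feature_b: str
    auc_a: float
    auc_b: float
    z: float
    p_value: float
    var_diff: float = 0.0
    flagged: bool = False


@dataclass(frozen=True)
class AgreementResult:
    feature_name: str
    icc: float
    icc_band: str
    bland_altman_bias: float
    loa_low: float
    loa_high: float
    icc_form: str = "icc2"
    flagged: bool = False


@dataclass
class CohortAnalysis:
    comparisons: list
    diagnostics: list
    delong: list
    n_features_tested: int
    alpha: float
    positive_label: str


def _summaries(values) -> dict:
    values = np.asarray(values, dtype=float)
    q75, q25 = np.percentile(values, [75, 25])
    return {"mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
            "median": float(np.median(values)),
            "iqr": float(q75 - q25)}


def _shapiro_p(values) -> float:
    """Shapiro-Wilk p; constant input is treated as non-normal (p = 0)."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0.0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(values).pvalue)


def compare_groups(soft_values, hard_values, feature_name: str = "",
                   alpha: float = 0.05) -> GroupComparison:
    """Normality-gated two-group comparison (Welch t or Mann-Whitney U)."""
    soft = np.asarray(soft_values, dtype=float)
    hard = np.asarray(hard_values, dtype=float)
    if soft.size < 3 or hard.size < 3:
        raise ValueError("each group needs at least 3 values")
    summaries = {"soft": _summaries(soft), "hard": _summaries(hard)}
    if (np.ptp(soft) == 0.0 and np.ptp(hard) == 0.0
            and soft[0] == hard[0]):
        # both groups one identical constant: no evidence of any difference
        return GroupComparison(feature_name, "t-test", 1.0, summaries,
                               {"soft": float("nan"), "hard": float("nan")},
                               flagged=True)
    sp = {"soft": _shapiro_p(soft), "hard": _shapiro_p(hard)}
    if sp["soft"] > alpha and sp["hard"] > alpha:
        test = "t-test"
        stat = sps.ttest_ind(soft, hard, equal_var=False)
        p = float(stat.pvalue)
    else:
        test = "mann-whitney"
        stat = sps.mannwhitneyu(soft, hard, alternative="two-sided")
        p = float(stat.pvalue)
    return GroupComparison(feature_name, test, p, summaries, sp)


def auc_mann_whitney(values, y) -> float:
    """Empirical AUC as the normalized Mann-Whitney U with ties counted 1/2."""
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=bool)
    pos, neg = values[y], values[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def delong_components(scores, y):
    """DeLong structural components: (auc, v10 per positive, v01 per negative).

    v10[i] is the fraction of negatives the i-th positive outranks (ties
    1/2); v01[j] the fraction of positives the j-th negative is outranked
    by.  Their means both equal the trapezoidal AUC.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=bool)
    pos, neg = scores[y], scores[~y]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tz = sps.rankdata(np.concatenate([pos, neg]))
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


def auc_variance(scores, y) -> float:
    """DeLong variance of a single empirical AUC."""
    _, v10, v01 = delong_components(scores, y)
    var10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    var01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return float(var10 / v10.size + var01 / v01.size)


def _labels_to_bool(labels, positive):
    labels = np.asarray(labels)
    y = labels == positive
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return y


def roc_analysis(values, labels, positive: str = "hard",
                 feature_name: str = "") -> DiagnosticResult:
    """Empirical ROC with DeLong CI and Youden-optimal operating point.

    The score orientation is chosen so that AUC >= 0.5 and recorded.  The
    cutoff is the observed value maximizing J (ties broken toward higher
    specificity); sensitivity/specificity/accuracy/PPV/NPV are evaluated by
    calling a subject positive when its oriented score >= cutoff.
    """
    values = np.asarray(values, dtype=float)
    y = _labels_to_bool(labels, positive)
    auc_raw = auc_mann_whitney(values, y)
    if auc_raw >= 0.5:
        scores, orientation = values, "higher-is-hard"
    else:
        scores, orientation = -values, "lower-is-hard"
    auc = auc_mann_whitney(scores, y)
    var = auc_variance(scores, y)
    half = 1.959963984540054 * np.sqrt(var)
    ci_low = float(np.clip(auc - half, 0.0, 1.0))
    ci_high = float(np.clip(auc + half, 0.0, 1.0))

    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    finite = np.isfinite(thr)
    fpr, tpr, thr = fpr[finite], tpr[finite], thr[finite]
    j = tpr - fpr
    # max J (1e-12 tolerance absorbs float noise in tpr - fpr), ties broken
    # toward higher specificity (lower fpr), then the higher cutoff
    cand = np.flatnonzero(j >= j.max() - 1e-12)
    best = cand[np.lexsort((-thr[cand], fpr[cand]))[0]]
    cutoff_score = float(thr[best])

    pred = scores >= cutoff_score
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    se = tp / (tp + fn)
    sp_ = tn / (tn + fp)
    acc = (tp + tn) / y.size
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    cutoff = cutoff_score if orientation == "higher-is-hard" else -cutoff_score
    flagged = bool(np.ptp(values) == 0.0)
    return DiagnosticResult(
        feature_name=feature_name, auc=auc, auc_ci_low=ci_low,
        auc_ci_high=ci_high, cutoff=float(cutoff), sensitivity=float(se),
        specificity=float(sp_), youden=float(se + sp_ - 1.0),
        accuracy=float(acc), ppv=float(ppv), npv=float(npv),
        orientation=orientation, flagged=flagged)


def delong_test(values_a, values_b, labels, positive: str = "hard",
                feature_a: str = "a", feature_b: str = "b") -> DeLongResult:
    """DeLong's test for the difference of two correlated empirical AUCs.

    Both features must be measured on the same subjects, in the same order.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired features must have equal length")
    y = _labels_to_bool(labels, positive)
    auc_a, v10_a, v01_a = delong_components(a, y)
    auc_b, v10_b, v01_b = delong_components(b, y)
    m, n = v10_a.size, v01_a.size
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ (s10 / m + s01 / n) @ contrast)
    diff = auc_a - auc_b
    if var <= 0:
        if np.isclose(diff, 0.0):
            return DeLongResult(feature_a, feature_b, auc_a, auc_b,
                                z=0.0, p_value=1.0, var_diff=0.0,
                                flagged=True)
        return DeLongResult(feature_a, feature_b, auc_a, auc_b,
                            z=float(np.sign(diff) * np.inf), p_value=0.0,
                            var_diff=0.0, flagged=True)
    z = diff / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return DeLongResult(feature_a, feature_b, auc_a, auc_b, z=float(z),
                        p_value=p, var_diff=var)


def icc_band(icc: float) -> str:
    """Agreement band on the conventional touching intervals
    (0.00-0.20 poor, 0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80 good,
    0.81-1.00 excellent); values strictly between printed bounds fall in
    the lower band."""
    if np.isnan(icc):
        return "undefined"
    for name, upper in ICC_BANDS:
        if icc < upper:
            return name
    return "excellent"


def interobserver_agreement(ratings_r1, ratings_r2, feature_name: str = "",
                            icc_form: str = "icc2") -> AgreementResult:
    """ICC(2,1) (or ICC(3,1)) plus Bland-Altman bias and limits of agreement.

    Bias is mean(r2 - r1); limits of agreement are bias +/- 1.96 * SD of the
    paired differences.  Perfectly identical raters give ICC = 1 by
    convention even when variance is degenerate.
    """
    if icc_form not in ("icc2", "icc3"):
        raise ValueError("icc_form must be 'icc2' or 'icc3'")
    r1 = np.asarray(ratings_r1, dtype=float)
    r2 = np.asarray(ratings_r2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("paired 1-D ratings required")
    if r1.size < 3:
        raise ValueError("need at least 3 paired measurements")
    d = r2 - r1
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    if np.all(d == 0.0):
        return AgreementResult(feature_name, 1.0, "excellent", 0.0, 0.0, 0.0,
                               icc_form=icc_form,
                               flagged=bool(np.ptp(r1) == 0.0))
    import pingouin as pg  # deferred: heavy import
    n = r1.size
    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["r1", "r2"], n),
        "rating": np.concatenate([r1, r2]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(data=long, targets="subject",
                                   raters="rater", ratings="rating")
    wanted = {"icc2": ("ICC2", "ICC(A,1)"),   # two-way random, absolute
              "icc3": ("ICC3", "ICC(C,1)")}[icc_form]  # two-way mixed
    row = table[table["Type"].isin(wanted)]
    icc = float(row["ICC"].iloc[0])
    flagged = bool(np.isnan(icc))
    return AgreementResult(feature_name, icc, icc_band(icc), bias,
                           float(loa_low), float(loa_high),
                           icc_form=icc_form, flagged=flagged)


def feature_columns(df: pd.DataFrame) -> list:
    """Feature columns of a cohort table (everything except bookkeeping)."""
    skip = {"subject_id", "label", "n_voxels", "seed"}
    return [c for c in df.columns if c not in skip]


def analyze_cohort(df: pd.DataFrame, alpha: float = 0.05,
                   positive: str = "hard",
                   features: list | None = None) -> CohortAnalysis:
    """Full diagnostic analysis of a cohort feature table.

    Compares every feature between groups, runs ROC analysis on the
    significant ones (scores oriented so the positive class has the higher
    oriented score), and DeLong comparisons for every significant pair.
    """
    labels = df["label"].to_numpy()
    classes = set(labels)
    if not {"soft", "hard"} <= classes:
        raise ValueError("cohort must contain both 'soft' and 'hard' labels")
    cols = features if features is not None else feature_columns(df)
    comparisons = []
    diagnostics = []
    for col in cols:
        vals = df[col].to_numpy(dtype=float)
        keep = np.isfinite(vals)
        gc = compare_groups(vals[keep & (labels == "soft")],
                            vals[keep & (labels == "hard")],
                            feature_name=col, alpha=alpha)
        comparisons.append(gc)
        if gc.p_value < alpha:
            diagnostics.append(roc_analysis(vals[keep], labels[keep],
                                            positive=positive,
                                            feature_name=col))
    delong = []
    diag_by_name = {d.feature_name: d for d in diagnostics}
    for fa, fb in itertools.combinations(diag_by_name, 2):
        va = df[fa].to_numpy(dtype=float)
        vb = df[fb].to_numpy(dtype=float)
        keep = np.isfinite(va) & np.isfinite(vb)
        if diag_by_name[fa].orientation == "lower-is-hard":
            va = -va
        if diag_by_name[fb].orientation == "lower-is-hard":
            vb = -vb
        delong.append(delong_test(va[keep], vb[keep], labels[keep],
                                  positive=positive, feature_a=fa,
                                  feature_b=fb))
    return CohortAnalysis(comparisons=comparisons, diagnostics=diagnostics,
                          delong=delong, n_features_tested=len(cols),
                          alpha=alpha, positive_label=positive)
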