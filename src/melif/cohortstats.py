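"""Cohort-level diagnostic statistics for scored patients.

Implements the validation battery applied to a scored cohort table:
per-group descriptive summaries (Tukey boxplot style), D'Agostino-Pearson
normality testing, unpaired t-tests, Pearson correlation with simple
linear regression and a Fisher-z confidence interval, and ROC analysis
with a DeLong confidence interval and a Youden-index cutoff.

Orientation note: the imaging scores *decrease* with disease severity, so
ROC analyses pass ``positive_is_low=True`` — a patient is called positive
(impaired) when the score falls at or below the cutoff.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "GroupSummary",
    "NormalityResult",
    "PearsonResult",
    "ROCResult",
    "group_summary",
    "normality_test",
    "ttest_unpaired",
    "pearson_with_regression",
    "roc_youden",
    "cohort_report",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float | None
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NormalityResult:
    assessable: bool
    statistic: float | None = None
    p_value: float | None = None


@dataclass
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    slope: float
    intercept: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def group_summary(values) -> GroupSummary:
    """Descriptive summary of one group of values.

    Quartiles use the (n+1)-based plotting-position method, matching the
    convention of common biostatistics packages; whiskers follow Tukey's
    rule (most extreme observation within 1.5 IQR of the quartiles).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValidationError("empty group")
    q1, q3 = (float(np.percentile(v, q, method="weibull")) for q in (25, 75))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return GroupSummary(
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else None,
        median=float(np.median(v)),
        q1=q1,
        q3=q3,
        iqr=iqr,
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]),
    )


def normality_test(values) -> NormalityResult:
    """D'Agostino-Pearson omnibus K^2 test; n < 8 is 'not assessable'."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 8:
        return NormalityResult(assessable=False)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # kurtosistest small-n warning
        stat, p = stats.normaltest(v)
    return NormalityResult(assessable=True, statistic=float(stat), p_value=float(p))


def ttest_unpaired(group_a, group_b, welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test (pooled variance by default), two-tailed.

    Returns ``(t, df, p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson_with_regression(x, y, ci: float = 0.95) -> PearsonResult:
    """Pearson r with Fisher-z CI, two-tailed p, and OLS slope/intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    if abs(r) < 1.0 and x.size > 3:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(x.size - 3)
        zc = stats.norm.ppf(0.5 + ci / 2)
        lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    else:
        lo = hi = r
    return PearsonResult(
        r=float(r),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(p),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        n=int(x.size),
    )


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Empirical AUC by the rank (Mann-Whitney) statistic, ties at 1/2."""
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    m = pos.size
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * neg.size))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    combined = np.concatenate([pos, neg])
    r_all = stats.rankdata(combined)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    m, n = pos.size, neg.size
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_youden(scores, labels, positive_is_low: bool = True, ci: float = 0.95) -> ROCResult:
    """ROC analysis with DeLong CI and a Youden-index cutoff.

    ``labels`` are 1 for the positive (impaired) class.  With
    ``positive_is_low`` a case is called positive when its score is <= the
    cutoff.  The cutoff is the midpoint between the adjacent observed
    scores that maximizes J = sensitivity + specificity - 1; ties prefer
    higher sensitivity, then the lower cutoff value.  The p-value is the
    DeLong test of AUC = 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.size != y.size or s.size == 0:
        raise ValidationError("scores and labels must be equal-length, nonempty")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")

    oriented = -s if positive_is_low else s
    pos, neg = oriented[y == 1], oriented[y == 0]
    auc = _rank_auc(pos, neg)
    var = _delong_variance(pos, neg)
    se = np.sqrt(var)
    zc = stats.norm.ppf(0.5 + ci / 2)
    if se > 0:
        lo = max(0.0, auc - zc * se)
        hi = min(1.0, auc + zc * se)
        p = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)
    else:
        lo = hi = auc
        p = 0.0 if auc != 0.5 else 1.0

    # Youden cutoff by exhaustive enumeration of midpoints between
    # consecutive distinct observed scores (original scale).
    uniq = np.unique(s)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], cands, [uniq[-1] + 1.0]])
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    best = None
    for c in cands:
        if positive_is_low:
            sens = (s[y == 1] <= c).sum() / n_pos
            spec = (s[y == 0] > c).sum() / n_neg
        else:
            sens = (s[y == 1] >= c).sum() / n_pos
            spec = (s[y == 0] < c).sum() / n_neg
        j = sens + spec - 1.0
        key = (j, sens, -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cutoff, sens, spec = best
    return ROCResult(
        auc=auc,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(p),
        cutoff=float(cutoff),
        sensitivity_pct=float(100.0 * sens),
        specificity_pct=float(100.0 * spec),
    )


_SCORE_COLUMNS = ("melif", "rrt1_mean_pct")


def cohort_report(cohort: pd.DataFrame, out_dir: str | Path | None = None) -> dict:
    """Full report bundle for a scored cohort table.

    Expects columns ``id, meld, meld_group, melif, rrt1_mean_pct`` (extra
    demographic columns are summarized when present).  Produces overall and
    per-group summaries, pairwise t-tests, correlations of both imaging
    scores with MELD, and ROC rows discriminating the normal (MELD <= 10)
    from the impaired (MELD 11-18) group; the severe group is too small
    for ROC by design and excluded.
    """
    required = {"id", "meld", "meld_group", "melif", "rrt1_mean_pct"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    if cohort.empty:
        raise ValidationError("empty cohort")
    if cohort["id"].duplicated().any():
        raise ValidationError("duplicate patient ids")

    report: dict = {"n": int(len(cohort))}

    overall_cols = [c for c in ("melif", "rrt1_mean_pct", "meld", "age", "height_m",
                                "weight_kg", "liver_volume_ml") if c in cohort.columns]
    report["overall"] = {c: group_summary(cohort[c]).to_dict() for c in overall_cols}

    groups = [g for g in ("normal", "impaired", "severe") if (cohort["meld_group"] == g).any()]
    report["groups"] = {}
    for g in groups:
        sub = cohort[cohort["meld_group"] == g]
        report["groups"][g] = {
            "n": int(len(sub)),
            **{c: group_summary(sub[c]).to_dict() for c in _SCORE_COLUMNS},
        }

    report["normality"] = {
        c: asdict(normality_test(cohort[c])) for c in _SCORE_COLUMNS
    }

    report["pairwise_ttests"] = {}
    for c in _SCORE_COLUMNS:
        rows = {}
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                a = cohort.loc[cohort["meld_group"] == ga, c]
                b = cohort.loc[cohort["meld_group"] == gb, c]
                if len(a) < 2 or len(b) < 2:
                    continue
                t, df, p = ttest_unpaired(a, b)
                rows[f"{ga}_vs_{gb}"] = {"t": t, "df": df, "p": p}
        report["pairwise_ttests"][c] = rows

    try:
        report["correlations_vs_meld"] = {
            c: pearson_with_regression(cohort["meld"], cohort[c]).to_dict()
            for c in _SCORE_COLUMNS
        }
    except ValidationError as exc:
        logger.info("correlations omitted: %s", exc)
        report["correlations_vs_meld"] = None

    roc_subset = cohort[cohort["meld_group"].isin(["normal", "impaired"])]
    if roc_subset["meld_group"].nunique() == 2:
        labels = (roc_subset["meld_group"] == "impaired").astype(int)
        report["roc_normal_vs_impaired"] = {
            c: roc_youden(roc_subset[c], labels, positive_is_low=True).to_dict()
            for c in _SCORE_COLUMNS
        }
    else:
        logger.info("ROC omitted: fewer than two MELD groups present")
        report["roc_normal_vs_impaired"] = None

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        rows = []
        for g in groups:
            for c in _SCORE_COLUMNS:
                gs = report["groups"][g][c]
                rows.append({"group": g, "score": c, **gs})
        pd.DataFrame(rows).to_csv(out / "group_summary.csv", index=False)
        cohort.to_csv(out / "cohort_scored.csv", index=False)
    return report
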