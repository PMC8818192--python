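"""Statistical comparison layer for fitted kinetic parameters.

Covers the downstream analysis of a fitted cohort: per-fit information
criteria (Gaussian least-squares AIC/BIC), two-group comparison of each
parameter (Student's t-test), discrimination analysis (ROC AUC with
DeLong variance and the DeLong test for correlated AUCs), and a cohort
summary table of mean +/- sd per parameter, group and fitting method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .optim import FitResult

__all__ = [
    "FitQuality",
    "fit_quality",
    "compare_groups",
    "RocResult",
    "roc_auc",
    "compare_auc",
    "fits_to_frame",
    "cohort_report",
    "CohortReport",
]

PARAM_COLUMNS = ["k1", "k2", "k3", "k4", "hpi"]


@dataclass(frozen=True)
class FitQuality:
    """Information-criterion summary of one fit."""

    aic: float
    bic: float
    rss: float
    n_frames: int
    n_params: int


def fit_quality(result: FitResult | None = None, *, rss: float | None = None,
                n_frames: int | None = None, n_params: int | None = None) -> FitQuality:
    """Gaussian least-squares AIC/BIC for one fit.

    ``AIC = n ln(RSS/n) + 2p`` and ``BIC = n ln(RSS/n) + p ln n`` with
    n the number of frames and p the number of free parameters (additive
    constants dropped — only differences between fits of the same data
    are meaningful).  An exactly zero RSS yields -inf with a warning.
    """
    if result is not None:
        rss = result.fun if result.residuals is None else float(result.residuals @ result.residuals)
        n_frames = result.n_obs
        n_params = result.n_params
    if rss is None or n_frames is None or n_params is None:
        raise ValueError("need rss, n_frames and n_params (or a complete FitResult)")
    if rss < 0:
        raise ValueError(f"rss must be >= 0, got {rss}")
    if n_frames <= n_params:
        raise ValueError(f"need n_frames > n_params, got n={n_frames}, p={n_params}")
    if rss == 0:
        warnings.warn("zero RSS: AIC/BIC are -inf", RuntimeWarning, stacklevel=2)
        return FitQuality(-math.inf, -math.inf, 0.0, n_frames, n_params)
    base = n_frames * math.log(rss / n_frames)
    return FitQuality(
        aic=base + 2 * n_params,
        bic=base + n_params * math.log(n_frames),
        rss=float(rss),
        n_frames=n_frames,
        n_params=n_params,
    )


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample two-sided t-test (pooled-variance Student's t by default).

    Returns ``(t, p)``; Welch's correction is available via
    ``equal_var=False``.  Two zero-variance groups with equal means give
    (0, 1) rather than NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ROC / DeLong


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Per-subject DeLong structural components and the empirical AUC.

    Uses the midrank construction; ties between a positive and a negative
    score count 1/2, so the AUC equals the scaled Mann-Whitney U.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() / (m * n)) - (m + 1.0) / (2.0 * n)
    v01 = (tz[:m] - tx) / n  # one component per positive subject
    v10 = 1.0 - (tz[m:] - ty) / m  # one per negative subject
    return auc, v01, v10


@dataclass(frozen=True)
class RocResult:
    """AUC with DeLong-variance confidence interval and score orientation."""

    auc: float
    ci_low: float
    ci_high: float
    direction: int  # +1: higher scores indicate the positive class; -1: flipped
    variance: float


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    level: float = 0.95,
    orient: bool = True,
) -> RocResult:
    """Empirical (Mann-Whitney) AUC with a DeLong-variance Wald CI.

    With ``orient=True`` the scores are flipped when the raw AUC is below
    0.5, so the reported AUC is always >= 0.5 and ``direction`` records
    which way discrimination ran.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    direction = 1
    auc, v01, v10 = _delong_components(scores, labels)
    if orient and auc < 0.5:
        direction = -1
        auc, v01, v10 = _delong_components(-scores, labels)
    var = v01.var(ddof=1) / v01.size + v10.var(ddof=1) / v10.size
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return RocResult(
        auc=float(auc),
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        direction=direction,
        variance=float(var),
    )


def compare_auc(
    scores_1: Sequence[float],
    scores_2: Sequence[float],
    labels: Sequence[int],
    orient: bool = True,
) -> float:
    """DeLong test for two correlated (paired) ROC curves; returns the p value.

    Both score vectors must be measured on the same subjects.  Each is
    oriented to AUC >= 0.5 before comparison (mirroring how absolute
    discriminative ability is reported), which also makes the test
    invariant to strictly monotone transforms of either score.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    labels = np.asarray(labels).astype(int)
    if s1.shape != s2.shape or s1.shape != labels.shape:
        raise ValueError("scores_1, scores_2 and labels must have identical shapes")
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    a1, v01_1, v10_1 = _delong_components(s1, labels)
    if orient and a1 < 0.5:
        a1, v01_1, v10_1 = _delong_components(-s1, labels)
    a2, v01_2, v10_2 = _delong_components(s2, labels)
    if orient and a2 < 0.5:
        a2, v01_2, v10_2 = _delong_components(-s2, labels)
    m, n = v01_1.size, v10_1.size
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    cov = s01 / m + s10 / n  # 2x2 covariance of (auc1, auc2)
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = a1 - a2
    if var_diff <= 1e-15:
        if abs(diff) < 1e-12:
            return 1.0
        raise ValueError(
            "degenerate AUC-difference variance with unequal AUCs; "
            "DeLong comparison is undefined"
        )
    z = diff / math.sqrt(var_diff)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# cohort summaries


def fits_to_frame(
    results: Sequence[FitResult], groups: Sequence[str], subject_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tabulate fits: one row per subject with parameters, RSS and AIC/BIC."""
    if len(results) != len(groups):
        raise ValueError("results and groups must have equal length")
    rows = []
    for idx, (res, grp) in enumerate(zip(results, groups)):
        q = fit_quality(res)
        row = {"subject": subject_ids[idx] if subject_ids else f"s{idx:03d}", "group": grp}
        row.update(dict(zip(PARAM_COLUMNS, res.x)))
        row.update({"rss": q.rss, "aic": q.aic, "bic": q.bic})
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


@dataclass
class CohortReport:
    """Cohort-level comparison across fitting methods."""

    summary: pd.DataFrame  # per (method, parameter): group means/sds, t, p, AUC + CI
    fit_quality: pd.DataFrame  # per (method, group): mean/sd AIC and BIC
    auc_comparisons: pd.DataFrame  # per (parameter, method pair): DeLong p
    excluded: list[str]


def cohort_report(
    tables: Mapping[str, pd.DataFrame],
    positive_group: str = "HCC",
    equal_var: bool = True,
) -> CohortReport:
    """Summarise per-method fits into a group-comparison report.

    ``tables`` maps method name to a :func:`fits_to_frame`-shaped frame.
    The report gives mean +/- sd per parameter per group with Student's
    t-test p values, oriented AUC with DeLong CI per parameter, pairwise
    DeLong AUC-difference p values between methods, and mean +/- sd
    AIC/BIC per group.  Subjects with non-finite parameter values are
    excluded with a warning.
    """
    excluded: list[str] = []
    clean: dict[str, pd.DataFrame] = {}
    for method, df in tables.items():
        ok = np.isfinite(df[PARAM_COLUMNS].to_numpy()).all(axis=1)
        if not ok.all():
            bad = list(df.index[~ok])
            excluded += [f"{method}:{s}" for s in bad]
            warnings.warn(
                f"excluding {len(bad)} subject(s) with non-finite fits from {method}",
                RuntimeWarning,
                stacklevel=2,
            )
        clean[method] = df[ok]

    summary_rows = []
    fq_rows = []
    cmp_rows = []
    for method, df in clean.items():
        groups = df["group"].unique()
        if positive_group not in groups or len(groups) < 2:
            raise ValueError(f"method {method!r} needs both groups; found {list(groups)}")
        pos = df[df["group"] == positive_group]
        neg = df[df["group"] != positive_group]
        labels = (df["group"] == positive_group).to_numpy().astype(int)
        for p in PARAM_COLUMNS:
            t, pval = compare_groups(pos[p], neg[p], equal_var=equal_var)
            roc = roc_auc(df[p].to_numpy(), labels)
            summary_rows.append(
                {
                    "method": method,
                    "parameter": p,
                    f"mean_{positive_group}": pos[p].mean(),
                    f"sd_{positive_group}": pos[p].std(ddof=1),
                    "mean_other": neg[p].mean(),
                    "sd_other": neg[p].std(ddof=1),
                    "t": t,
                    "p": pval,
                    "auc": roc.auc,
                    "auc_ci_low": roc.ci_low,
                    "auc_ci_high": roc.ci_high,
                    "auc_direction": roc.direction,
                }
            )
        for grp, sub in df.groupby("group"):
            fq_rows.append(
                {
                    "method": method,
                    "group": grp,
                    "aic_mean": sub["aic"].mean(),
                    "aic_sd": sub["aic"].std(ddof=1),
                    "bic_mean": sub["bic"].mean(),
                    "bic_sd": sub["bic"].std(ddof=1),
                }
            )

    methods = list(clean)
    for ia, ma in enumerate(methods):
        for mb in methods[ia + 1 :]:
            shared = clean[ma].index.intersection(clean[mb].index)
            if len(shared) < 4:
                continue
            la = (clean[ma].loc[shared, "group"] == positive_group).to_numpy().astype(int)
            for p in PARAM_COLUMNS:
                try:
                    pval = compare_auc(
                        clean[ma].loc[shared, p].to_numpy(),
                        clean[mb].loc[shared, p].to_numpy(),
                        la,
                    )
                except ValueError:  # degenerate variance on tiny/perfect cohorts
                    pval = math.nan
                cmp_rows.append(
                    {"parameter": p, "method_a": ma, "method_b": mb, "p": pval}
                )

    return CohortReport(
        summary=pd.DataFrame(summary_rows),
        fit_quality=pd.DataFrame(fq_rows),
        auc_comparisons=pd.DataFrame(cmp_rows),
        excluded=excluded,
    )
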