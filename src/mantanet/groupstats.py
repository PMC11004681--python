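"""Sex-bias comparisons of movement behaviour.

For a chosen per-animal metric (total movements, or mean direct distance
travelled) the two sexes are compared with the classical battery: a
Shapiro–Wilk normality test per group, a two-sided variance-ratio F-test,
then an unpaired two-sample t-test — pooled-variance when the F-test gives
no evidence of unequal variances (at alpha 0.05), Welch otherwise. Both
t-test variants are always reported. P-values are reported with a graded
evidence phrase rather than a dichotomous significance label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SexComparison", "compare_sexes", "evidence_phrase", "variance_ratio_test"]

METRIC_COLUMNS = {
    "total_movements": "n_movements",
    "mean_distance_km": "distance_km",
}


def evidence_phrase(p: float) -> str:
    """Graded evidence language for a p-value (no binary 'significant')."""
    if p <= 0.001:
        return "very strong evidence"
    if p <= 0.01:
        return "strong evidence"
    if p <= 0.05:
        return "moderate evidence"
    if p <= 0.1:
        return "weak evidence"
    return "no evidence"


def variance_ratio_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test of equal variances (R ``var.test`` semantics).

    Returns (F statistic = var(x)/var(y), p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    f = np.var(x, ddof=1) / np.var(y, ddof=1)
    df1, df2 = len(x) - 1, len(y) - 1
    cdf = stats.f.cdf(f, df1, df2)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(f), float(min(p, 1.0))


@dataclass
class SexComparison:
    metric: str
    groups: dict                       # sex -> dict(n, mean, sd, median)
    shapiro_p: dict = field(default_factory=dict)   # sex -> p
    f_stat: Optional[float] = None
    f_test_p: Optional[float] = None
    t_stat: Optional[float] = None
    t_test_p: Optional[float] = None
    pooled_p: Optional[float] = None
    welch_p: Optional[float] = None
    equal_var_assumed: Optional[bool] = None
    conclusion: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _summary(x: np.ndarray) -> dict:
    return dict(n=int(len(x)),
                mean=float(np.mean(x)) if len(x) else float("nan"),
                sd=float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
                median=float(np.median(x)) if len(x) else float("nan"))


def compare_sexes(per_individual: pd.DataFrame,
                  metric: str = "total_movements",
                  cohort_filter: Union[dict, Callable, None] = None,
                  sexes: tuple = ("F", "M"),
                  alpha_var: float = 0.05) -> SexComparison:
    """Compare a per-animal movement metric between two sexes.

    Parameters
    ----------
    per_individual : table from :func:`mantanet.events.per_individual_summary`.
    metric : ``'total_movements'`` or ``'mean_distance_km'`` (or directly a
        column name of the table).
    cohort_filter : optional restriction of the cohort before testing — a
        dict of column -> required value (e.g. restrict to animals tagged at
        one station where tagging effort was sex-balanced), or a callable
        returning a boolean mask.
    sexes : the two group labels to compare (unsexed animals are excluded).
    alpha_var : threshold on the F-test p-value below which the Welch
        (unequal-variance) t-test is adopted instead of the pooled one.
    """
    col = METRIC_COLUMNS.get(metric, metric)
    if col not in per_individual.columns:
        raise KeyError(f"metric column {col!r} not in per-individual table")
    df = per_individual
    if cohort_filter is not None:
        if callable(cohort_filter):
            df = df[cohort_filter(df)]
        else:
            for k, val in cohort_filter.items():
                df = df[df[k] == val]
    if len(sexes) != 2:
        raise ValueError("exactly two sexes must be compared")
    vals = {s: df.loc[df["sex"] == s, col].dropna().to_numpy(dtype=float)
            for s in sexes}
    res = SexComparison(metric=metric,
                        groups={s: _summary(v) for s, v in vals.items()})
    small = [s for s, v in vals.items() if len(v) < 3]
    if small:
        res.conclusion = (
            f"tests skipped: group(s) {', '.join(small)} have fewer than 3 "
            f"animals after the cohort filter")
        return res
    x, y = vals[sexes[0]], vals[sexes[1]]
    for s, v in vals.items():
        if np.ptp(v) == 0:
            res.shapiro_p[s] = float("nan")  # Shapiro undefined on constants
        else:
            res.shapiro_p[s] = float(stats.shapiro(v).pvalue)
    res.f_stat, res.f_test_p = variance_ratio_test(x, y)
    pooled = stats.ttest_ind(x, y, equal_var=True)
    welch = stats.ttest_ind(x, y, equal_var=False)
    res.pooled_p = float(pooled.pvalue)
    res.welch_p = float(welch.pvalue)
    res.equal_var_assumed = bool(res.f_test_p >= alpha_var)
    chosen = pooled if res.equal_var_assumed else welch
    res.t_stat = float(chosen.statistic)
    res.t_test_p = float(chosen.pvalue)
    a, b = sexes
    res.conclusion = (
        f"{evidence_phrase(res.t_test_p)} (p = {res.t_test_p:.3f}) of a "
        f"difference in {metric} between {a} "
        f"(mean ± sd = {res.groups[a]['mean']:.1f} ± {res.groups[a]['sd']:.1f}, "
        f"median = {res.groups[a]['median']:.1f}, n = {res.groups[a]['n']}) and {b} "
        f"(mean ± sd = {res.groups[b]['mean']:.1f} ± {res.groups[b]['sd']:.1f}, "
        f"median = {res.groups[b]['median']:.1f}, n = {res.groups[b]['n']}); "
        f"{'pooled' if res.equal_var_assumed else 'Welch'} t-test")
    return res
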