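"""Statistical validation of scored cohorts.

Two analyses mirror the construct-validity workflow for expertise scores:

* group comparison — one-way ANOVA over participant-average scores across
  expertise groups, with Tukey-Kramer post-hoc pairwise differences (the
  Tukey HSD adjusted for unequal group sizes), Shapiro-Wilk normality checks
  per group and the median-centered Levene (Brown-Forsythe) test for
  homogeneity of variances;
* training-year regression — ordinary least squares of a trainee's average
  score on their year of training (fellows coded as year 7), with slope CI,
  F test, R-squared and adjusted R-squared.

Group confidence intervals are t-based intervals on the group mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.regression.linear_model import OLS
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools import add_constant

from .exceptions import DegenerateRegressionError, InsufficientGroupError

__all__ = [
    "GroupStats",
    "PairwiseDifference",
    "AnovaReport",
    "RegressionReport",
    "ValidationReport",
    "group_comparison",
    "training_year_regression",
]


@dataclass
class GroupStats:
    label: str
    n: int
    mean: float
    ci_low: float
    ci_high: float
    shapiro_p: float


@dataclass
class PairwiseDifference:
    group_a: str
    group_b: str
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    reject: bool


@dataclass
class AnovaReport:
    groups: list[GroupStats]
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    levene_median_p: float
    pairwise: list[PairwiseDifference]

    def to_dict(self) -> dict:
        return {
            "groups": [vars(g) for g in self.groups],
            "anova": {
                "F": self.f_statistic,
                "df_between": self.df_between,
                "df_within": self.df_within,
                "p": self.p_value,
            },
            "levene_median_p": self.levene_median_p,
            "tukey_kramer": [vars(p) for p in self.pairwise],
        }

    def to_text(self) -> str:
        lines = ["One-way ANOVA on participant-average scores", "-" * 52]
        for g in self.groups:
            lines.append(
                f"  {g.label:<10} n={g.n:<3} mean={g.mean:+.3f} "
                f"95% CI [{g.ci_low:+.3f}, {g.ci_high:+.3f}] "
                f"Shapiro-Wilk p={g.shapiro_p:.3f}"
            )
        lines.append(
            f"  F({self.df_between},{self.df_within}) = {self.f_statistic:.3f}, "
            f"p = {self.p_value:.4g}; Levene (median) p = {self.levene_median_p:.3f}"
        )
        lines.append("  Tukey-Kramer pairwise differences:")
        for p in self.pairwise:
            lines.append(
                f"    {p.group_a} - {p.group_b}: {p.mean_difference:+.3f} "
                f"95% CI [{p.ci_low:+.3f}, {p.ci_high:+.3f}] p = {p.p_value:.4g}"
            )
        return "\n".join(lines)


@dataclass
class RegressionReport:
    n: int
    slope: float
    slope_ci_low: float
    slope_ci_high: float
    intercept: float
    f_statistic: float
    df_model: int
    df_resid: int
    p_value: float
    r_squared: float
    adj_r_squared: float

    def to_dict(self) -> dict:
        return dict(vars(self))

    def to_text(self) -> str:
        return "\n".join([
            "OLS: average score ~ year of training",
            "-" * 52,
            f"  n = {self.n}",
            f"  slope = {self.slope:+.4f} per year, "
            f"95% CI [{self.slope_ci_low:+.4f}, {self.slope_ci_high:+.4f}]",
            f"  F({self.df_model},{self.df_resid}) = {self.f_statistic:.3f}, "
            f"p = {self.p_value:.4g}",
            f"  R^2 = {self.r_squared:.3f}, adjusted R^2 = {self.adj_r_squared:.3f}",
        ])


@dataclass
class ValidationReport:
    anova: AnovaReport | None = None
    regression: RegressionReport | None = None

    def to_dict(self) -> dict:
        out: dict = {}
        if self.anova is not None:
            out["group_comparison"] = self.anova.to_dict()
        if self.regression is not None:
            out["training_year_regression"] = self.regression.to_dict()
        return out

    def to_text(self) -> str:
        parts = []
        if self.anova is not None:
            parts.append(self.anova.to_text())
        if self.regression is not None:
            parts.append(self.regression.to_text())
        return "\n\n".join(parts)


def group_comparison(scores: dict[str, list[float]]) -> ValidationReport:
    """One-way ANOVA + Tukey-Kramer + assumption checks on group score lists."""
    if len(scores) < 2:
        raise InsufficientGroupError("need at least two groups to compare")
    labels = list(scores)
    arrays = {k: np.asarray(v, float) for k, v in scores.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise InsufficientGroupError(
                f"group {k!r} has {v.size} observation(s); need at least 2"
            )

    group_stats = []
    for k in labels:
        v = arrays[k]
        n = v.size
        m = float(v.mean())
        sem = float(v.std(ddof=1) / np.sqrt(n))
        tcrit = float(sps.t.ppf(0.975, n - 1))
        sw_p = (
            float(sps.shapiro(v).pvalue) if n >= 3 and v.std() > 0 else float("nan")
        )
        group_stats.append(
            GroupStats(k, n, m, m - tcrit * sem, m + tcrit * sem, sw_p)
        )

    n_total = sum(arrays[k].size for k in labels)
    df_b, df_w = len(labels) - 1, n_total - len(labels)
    grand = float(np.concatenate([arrays[k] for k in labels]).mean())
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    if ss_between == 0.0:  # no variance between groups; F is 0 by definition
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = sps.f_oneway(*[arrays[k] for k in labels])
    if all(v.std() == 0 for v in arrays.values()):
        levene_p = float("nan")
    else:
        levene_p = float(
            sps.levene(*[arrays[k] for k in labels], center="median").pvalue
        )

    values = np.concatenate([arrays[k] for k in labels])
    group_vec = np.concatenate([[k] * arrays[k].size for k in labels])
    tk = pairwise_tukeyhsd(values, group_vec, alpha=0.05)
    pairwise = [
        PairwiseDifference(
            group_a=str(a),
            group_b=str(b),
            mean_difference=float(diff),
            ci_low=float(lo),
            ci_high=float(hi),
            p_value=float(pv),
            reject=bool(rej),
        )
        for (a, b), diff, lo, hi, pv, rej in zip(
            ((row[0], row[1]) for row in tk.summary().data[1:]),
            tk.meandiffs,
            tk.confint[:, 0],
            tk.confint[:, 1],
            tk.pvalues,
            tk.reject,
        )
    ]

    return ValidationReport(
        anova=AnovaReport(
            groups=group_stats,
            f_statistic=float(f_stat),
            df_between=df_b,
            df_within=df_w,
            p_value=float(p),
            levene_median_p=levene_p,
            pairwise=pairwise,
        )
    )


def training_year_regression(participant_scores, years_in_training
                             ) -> ValidationReport:
    """OLS of participant-average score on (numeric) year of training."""
    y = np.asarray(participant_scores, float)
    x = np.asarray(years_in_training, float)
    if y.size != x.size:
        raise DegenerateRegressionError("scores and years must be the same length")
    if y.size < 3:
        raise DegenerateRegressionError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("year of training is constant")
    if np.ptp(y) == 0:
        # constant response: flat line fits exactly; nothing to explain
        return ValidationReport(
            regression=RegressionReport(
                n=int(y.size), slope=0.0, slope_ci_low=0.0, slope_ci_high=0.0,
                intercept=float(y[0]), f_statistic=0.0, df_model=1,
                df_resid=int(y.size - 2), p_value=1.0, r_squared=0.0,
                adj_r_squared=0.0,
            )
        )
    res = OLS(y, add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return ValidationReport(
        regression=RegressionReport(
            n=int(y.size),
            slope=float(res.params[1]),
            slope_ci_low=float(ci[1, 0]),
            slope_ci_high=float(ci[1, 1]),
            intercept=float(res.params[0]),
            f_statistic=float(res.fvalue),
            df_model=int(res.df_model),
            df_resid=int(res.df_resid),
            p_value=float(res.f_pvalue),
            r_squared=float(res.rsquared),
            adj_r_squared=float(res.rsquared_adj),
        )
    )
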