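"""Two-group repeated-measures statistical workflow.

Covers the full comparison chain for a cohort measured at several speeds and
split in two on a categorical axis: assumption checks (composite-null
normality, variance homogeneity), one-way/non-parametric omnibus tests on
participant characteristics, a split-plot (mixed) ANOVA with sphericity
handling, Holm-corrected pairwise post-hocs, pooled-SD Cohen's d and
confidence intervals of mean differences.

The mixed ANOVA is a direct sums-of-squares implementation (one between
factor, one within factor, complete cases) so large simulation studies run
fast; it is validated in the test suite against independent implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, InvalidInputError, UndefinedEffectError

__all__ = [
    "StatsConfig",
    "AnovaResult",
    "EffectEstimate",
    "holm_adjust",
    "cohens_d",
    "cohens_d_from_samples",
    "classify_d",
    "mean_diff_ci",
    "characteristic_comparison",
    "mixed_anova",
    "posthoc_pairwise",
    "two_sample_power",
]


@dataclass(frozen=True)
class StatsConfig:
    """Knobs of the statistical workflow.

    ``d_thresholds`` are the lower bounds of the small / moderate / large
    effect-size classes. ``normality_test`` selects the composite-null
    Lilliefors variant (default) or a plain Kolmogorov-Smirnov test against
    the fitted normal. ``welch`` switches mean-difference CIs from pooled
    variance to Welch.
    """

    alpha: float = 0.05
    ci_level: float = 0.95
    d_thresholds: tuple[float, float, float] = (0.2, 0.5, 0.8)
    normality_test: str = "lilliefors"
    welch: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidInputError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.ci_level < 1:
            raise InvalidInputError(f"ci_level must be in (0, 1), got {self.ci_level}")
        lo, mid, hi = self.d_thresholds
        if not lo < mid < hi:
            raise InvalidInputError("d_thresholds must be strictly increasing")
        if self.normality_test not in ("lilliefors", "ks"):
            raise InvalidInputError(f"unknown normality_test {self.normality_test!r}")


@dataclass(frozen=True)
class AnovaResult:
    """Split-plot ANOVA summary: group / within / interaction effects.

    ``p_within`` and ``p_interaction`` carry the sphericity-corrected values
    when the Mauchly gate fired (``corrected=True``); the uncorrected ones are
    always available with the ``_unc`` suffix.
    """

    between_label: str
    within_label: str
    n_subjects: int
    group_sizes: dict[str, int]
    f_group: float
    df1_group: float
    df2_group: float
    p_group: float
    f_within: float
    df1_within: float
    df2_within: float
    p_within: float
    p_within_unc: float
    f_interaction: float
    df1_interaction: float
    df2_interaction: float
    p_interaction: float
    p_interaction_unc: float
    epsilon: float
    mauchly_w: float
    mauchly_p: float
    corrected: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("group", self.f_group, self.df1_group, self.df2_group, self.p_group,
             self.p_group),
            ("within", self.f_within, self.df1_within, self.df2_within,
             self.p_within, self.p_within_unc),
            ("interaction", self.f_interaction, self.df1_interaction,
             self.df2_interaction, self.p_interaction, self.p_interaction_unc),
        ]
        return pd.DataFrame(
            rows, columns=["effect", "F", "df1", "df2", "p", "p_uncorrected"]
        ).assign(
            epsilon=self.epsilon,
            mauchly_w=self.mauchly_w,
            mauchly_p=self.mauchly_p,
            corrected=self.corrected,
        )


@dataclass(frozen=True)
class EffectEstimate:
    """A two-group contrast: mean difference, CI, Cohen's d, p-values."""

    label: str
    delta: float
    ci_low: float
    ci_high: float
    d: float
    d_class: str
    p_raw: float
    p_adjusted: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not self.ci_low <= self.delta <= self.ci_high:
            raise InvalidInputError("CI must bracket the mean difference")


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("p_values must be a non-empty 1-d sequence")
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = p[order] * (m - np.arange(m))
    stepped = np.minimum(np.maximum.accumulate(stepped), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = stepped
    return adjusted


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Pooled-SD Cohen's d, signed as (second group minus first group).

    No small-sample (Hedges) correction is applied.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need n >= 2 in each group")
    if sd1 < 0 or sd2 < 0:
        raise InvalidInputError("standard deviations must be non-negative")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise UndefinedEffectError("zero pooled standard deviation")
    return (mean2 - mean1) / np.sqrt(pooled_var)


def cohens_d_from_samples(x1, x2) -> float:
    """Cohen's d from raw samples; sign is mean(x2) - mean(x1)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise InsufficientDataError("need n >= 2 in each group")
    return cohens_d(
        x1.mean(), x1.std(ddof=1), x1.size, x2.mean(), x2.std(ddof=1), x2.size
    )


def classify_d(d: float, thresholds: tuple[float, float, float] = (0.2, 0.5, 0.8)) -> str:
    """Bucket |d| into trivial / small / moderate / large."""
    small, moderate, large = thresholds
    a = abs(d)
    if a >= large:
        return "large"
    if a >= moderate:
        return "moderate"
    if a >= small:
        return "small"
    return "trivial"


def mean_diff_ci(
    group1, group2, level: float = 0.95, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t interval on mean(group1) - mean(group2).

    Pooled variance by default; Welch on request. Returns (delta, lo, hi).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("need n >= 2 in each group")
    delta = x.mean() - y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se = np.sqrt(vx / x.size + vy / y.size)
        if se == 0:
            return float(delta), float(delta), float(delta)
        df = se**4 / (
            (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
        )
    else:
        pooled = ((x.size - 1) * vx + (y.size - 1) * vy) / (x.size + y.size - 2)
        se = np.sqrt(pooled * (1 / x.size + 1 / y.size))
        df = x.size + y.size - 2
    half = stats.t.ppf(0.5 + level / 2.0, df) * se
    return float(delta), float(delta - half), float(delta + half)


def _normality_p(values: np.ndarray, method: str) -> float:
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        return float(lilliefors(values, dist="norm")[1])
    z = (values - values.mean()) / values.std(ddof=1)
    return float(stats.kstest(z, "norm").pvalue)


def characteristic_comparison(
    values_by_group: dict[str, np.ndarray],
    cfg: StatsConfig = StatsConfig(),
) -> dict[str, float | str]:
    """Compare one characteristic between the two categories of an axis.

    Runs the normality check on the pooled sample and Levene's test across
    groups, then a one-way ANOVA if normality holds at ``cfg.alpha`` and a
    Kruskal-Wallis test otherwise. Cohen's d is signed second-listed minus
    first-listed group.
    """
    if len(values_by_group) != 2:
        raise InvalidInputError("expected exactly two groups")
    (label1, g1), (label2, g2) = (
        (k, np.asarray(v, dtype=float)) for k, v in values_by_group.items()
    )
    if g1.size < 2 or g2.size < 2:
        raise InsufficientDataError("each group needs at least 2 members")
    pooled = np.concatenate([g1, g2])
    normality_p = _normality_p(pooled, cfg.normality_test)
    homogeneity_p = float(stats.levene(g1, g2).pvalue)
    if normality_p > cfg.alpha:
        omnibus_p = float(stats.f_oneway(g1, g2).pvalue)
        test = "anova"
    else:
        omnibus_p = float(stats.kruskal(g1, g2).pvalue)
        test = "kruskal"
    d = cohens_d_from_samples(g1, g2)
    return {
        "group1": label1,
        "group2": label2,
        "n1": int(g1.size),
        "n2": int(g2.size),
        "mean1": float(g1.mean()),
        "sd1": float(g1.std(ddof=1)),
        "mean2": float(g2.mean()),
        "sd2": float(g2.std(ddof=1)),
        "normality_p": normality_p,
        "homogeneity_p": homogeneity_p,
        "omnibus_p": omnibus_p,
        "test": test,
        "d": d,
        "d_class": classify_d(d, cfg.d_thresholds),
    }


def _sphericity(Y: np.ndarray) -> tuple[float, float, float]:
    """Mauchly's W and its chi-square p, plus the Greenhouse-Geisser epsilon.

    Computed from the sample covariance of the subject-by-condition matrix.
    With two conditions sphericity holds trivially (W = 1, epsilon = 1).
    """
    n, k = Y.shape
    if k < 3:
        return 1.0, 1.0, 1.0
    S = np.cov(Y, rowvar=False)
    # orthonormal contrast basis spanning the within-subject differences
    C = np.linalg.qr(np.vstack([np.ones(k), np.eye(k - 1, k)]).T)[0][:, 1:]
    St = C.T @ S @ C
    eigs = np.linalg.eigvalsh(St)
    eigs = np.clip(eigs, 1e-300, None)
    W = float(np.prod(eigs) / (eigs.mean() ** (k - 1)))
    W = min(W, 1.0)
    f_corr = (2.0 * (k - 1) ** 2 + (k - 1) + 2.0) / (6.0 * (k - 1))
    chi2 = -(n - 1 - f_corr) * np.log(W)
    dof = k * (k - 1) / 2.0 - 1.0
    p = float(stats.chi2.sf(max(chi2, 0.0), dof))
    eps = float(eigs.sum() ** 2 / ((k - 1) * np.sum(eigs**2)))
    return W, p, min(eps, 1.0)


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str,
    cfg: StatsConfig = StatsConfig(),
) -> AnovaResult:
    """Split-plot ANOVA: one two-level between factor, one within factor.

    Complete cases only (subjects observed at every within level). Sums of
    squares use the classical weighted decomposition, which is orthogonal here
    because every subject contributes all within levels (proportional cell
    frequencies). Mauchly's test at ``cfg.alpha`` gates a Greenhouse-Geisser
    degrees-of-freedom correction on the within and interaction effects.
    """
    wide = data.pivot(index=subject, columns=within, values=dv).dropna()
    if wide.shape[1] < 2:
        raise InsufficientDataError("need at least two within-factor levels")
    group_of = data.drop_duplicates(subject).set_index(subject)[between]
    groups = group_of.loc[wide.index].to_numpy()
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise InsufficientDataError(f"between factor must have 2 levels, got {labels}")
    sizes = {str(lab): int((groups == lab).sum()) for lab in labels}
    if min(sizes.values()) < 2:
        raise InsufficientDataError("each group needs at least 2 complete subjects")

    Y = wide.to_numpy(dtype=float)
    n, k = Y.shape
    g = 2
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    masks = [groups == lab for lab in labels]
    ng = np.array([m.sum() for m in masks], dtype=float)
    group_means = np.array([Y[m].mean() for m in masks])
    cell_means = np.array([Y[m].mean(axis=0) for m in masks])  # g x k
    col_means = Y.mean(axis=0)

    ss_group = k * np.sum(ng * (group_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - group_means[np.where(masks[0], 0, 1)]) ** 2)
    ss_within_total = np.sum((Y - subj_means[:, None]) ** 2)
    ss_speed = n * np.sum((col_means - grand) ** 2)
    ss_inter = np.sum(
        ng[:, None]
        * (cell_means - group_means[:, None] - col_means[None, :] + grand) ** 2
    )
    ss_err = ss_within_total - ss_speed - ss_inter

    df_group = g - 1.0
    df_subj = n - g
    df_speed = k - 1.0
    df_inter = (g - 1.0) * (k - 1.0)
    df_err = (n - g) * (k - 1.0)

    ms_subj = ss_subj / df_subj
    ms_err = ss_err / df_err
    f_group = (ss_group / df_group) / ms_subj
    f_speed = (ss_speed / df_speed) / ms_err
    f_inter = (ss_inter / df_inter) / ms_err

    p_group = float(stats.f.sf(f_group, df_group, df_subj))
    p_speed_unc = float(stats.f.sf(f_speed, df_speed, df_err))
    p_inter_unc = float(stats.f.sf(f_inter, df_inter, df_err))

    w, mauchly_p, eps = _sphericity(Y)
    corrected = mauchly_p <= cfg.alpha and k > 2
    if corrected:
        p_speed = float(stats.f.sf(f_speed, eps * df_speed, eps * df_err))
        p_inter = float(stats.f.sf(f_inter, eps * df_inter, eps * df_err))
        df_speed_rep, df_inter_rep, df_err_rep = (
            eps * df_speed,
            eps * df_inter,
            eps * df_err,
        )
    else:
        p_speed, p_inter = p_speed_unc, p_inter_unc
        df_speed_rep, df_inter_rep, df_err_rep = df_speed, df_inter, df_err

    return AnovaResult(
        between_label=between,
        within_label=within,
        n_subjects=n,
        group_sizes=sizes,
        f_group=float(f_group),
        df1_group=df_group,
        df2_group=float(df_subj),
        p_group=p_group,
        f_within=float(f_speed),
        df1_within=float(df_speed_rep),
        df2_within=float(df_err_rep),
        p_within=p_speed,
        p_within_unc=p_speed_unc,
        f_interaction=float(f_inter),
        df1_interaction=float(df_inter_rep),
        df2_interaction=float(df_err_rep),
        p_interaction=p_inter,
        p_interaction_unc=p_inter_unc,
        epsilon=eps,
        mauchly_w=w,
        mauchly_p=mauchly_p,
        corrected=corrected,
    )


def posthoc_pairwise(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    group_order: tuple[str, str],
    cfg: StatsConfig = StatsConfig(),
) -> list[EffectEstimate]:
    """Per-within-level two-group contrasts with Holm-adjusted p-values.

    Delta, CI and d are all signed first-listed minus second-listed group, so
    a positive delta means the first group has the larger mean.
    """
    first, second = group_order
    levels = sorted(data[within].unique())
    raw_p: list[float] = []
    partial: list[tuple[str, float, float, float, float]] = []
    for level in levels:
        sub = data[data[within] == level]
        x = sub.loc[sub[between] == first, dv].to_numpy(dtype=float)
        y = sub.loc[sub[between] == second, dv].to_numpy(dtype=float)
        if x.size < 2 or y.size < 2:
            raise InsufficientDataError(f"level {level}: each group needs n >= 2")
        delta, lo, hi = mean_diff_ci(x, y, level=cfg.ci_level, welch=cfg.welch)
        d = cohens_d_from_samples(y, x)  # second-minus-first flipped -> first minus second
        p = float(stats.ttest_ind(x, y, equal_var=not cfg.welch).pvalue)
        raw_p.append(p)
        partial.append((f"{first}-{second}@{level}", delta, lo, hi, d))
    adjusted = holm_adjust(raw_p)
    return [
        EffectEstimate(
            label=label,
            delta=delta,
            ci_low=lo,
            ci_high=hi,
            d=d,
            d_class=classify_d(d, cfg.d_thresholds),
            p_raw=p,
            p_adjusted=float(p_adj),
        )
        for (label, delta, lo, hi, d), p, p_adj in zip(partial, raw_p, adjusted)
    ]


def two_sample_power(
    d: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Power of a two-sided two-sample t test at effect size d (convenience)."""
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need n >= 2 in each group")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    crit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))
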