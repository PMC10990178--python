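import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from springgait import (
    InsufficientDataError,
    InvalidInputError,
    StatsConfig,
    UndefinedEffectError,
    characteristic_comparison,
    classify_d,
    cohens_d,
    cohens_d_from_samples,
    holm_adjust,
    mean_diff_ci,
    mixed_anova,
    posthoc_pairwise,
    two_sample_power,
)


# ---------------------------------------------------------------------------
# Holm adjustment


def test_holm_single_p_unchanged():
    assert holm_adjust([0.03]) == pytest.approx([0.03])


def test_holm_hand_stepped_example():
    assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])


def test_holm_ties_all_equal():
    out = holm_adjust([0.02, 0.02, 0.02])
    assert out == pytest.approx([0.06, 0.06, 0.06])
    out = holm_adjust([0.5, 0.5, 0.5])
    assert out == pytest.approx([1.0, 1.0, 1.0])  # capped at min(3p, 1)


def test_holm_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(20):
        p = rng.uniform(0, 1, rng.integers(1, 8))
        ours = holm_adjust(p)
        theirs = multipletests(p, method="holm")[1]
        assert ours == pytest.approx(theirs)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
def test_holm_adjusted_at_least_raw(p):
    adj = holm_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    assert np.all(adj <= 1.0)


@given(st.lists(st.floats(0, 1), min_size=2, max_size=8), st.permutations(range(8)))
def test_holm_order_invariant(p, perm):
    idx = [i for i in perm if i < len(p)]
    shuffled = [p[i] for i in idx]
    adj_direct = holm_adjust(p)
    adj_shuffled = holm_adjust(shuffled)
    for pos, i in enumerate(idx):
        assert adj_shuffled[pos] == pytest.approx(adj_direct[i])


def test_holm_rejects_bad_p():
    with pytest.raises(InvalidInputError):
        holm_adjust([0.5, 1.2])
    with pytest.raises(InvalidInputError):
        holm_adjust([-0.1])
    with pytest.raises(InvalidInputError):
        holm_adjust([])


# ---------------------------------------------------------------------------
# Cohen's d


def test_cohens_d_zero_for_equal_means():
    assert cohens_d(5.0, 1.0, 10, 5.0, 2.0, 10) == 0.0


def test_cohens_d_published_height_cells():
    # second-listed minus first-listed convention
    assert round(cohens_d(179, 7, 35, 174, 8, 45), 2) == -0.66


def test_cohens_d_mass_cells_from_rounded_inputs():
    # pooled SD is exactly 9 here, so d = -4/9
    assert cohens_d(72, 9, 35, 68, 9, 45) == pytest.approx(-4 / 9, abs=1e-12)


def test_cohens_d_zero_pooled_sd():
    with pytest.raises(UndefinedEffectError):
        cohens_d(1.0, 0.0, 5, 2.0, 0.0, 5)


def test_cohens_d_requires_two_per_group():
    with pytest.raises(InsufficientDataError):
        cohens_d(1.0, 1.0, 1, 2.0, 1.0, 5)


def test_cohens_d_from_samples_matches_summary(rng):
    x = rng.normal(0, 1, 30)
    y = rng.normal(0.5, 1.2, 20)
    expected = cohens_d(x.mean(), x.std(ddof=1), 30, y.mean(), y.std(ddof=1), 20)
    assert cohens_d_from_samples(x, y) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "d,expected",
    [(0.1, "trivial"), (0.2, "small"), (-0.44, "small"), (0.5, "moderate"),
     (-0.73, "moderate"), (0.8, "large"), (-1.02, "large")],
)
def test_classify_d(d, expected):
    assert classify_d(d) == expected


# ---------------------------------------------------------------------------
# mean difference CI


def test_mean_diff_ci_identical_groups():
    delta, lo, hi = mean_diff_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert delta == 0.0
    assert lo == pytest.approx(-hi)


def test_mean_diff_ci_hand_computation():
    # pooled sd = 1, se = sqrt(2/3), t(4, .975) = 2.7764
    delta, lo, hi = mean_diff_ci([1, 2, 3], [2, 3, 4])
    assert delta == pytest.approx(-1.0)
    assert lo == pytest.approx(-3.267, abs=1e-3)
    assert hi == pytest.approx(1.267, abs=1e-3)


def test_mean_diff_ci_brackets_and_shrinks(rng):
    widths = []
    for n in (10, 40, 160):
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n)
        delta, lo, hi = mean_diff_ci(x, y)
        assert lo <= delta <= hi
        widths.append(hi - lo)
    # width ~ 1/sqrt(n): quadrupling n should roughly halve the width
    assert widths[1] < widths[0] * 0.75
    assert widths[2] < widths[1] * 0.75


def test_mean_diff_ci_insufficient_data():
    with pytest.raises(InsufficientDataError):
        mean_diff_ci([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# characteristic comparison


def test_characteristic_identical_groups(rng):
    g = rng.normal(175, 7, 40)
    res = characteristic_comparison({"A": g, "B": g.copy()})
    assert res["d"] == pytest.approx(0.0, abs=1e-12)
    assert res["omnibus_p"] > 0.9


def test_characteristic_f_equals_t_squared(rng):
    # two-group one-way ANOVA F is the squared pooled t
    for _ in range(5):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.4, 1, 18)
        f = stats.f_oneway(x, y)
        t = stats.ttest_ind(x, y, equal_var=True)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert f.pvalue == pytest.approx(t.pvalue, rel=1e-10)


def test_characteristic_nonnormal_uses_kruskal(rng):
    x = rng.exponential(2.0, 300) ** 3
    y = rng.exponential(2.0, 300) ** 3
    res = characteristic_comparison({"A": x, "B": y})
    assert res["normality_p"] <= 0.05
    assert res["test"] == "kruskal"


def test_characteristic_normal_uses_anova(rng):
    x = rng.normal(176, 8, 200)
    y = rng.normal(177, 7, 200)
    res = characteristic_comparison({"A": x, "B": y})
    assert res["test"] == "anova"
    assert res["normality_p"] > 0.05


def test_characteristic_requires_two_members():
    with pytest.raises(InsufficientDataError):
        characteristic_comparison({"A": np.array([1.0]), "B": np.array([1.0, 2.0])})


# ---------------------------------------------------------------------------
# mixed ANOVA


def _hand_ss_oracle(df):
    """Scalar-loop split-plot decomposition (independent of the implementation)."""
    subjects = sorted(df["subject"].unique())
    levels = sorted(df["speed"].unique())
    k, n = len(levels), len(subjects)
    y = {(s, l): df[(df.subject == s) & (df.speed == l)]["y"].iloc[0]
         for s in subjects for l in levels}
    grp = {s: df[df.subject == s]["grp"].iloc[0] for s in subjects}
    groups = sorted(set(grp.values()))
    grand = sum(y.values()) / (n * k)
    subj_mean = {s: sum(y[(s, l)] for l in levels) / k for s in subjects}
    grp_subjects = {g: [s for s in subjects if grp[s] == g] for g in groups}
    grp_mean = {g: sum(subj_mean[s] for s in grp_subjects[g]) / len(grp_subjects[g])
                for g in groups}
    col_mean = {l: sum(y[(s, l)] for s in subjects) / n for l in levels}
    cell_mean = {(g, l): sum(y[(s, l)] for s in grp_subjects[g]) / len(grp_subjects[g])
                 for g in groups for l in levels}
    ss_group = k * sum(len(grp_subjects[g]) * (grp_mean[g] - grand) ** 2 for g in groups)
    ss_subj = k * sum((subj_mean[s] - grp_mean[grp[s]]) ** 2 for s in subjects)
    ss_speed = n * sum((col_mean[l] - grand) ** 2 for l in levels)
    ss_inter = sum(
        len(grp_subjects[g])
        * (cell_mean[(g, l)] - grp_mean[g] - col_mean[l] + grand) ** 2
        for g in groups for l in levels
    )
    ss_err = (
        sum((y[(s, l)] - subj_mean[s]) ** 2 for s in subjects for l in levels)
        - ss_speed - ss_inter
    )
    n_g = len(groups)
    f_group = (ss_group / (n_g - 1)) / (ss_subj / (n - n_g))
    f_speed = (ss_speed / (k - 1)) / (ss_err / ((n - n_g) * (k - 1)))
    f_inter = (ss_inter / ((n_g - 1) * (k - 1))) / (ss_err / ((n - n_g) * (k - 1)))
    return f_group, f_speed, f_inter


def test_mixed_anova_matches_hand_oracle(toy_mixed_df):
    res = mixed_anova(toy_mixed_df, dv="y", within="speed", subject="subject",
                      between="grp")
    f_group, f_speed, f_inter = _hand_ss_oracle(toy_mixed_df)
    assert res.f_group == pytest.approx(f_group, rel=1e-10)
    assert res.f_within == pytest.approx(f_speed, rel=1e-10)
    assert res.f_interaction == pytest.approx(f_inter, rel=1e-10)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("sizes", [(5, 3), (4, 4), (12, 7)])
def test_mixed_anova_matches_pingouin(seed, sizes):
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(seed)
    n1, n2 = sizes
    rows = []
    for i in range(n1 + n2):
        grp = "A" if i < n1 else "B"
        base = rng.normal(0, 1)
        for j, sp in enumerate([3.3, 4.2, 5.0]):
            rows.append({"subject": f"s{i}", "grp": grp, "speed": sp,
                         "y": base + rng.normal(j * 0.4 + (0.6 if grp == "B" else 0),
                                                0.8)})
    df = pd.DataFrame(rows)
    res = mixed_anova(df, dv="y", within="speed", subject="subject", between="grp")
    ref = pg.mixed_anova(data=df, dv="y", within="speed", subject="subject",
                         between="grp", correction=True).set_index("Source")
    assert res.f_group == pytest.approx(ref.loc["grp", "F"], rel=1e-9)
    assert res.f_within == pytest.approx(ref.loc["speed", "F"], rel=1e-9)
    assert res.f_interaction == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)
    assert res.p_group == pytest.approx(ref.loc["grp", "p_unc"], rel=1e-9)
    assert res.p_within_unc == pytest.approx(ref.loc["speed", "p_unc"], rel=1e-9)
    assert res.epsilon == pytest.approx(ref.loc["speed", "eps"], rel=1e-9)
    sph = pg.sphericity(df, dv="y", within="speed", subject="subject")
    assert res.mauchly_w == pytest.approx(sph.W, rel=1e-9)
    assert res.mauchly_p == pytest.approx(sph.pval, rel=1e-9)


def test_mixed_anova_group_shift_invariance(rng):
    rows = []
    for i in range(12):
        grp = "A" if i < 6 else "B"
        base = rng.normal(0, 1)
        for j, sp in enumerate([3.3, 4.2, 5.0]):
            rows.append({"subject": f"s{i}", "grp": grp, "speed": sp,
                         "y": base + j * 0.5 + rng.normal(0, 0.3)})
    df = pd.DataFrame(rows)
    base_res = mixed_anova(df, dv="y", within="speed", subject="subject",
                           between="grp")
    shifted = df.copy()
    shifted.loc[shifted["grp"] == "B", "y"] += 50.0
    res = mixed_anova(shifted, dv="y", within="speed", subject="subject",
                      between="grp")
    # a pure between-group shift leaves within/interaction untouched
    assert res.f_interaction == pytest.approx(base_res.f_interaction, rel=1e-6)
    assert res.f_within == pytest.approx(base_res.f_within, rel=1e-6)
    assert res.f_group > base_res.f_group
    assert res.p_group < 1e-6


def test_mixed_anova_two_levels_epsilon_one(rng):
    rows = []
    for i in range(10):
        grp = "A" if i < 5 else "B"
        for sp in (3.3, 4.2):
            rows.append({"subject": f"s{i}", "grp": grp, "speed": sp,
                         "y": rng.normal()})
    res = mixed_anova(pd.DataFrame(rows), dv="y", within="speed",
                      subject="subject", between="grp")
    assert res.epsilon == 1.0
    assert res.mauchly_p == 1.0
    assert not res.corrected


def test_mixed_anova_insufficient_groups(toy_mixed_df):
    df = toy_mixed_df.assign(grp="A")
    with pytest.raises(InsufficientDataError):
        mixed_anova(df, dv="y", within="speed", subject="subject", between="grp")


# ---------------------------------------------------------------------------
# post-hoc pairwise


@pytest.fixture
def posthoc_df(rng):
    rows = []
    for i in range(24):
        grp = "S" if i < 14 else "N"
        shift = 0.0 if grp == "S" else -0.9
        for sp in (3.3, 4.2, 5.0):
            rows.append({"participant_id": f"P{i}", "grp": grp, "speed": sp,
                         "y": rng.normal(shift, 1.0)})
    return pd.DataFrame(rows)


def test_posthoc_structure_and_holm(posthoc_df):
    ests = posthoc_pairwise(posthoc_df, dv="y", within="speed", between="grp",
                            group_order=("S", "N"))
    assert len(ests) == 3
    raw = [e.p_raw for e in ests]
    adj = holm_adjust(raw)
    for e, a in zip(ests, adj):
        assert e.p_adjusted == pytest.approx(a)
        assert e.p_adjusted >= e.p_raw - 1e-15
        assert e.ci_low <= e.delta <= e.ci_high


def test_posthoc_sign_convention(posthoc_df):
    # S group has the larger mean; first-listed minus second-listed is positive
    ests = posthoc_pairwise(posthoc_df, dv="y", within="speed", between="grp",
                            group_order=("S", "N"))
    for e in ests:
        assert e.delta > 0
        assert e.d > 0
    flipped = posthoc_pairwise(posthoc_df, dv="y", within="speed", between="grp",
                               group_order=("N", "S"))
    for e, f in zip(ests, flipped):
        assert f.delta == pytest.approx(-e.delta)
        assert f.d == pytest.approx(-e.d)


def test_posthoc_matches_mean_diff_ci(posthoc_df):
    ests = posthoc_pairwise(posthoc_df, dv="y", within="speed", between="grp",
                            group_order=("S", "N"))
    sub = posthoc_df[posthoc_df["speed"] == 3.3]
    x = sub.loc[sub.grp == "S", "y"]
    y = sub.loc[sub.grp == "N", "y"]
    delta, lo, hi = mean_diff_ci(x, y)
    assert ests[0].delta == pytest.approx(delta)
    assert ests[0].ci_low == pytest.approx(lo)
    assert ests[0].ci_high == pytest.approx(hi)


# ---------------------------------------------------------------------------
# power helper


def test_two_sample_power_classic_value():
    # d = 0.5 with n = 64 per arm is the textbook 80 % design
    assert two_sample_power(0.5, 64, 64) == pytest.approx(0.80, abs=0.01)


def test_two_sample_power_monotone_in_n():
    assert two_sample_power(0.5, 100, 100) > two_sample_power(0.5, 30, 30)


def test_stats_config_validation():
    with pytest.raises(InvalidInputError):
        StatsConfig(alpha=0.0)
    with pytest.raises(InvalidInputError):
        StatsConfig(d_thresholds=(0.5, 0.2, 0.8))
    with pytest.raises(InvalidInputError):
        StatsConfig(normality_test="shapiro")
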