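"""Inference layer: closed-form oracles, published-statistic recomputation,
and Monte-Carlo calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats as sps

from slstream.lexicon import DesignError
from slstream.stats import (
    bonferroni,
    effect_size_and_power,
    gg_epsilon,
    mixed_rm_anova,
    one_sample_t,
    pairwise_bonferroni,
    significance_label,
)


def test_one_sample_t_closed_form():
    vals = [52.0, 58.0, 61.0, 49.0, 66.0, 55.0]
    res = one_sample_t(vals)
    mean, sd, n = np.mean(vals), np.std(vals, ddof=1), len(vals)
    assert res.t == pytest.approx((mean - 50) / (sd / np.sqrt(n)), abs=1e-12)
    assert res.df == n - 1
    # scipy as an independent route
    t_sp, p_sp = sps.ttest_1samp(vals, 50.0, alternative="greater")
    assert res.t == pytest.approx(t_sp, abs=1e-12)
    assert res.p == pytest.approx(p_sp, abs=1e-12)
    two = one_sample_t(vals, tail="two")
    assert two.p == pytest.approx(2 * sps.t.sf(abs(two.t), two.df), abs=1e-15)


def test_one_sample_t_from_summaries_matches_published():
    # published: t(15) = 2.70, p = 0.008 (one-tailed)
    res = one_sample_t(mean=55.9, sd=8.7, n=16)
    assert res.t == pytest.approx(2.71, abs=0.005)
    assert res.p == pytest.approx(0.008, abs=0.001)
    assert one_sample_t(mean=71.5, sd=12.3, n=16).t == pytest.approx(7.00, abs=0.01)
    assert one_sample_t(mean=62.2, sd=15.1, n=23).t == pytest.approx(3.88, abs=0.01)
    assert one_sample_t(mean=65.8, sd=23.0, n=23).t == pytest.approx(3.29, abs=0.01)


def test_one_sample_t_degenerate_inputs():
    with pytest.raises(DesignError):
        one_sample_t([50.0])
    with pytest.raises(DesignError):
        one_sample_t([50.0, 50.0, 50.0])  # zero variance at the null
    inf_case = one_sample_t([60.0, 60.0, 60.0])
    assert inf_case.t == np.inf and inf_case.p == 0.0


def test_type_one_error_calibration(rng):
    """One-tailed chance test rejects ~5% of null cohorts (2,000 replicates)."""
    n, trials, reps = 16, 16, 2000
    acc = rng.binomial(trials, 0.5, size=(reps, n)) / trials * 100
    rejections = 0
    for row in acc:
        if np.std(row, ddof=1) == 0:
            continue
        if one_sample_t(row).p < 0.05:
            rejections += 1
    assert rejections / reps == pytest.approx(0.05, abs=0.01)


def test_gg_epsilon_bounds_and_sphericity():
    k = 4
    cs = np.full((k, k), 0.4) + np.eye(k) * 0.6  # compound symmetry
    assert gg_epsilon(cs) == pytest.approx(1.0)
    assert gg_epsilon(np.eye(2)) == pytest.approx(1.0)  # k=2 forced by bounds
    with pytest.raises(DesignError):
        gg_epsilon(np.ones((3, 3)))  # singular after centering


def test_gg_epsilon_matches_elementwise_formula(rng):
    """Textbook element-wise formula as an independent oracle, 1,000 draws."""
    for _ in range(1000):
        k = int(rng.integers(2, 6))
        a = rng.normal(size=(k, k + 3))
        s = a @ a.T
        # element-wise statement of the correction factor
        sbar = s.mean()
        dbar = np.diag(s).mean()
        row_means = s.mean(axis=1)
        num = (k * (dbar - sbar)) ** 2
        den = (k - 1) * (
            (s**2).sum() - 2 * k * (row_means**2).sum() + k**2 * sbar**2
        )
        expected = np.clip(num / den, 1 / (k - 1), 1.0)
        assert gg_epsilon(s) == pytest.approx(expected, abs=1e-10)
        assert 1 / (k - 1) - 1e-12 <= gg_epsilon(s) <= 1.0 + 1e-12


def test_effect_size_and_power_published_pair():
    # published: F(1, 52) = 12.54 -> eta_p2 = 0.194, pw = 0.935
    eta, pw = effect_size_and_power(12.54, 1, 52)
    assert eta == pytest.approx(0.194, abs=0.0005)
    assert pw == pytest.approx(0.935, abs=0.0005)
    eta0, pw0 = effect_size_and_power(0.0, 1, 52)
    assert eta0 == 0.0 and pw0 == pytest.approx(0.05)


def test_power_matches_quadrature(rng):
    """Observed power equals numerical integration of the noncentral-F
    density above the critical value."""
    for _ in range(100):
        F = float(rng.uniform(0.5, 15))
        df1 = int(rng.integers(1, 5))
        df2 = int(rng.integers(5, 60))
        _, pw = effect_size_and_power(F, df1, df2)
        crit = sps.f.ppf(0.95, df1, df2)
        quad, _ = integrate.quad(
            lambda x: sps.ncf.pdf(x, df1, df2, F * df1), crit, np.inf, limit=200
        )
        assert pw == pytest.approx(quad, abs=1e-6)


def test_bonferroni_arithmetic():
    assert bonferroni([0.01], m=3) == [pytest.approx(0.03)]
    assert bonferroni([0.6], m=3) == [1.0]
    with pytest.raises(DesignError):
        bonferroni([0.01], m=0)
    with pytest.raises(DesignError):
        bonferroni([1.5], m=2)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
def test_bonferroni_dominates_raw(pvals):
    adj = bonferroni(pvals)
    assert all(a >= p for a, p in zip(adj, pvals))
    assert all(0 <= a <= 1 for a in adj)


def _mixed_2x2_table():
    # 3 subjects per group, within factor with 2 levels
    rows = []
    data = {
        ("g1", "w1"): [4.0, 6.0, 5.0],
        ("g1", "w2"): [7.0, 9.0, 8.0],
        ("g2", "w1"): [3.0, 2.0, 4.0],
        ("g2", "w2"): [5.0, 3.0, 4.0],
    }
    for (g, w), vals in data.items():
        for i, v in enumerate(vals):
            rows.append({"subj": f"{g}_{i}", "group": g, "cond": w, "y": v})
    return pd.DataFrame(rows)


def _hand_mixed_anova(df):
    """Sums-of-squares arithmetic for a balanced one-between/one-within
    design, written out longhand as an independent oracle."""
    groups = sorted(df.group.unique())
    conds = sorted(df.cond.unique())
    subjects = sorted(df.subj.unique())
    n = len(subjects) / len(groups)
    k = len(conds)
    grand = df.y.mean()
    ss_between_subj = sum(
        k * (df[df.subj == s].y.mean() - grand) ** 2 for s in subjects
    )
    ss_group = sum(
        n * k * (df[df.group == g].y.mean() - grand) ** 2 for g in groups
    )
    ss_subj_within = ss_between_subj - ss_group
    ss_total = ((df.y - grand) ** 2).sum()
    ss_within_subj = ss_total - ss_between_subj
    ss_cond = sum(
        n * len(groups) * (df[df.cond == c].y.mean() - grand) ** 2 for c in conds
    )
    ss_cells = sum(
        n * (df[(df.group == g) & (df.cond == c)].y.mean() - grand) ** 2
        for g in groups
        for c in conds
    )
    ss_interaction = ss_cells - ss_group - ss_cond
    ss_error_within = ss_within_subj - ss_cond - ss_interaction
    df_group = len(groups) - 1
    df_subj = len(subjects) - len(groups)
    df_cond = k - 1
    df_inter = df_group * df_cond
    df_err = df_subj * df_cond
    return {
        "group": (ss_group / df_group) / (ss_subj_within / df_subj),
        "cond": (ss_cond / df_cond) / (ss_error_within / df_err),
        "group:cond": (ss_interaction / df_inter) / (ss_error_within / df_err),
    }


def test_mixed_anova_matches_hand_computation():
    df = _mixed_2x2_table()
    res = mixed_rm_anova(df, dv="y", subject="subj", between="group", within=["cond"])
    by_name = {r.effect: r for r in res}
    oracle = _hand_mixed_anova(df)
    assert by_name["group"].F == pytest.approx(oracle["group"], abs=1e-10)
    assert by_name["cond"].F == pytest.approx(oracle["cond"], abs=1e-10)
    assert by_name["group:cond"].F == pytest.approx(oracle["group:cond"], abs=1e-10)
    for r in res:
        assert r.epsilon == 1.0  # two-level within factor
        assert 0 <= r.eta_p2 < 1
        assert r.pw >= 0.05


def test_anova_identical_values_give_zero_f():
    df = _mixed_2x2_table()
    df["y"] = 5.0
    res = mixed_rm_anova(df, dv="y", subject="subj", between="group", within=["cond"])
    assert all(r.F == pytest.approx(0.0, abs=1e-9) for r in res)


def test_fully_within_design_runs():
    rng = np.random.default_rng(3)
    rows = [
        {"subj": s, "a": a, "b": b, "y": rng.normal()}
        for s in range(6)
        for a in ("x", "y")
        for b in ("1", "2")
    ]
    res = mixed_rm_anova(
        pd.DataFrame(rows), dv="y", subject="subj", within=["a", "b"]
    )
    assert {r.effect for r in res} == {"a", "b", "a:b"}
    assert all(r.epsilon == 1.0 for r in res)


def test_missing_cells_reported():
    df = _mixed_2x2_table().iloc[:-1]
    with pytest.raises(DesignError, match="cells"):
        mixed_rm_anova(df, dv="y", subject="subj", between="group", within=["cond"])


def test_pairwise_bonferroni_adjusts():
    df = _mixed_2x2_table()
    out = pairwise_bonferroni(df, dv="y", group="group")
    assert len(out) == 1
    assert (out.p_bonf >= out.p_unc).all()


def test_significance_labels():
    assert significance_label(0.01) == "significant"
    assert significance_label(0.06) == "marginal"
    assert significance_label(0.2) == "ns"
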