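"""Inferential statistics against hand oracles and independent libraries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special, stats

from rgcest.cohort_stats import (
    games_howell,
    one_way_anova,
    pearson_r2,
    roc_auc,
    welch_t,
)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

class TestAnova:
    def test_identical_group_means(self):
        vals = np.array([1.0, 2.0, 3.0] * 3)
        labs = np.repeat(["a", "b", "c"], 3)
        res = one_way_anova(vals, labs)
        assert res.f_statistic == pytest.approx(0.0)
        assert res.eta_squared == pytest.approx(0.0)

    def test_matches_hand_sum_of_squares(self):
        groups = {"a": [1.0, 2, 3], "b": [2.0, 3, 4], "c": [6.0, 7, 8]}
        vals = np.concatenate(list(groups.values()))
        labs = np.repeat(list(groups), 3)
        res = one_way_anova(vals, labs)
        grand = vals.mean()
        ssb = sum(3 * (np.mean(g) - grand) ** 2 for g in groups.values())
        ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups.values())
        f = (ssb / 2) / (ssw / 6)
        assert res.f_statistic == pytest.approx(f, rel=1e-9)
        assert res.eta_squared == pytest.approx(ssb / (ssb + ssw), rel=1e-9)
        # agree with the independent scipy implementation
        sp = stats.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(sp.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(sp.pvalue, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0, 2.0, 3.0], ["a", "a", "a"])

    def test_eta_squared_limits(self, rng):
        vals = rng.normal(size=60)
        labs = np.repeat(["a", "b", "c"], 20)
        res = one_way_anova(vals, labs)
        assert 0.0 <= res.eta_squared <= 1.0
        # shrink within-group variance toward zero with distinct means
        tight = np.repeat([0.0, 5.0, 10.0], 20) + 1e-8 * vals
        res = one_way_anova(tight, labs)
        assert res.eta_squared > 0.999999


# ---------------------------------------------------------------------------
# Games-Howell
# ---------------------------------------------------------------------------

def studentized_range_sf_quadrature(q: float, k: int, df: float) -> float:
    """Survival function of the studentized range by direct quadrature.

    P(Q <= q) = ∫ g(s) * k ∫ φ(z) [Φ(z) − Φ(z − q·s)]^(k−1) dz ds with
    g the density of S = χ_df / sqrt(df).
    """

    def chi_scaled_pdf(s):
        return (
            df ** (df / 2)
            / (special.gamma(df / 2) * 2 ** (df / 2 - 1))
            * s ** (df - 1)
            * np.exp(-df * s * s / 2)
        )

    def inner(s):
        f = lambda z: stats.norm.pdf(z) * (
            stats.norm.cdf(z) - stats.norm.cdf(z - q * s)
        ) ** (k - 1)
        val, _ = integrate.quad(f, -8, 8, limit=200)
        return k * val

    cdf, _ = integrate.quad(lambda s: chi_scaled_pdf(s) * inner(s), 1e-9, 8, limit=200)
    return 1.0 - cdf


class TestGamesHowell:
    def test_identical_groups(self):
        vals = np.array([1.0, 2, 3, 4] * 2)
        labs = np.repeat(["a", "b"], 4)
        (comp,) = games_howell(vals, labs)
        assert comp.mean_difference == pytest.approx(0.0)
        assert comp.p_value == pytest.approx(1.0)

    def test_reported_mean_difference_is_absolute(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(5, 2, 6)
        (comp,) = games_howell(np.r_[a, b], np.repeat(["a", "b"], [10, 6]))
        assert comp.mean_difference == pytest.approx(abs(a.mean() - b.mean()))
        assert comp.mean_difference >= 0
        assert comp.signed_difference == pytest.approx(a.mean() - b.mean())

    def test_p_matches_quadrature_oracle_on_small_groups(self, rng):
        vals = np.r_[
            rng.normal(0, 1, 5), rng.normal(1.5, 2, 6), rng.normal(3, 1, 4)
        ]
        labs = np.repeat(["a", "b", "c"], [5, 6, 4])
        for comp in games_howell(vals, labs):
            oracle = studentized_range_sf_quadrature(comp.statistic, 3, comp.df)
            assert comp.p_value == pytest.approx(oracle, abs=1e-4)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        vals = np.r_[
            rng.normal(10, 2, 12), rng.normal(12, 4, 8), rng.normal(15, 1, 6)
        ]
        labs = np.repeat(["a", "b", "c"], [12, 8, 6])
        df = pd.DataFrame({"y": vals, "g": labs})
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        ours = {
            frozenset((c.group_a, c.group_b)): c for c in games_howell(vals, labs)
        }
        for _, row in ref.iterrows():
            c = ours[frozenset((row["A"], row["B"]))]
            assert c.df == pytest.approx(row["df"], rel=1e-9)
            assert c.p_value == pytest.approx(row["pval"], abs=1e-9)
            assert c.mean_difference == pytest.approx(abs(row["diff"]), rel=1e-9)

    def test_two_group_p_equals_welch(self, rng):
        """With k = 2 the studentized-range test reduces to Welch's t."""
        for _ in range(5):
            a = rng.normal(0, 1, rng.integers(4, 12))
            b = rng.normal(0.8, 2.5, rng.integers(4, 12))
            (comp,) = games_howell(np.r_[a, b], np.repeat(["a", "b"], [a.size, b.size]))
            t, df, p = welch_t(a, b)
            assert comp.df == pytest.approx(df, rel=1e-12)
            assert comp.statistic == pytest.approx(abs(t) * np.sqrt(2), rel=1e-12)
            assert comp.p_value == pytest.approx(p, abs=1e-6)

    @given(
        shift=st.floats(-1e3, 1e3, allow_nan=False),
        scale=st.floats(0.01, 1e3, allow_nan=False),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariance_to_shift_and_positive_rescaling(self, shift, scale):
        rng = np.random.default_rng(99)
        vals = np.r_[rng.normal(0, 1, 8), rng.normal(1, 2, 6), rng.normal(2, 1, 7)]
        labs = np.repeat(["a", "b", "c"], [8, 6, 7])
        base = games_howell(vals, labs)
        moved = games_howell(vals * scale + shift, labs)
        for b, m in zip(base, moved):
            assert m.p_value == pytest.approx(b.p_value, abs=1e-9)
            assert m.statistic == pytest.approx(b.statistic, rel=1e-6)

    def test_zero_variance_pair_rejected(self):
        vals = np.array([1.0, 1, 1, 2, 2, 2])
        labs = np.repeat(["a", "b"], 3)
        with pytest.raises(ValueError):
            games_howell(vals, labs)


# ---------------------------------------------------------------------------
# Pearson / Welch
# ---------------------------------------------------------------------------

class TestPearsonWelch:
    def test_identity_correlation(self):
        x = np.array([1.0, 2, 3, 5, 8])
        r2, p = pearson_r2(x, x)
        assert r2 == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r2([1.0, 2, 3], [4.0, 4, 4])

    def test_matches_hand_covariance_arithmetic(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 7])
        r2, p = pearson_r2(x, y)
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r2 == pytest.approx(r**2, rel=1e-9)
        t = r * np.sqrt(3 / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 3), rel=1e-9)

    def test_welch_identical_samples(self):
        t, df, p = welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_matches_manual_formula(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([2.0, 4, 6, 8])
        t, df, p = welch_t(a, b)
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        assert t == pytest.approx(t_hand, rel=1e-9)
        assert df == pytest.approx(df_hand, rel=1e-9)

    def test_welch_degenerate_samples(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])  # zero variance, unequal means


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def auc_pair_counting(scores, labels, positive):
    """Exhaustive between-class pair enumeration (ties count half)."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        res = roc_auc([1.0, 2, 3, 10, 11, 12], ["n"] * 3 + ["p"] * 3)
        assert res.auc == pytest.approx(1.0)
        assert res.positive_label == "p"

    def test_all_ties(self):
        res = roc_auc([5.0] * 6, ["n", "p"] * 3)
        assert res.auc == pytest.approx(0.5)
        assert res.p_value == pytest.approx(1.0)

    def test_orientation_flips_to_discriminating_side(self):
        # positives score LOWER; default orientation reports AUC >= 0.5
        res = roc_auc([1.0, 2, 3, 10, 11, 12], ["p"] * 3 + ["n"] * 3)
        assert res.auc == pytest.approx(1.0)
        assert res.positive_label == "n"
        assert res.direction == "n > p"
        pinned = roc_auc([1.0, 2, 3, 10, 11, 12], ["p"] * 3 + ["n"] * 3,
                         positive_label="p")
        assert pinned.auc == pytest.approx(0.0)

    def test_eight_observation_toy_matches_enumeration(self):
        scores = [3.0, 1.0, 2.0, 2.0, 5.0, 4.0, 2.0, 6.0]
        labels = ["n", "n", "n", "n", "p", "p", "p", "p"]
        res = roc_auc(scores, labels, positive_label="p")
        assert res.auc == pytest.approx(auc_pair_counting(scores, labels, "p"))

    def test_agrees_with_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if len(set(labels)) < 2:
            labels[0] = 1 - labels[0]
        res = roc_auc(scores, labels, positive_label=1)
        assert res.auc == pytest.approx(sk.roc_auc_score(labels, scores), rel=1e-12)

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_pair_counting_oracle_on_all_small_instances(self, data):
        n = data.draw(st.integers(4, 30))
        scores = data.draw(
            st.lists(
                st.floats(-100, 100, allow_nan=False, allow_infinity=False),
                min_size=n, max_size=n,
            )
        )
        labels = data.draw(
            st.lists(st.sampled_from(["n", "p"]), min_size=n, max_size=n)
        )
        if len(set(labels)) < 2:
            labels[0] = "p" if labels[0] == "n" else "n"
        res = roc_auc(scores, labels, positive_label="p")
        assert res.auc == pytest.approx(
            auc_pair_counting(scores, labels, "p"), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], ["p", "p"])
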