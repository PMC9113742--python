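"""Band ratios and the inferential toolbox (t, ANOVA, Tukey-Kramer)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormcal.stats import (
    band_ratio,
    band_ratio_table,
    one_way_anova,
    t_test,
    tukey_kramer,
    two_way_anova,
)
from wormcal.synth import gen_densitometry


class TestBandRatio:
    def test_arithmetic(self):
        assert band_ratio(50, 100) == pytest.approx(0.5)
        assert band_ratio(7.3, 7.3) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            band_ratio(50, 0)
        with pytest.raises(ValueError):
            band_ratio(-1, 100)

    def test_triplicate_means_recover_group_truth(self):
        means = {"WT": 1.0, "KO": 0.3}
        df, _ = gen_densitometry(group_means=means, cv=0.15, reps=200, seed=1)
        table = band_ratio_table(df)
        for grp, true_mean in means.items():
            vals = table.loc[table["group"] == grp, "ratio"]
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - true_mean) < 3 * se


class TestTTest:
    def test_identical_samples_p_one(self):
        t, p = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        t, p = t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-3)
        assert p == pytest.approx(0.288, abs=5e-3)

    def test_zero_variance_equal_means_convention(self):
        t, p = t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            t_test(rng.normal(size=10), rng.normal(size=10))[1] < 0.05
            for _ in range(5000)
        )
        assert abs(rejections / 5000 - 0.05) < 0.01

    @given(gain=st.floats(0.1, 50), offset=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, gain, offset):
        a = np.array([1.0, 2.5, 3.0, 4.2])
        b = np.array([2.0, 3.1, 4.4, 5.0])
        _, p0 = t_test(a, b)
        _, p1 = t_test(gain * a + offset, gain * b + offset)
        assert p1 == pytest.approx(p0, rel=1e-9)


class TestOneWayAnova:
    def test_identical_constant_groups(self):
        f, p = one_way_anova([[3.0, 3.0], [3.0, 3.0], [3.0, 3.0]])
        assert (f, p) == (0.0, 1.0)

    def test_two_groups_redirected(self):
        with pytest.raises(ValueError, match="t_test"):
            one_way_anova([[1, 2], [3, 4]])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(1)
        rej = sum(
            one_way_anova([rng.normal(size=8) for _ in range(3)])[1] < 0.05
            for _ in range(5000)
        )
        assert abs(rej / 5000 - 0.05) < 0.01

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                  rng.normal(3, 1, 20)]
        f, p = one_way_anova(groups)
        assert p < 0.001

    def test_t_squared_equals_f_identity(self):
        """Classical identity on two groups, at machine precision."""
        from scipy.stats import f_oneway

        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.normal(size=9), rng.normal(1, 1, size=7)
            t, _ = t_test(a, b)
            f = f_oneway(a, b).statistic
            assert t**2 == pytest.approx(f, rel=1e-12)


class TestTukeyKramer:
    def test_identical_groups_nothing_flagged(self):
        res = tukey_kramer([[1.0, 1.0, 1.0]] * 3)
        assert not any(sig for *_, sig in res)

    def test_only_shifted_pairs_flagged(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 25), rng.normal(0, 1, 30),
                  rng.normal(4, 1, 20)]  # unequal n exercises Kramer
        res = {(i, j): sig for i, j, _, sig in tukey_kramer(groups)}
        assert res[(0, 2)] and res[(1, 2)]
        assert not res[(0, 1)]

    def test_familywise_error_controlled(self):
        rng = np.random.default_rng(5)
        fwe = 0
        for _ in range(2000):
            groups = [rng.normal(size=8) for _ in range(3)]
            if any(sig for *_, sig in tukey_kramer(groups, alpha=0.05)):
                fwe += 1
        assert fwe / 2000 <= 0.05 + 0.01


def _balanced_two_way_oracle(df, value, fa, fb):
    """Closed-form balanced two-way ANOVA decomposition."""
    grand = df[value].mean()
    n = len(df)
    a_lv, b_lv = df[fa].unique(), df[fb].unique()
    cell_n = len(df) / (len(a_lv) * len(b_lv))
    ssa = sum(
        (df[df[fa] == a][value].mean() - grand) ** 2 * len(df[df[fa] == a])
        for a in a_lv
    )
    ssb = sum(
        (df[df[fb] == b][value].mean() - grand) ** 2 * len(df[df[fb] == b])
        for b in b_lv
    )
    ssab = 0.0
    sse = 0.0
    for a in a_lv:
        for b in b_lv:
            cell = df[(df[fa] == a) & (df[fb] == b)][value]
            interaction = (cell.mean() - df[df[fa] == a][value].mean()
                           - df[df[fb] == b][value].mean() + grand)
            ssab += cell_n * interaction**2
            sse += ((cell - cell.mean()) ** 2).sum()
    dfa, dfb = len(a_lv) - 1, len(b_lv) - 1
    dfab = dfa * dfb
    dfe = n - len(a_lv) * len(b_lv)
    return {
        fa: (ssa / dfa) / (sse / dfe),
        fb: (ssb / dfb) / (sse / dfe),
        f"{fa}:{fb}": (ssab / dfab) / (sse / dfe),
    }


class TestTwoWayAnova:
    def _table(self, effect_a=1.0, effect_b=0.0, interaction=0.0, noise=0.5,
               reps=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for ai, a in enumerate(("a0", "a1", "a2")):
            for bi, b in enumerate(("b0", "b1")):
                mu = effect_a * ai + effect_b * bi + interaction * ai * bi
                for _ in range(reps):
                    rows.append({"y": mu + rng.normal(0, noise),
                                 "geno": a, "age": b})
        return pd.DataFrame(rows)

    def test_additive_noiseless_data_has_zero_interaction(self):
        df = self._table(effect_a=2.0, effect_b=1.0, interaction=0.0, noise=0.0)
        # add infinitesimal jitter so the residual is not exactly singular
        rng = np.random.default_rng(1)
        df["y"] += rng.normal(0, 1e-9, len(df))
        res = two_way_anova(df, "y", "geno", "age")
        # perfectly additive: the interaction explains nothing
        assert res.loc["geno:age", "sum_sq"] < 1e-12 * res.loc["geno", "sum_sq"]

    def test_pure_interaction_pattern(self):
        rng = np.random.default_rng(2)
        rows = []
        for a in ("a0", "a1"):
            for b in ("b0", "b1"):
                mu = 2.0 if a == "a1" and b == "b1" else 0.0
                for _ in range(8):
                    rows.append({"y": mu + rng.normal(0, 0.5), "geno": a,
                                 "age": b})
        res = two_way_anova(pd.DataFrame(rows), "y", "geno", "age")
        assert res.loc["geno:age", "p_value"] < 0.05

    def test_matches_closed_form_on_balanced_design(self):
        df = self._table(effect_a=1.5, effect_b=0.7, interaction=0.4, seed=3)
        res = two_way_anova(df, "y", "geno", "age")
        oracle = _balanced_two_way_oracle(df, "y", "geno", "age")
        for effect, f_true in oracle.items():
            assert res.loc[effect, "F"] == pytest.approx(f_true, rel=1e-9)

    def test_empty_cell_rejected(self):
        df = self._table()
        df = df[~((df["geno"] == "a2") & (df["age"] == "b1"))]
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova(df, "y", "geno", "age")
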