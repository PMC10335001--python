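import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from slopesim.meta import (
    DESIGN_FACTORS,
    IncompleteFactorialError,
    anova_eta2,
    threshold_percentages,
    tukey_hsd,
)


def _toy_grid(outcome_fn, reps_per_cell=1):
    """Complete balanced factorial with a deterministic outcome."""
    levels = {
        "n_waves": [3, 4],
        "class_size": [10, 20],
        "n_classrooms": [20, 30],
        "prop_treatment": [0.5, 0.3],
        "icc": [0.086, 0.2],
        "effect_label": ["small", "large"],
    }
    rows = []
    for cell in itertools.product(*levels.values()):
        d = dict(zip(levels.keys(), cell))
        for _ in range(reps_per_cell):
            d2 = dict(d)
            d2["power"] = outcome_fn(d)
            rows.append(d2)
    return pd.DataFrame(rows)


class TestAnova:
    def test_constant_outcome_gives_zero_eta2(self):
        tab = anova_eta2(_toy_grid(lambda d: 0.5), "power")
        terms = tab[tab["term"] != "Residual"]
        assert np.allclose(terms["eta_squared"], 0.0)

    def test_single_factor_signal_hand_computed(self):
        # outcome splits 0/1 along effect_label only: eta2(effect) = 1
        tab = anova_eta2(
            _toy_grid(lambda d: 1.0 if d["effect_label"] == "large" else 0.0), "power"
        )
        tab = tab.set_index("term")["eta_squared"]
        assert tab["effect_label"] == pytest.approx(1.0)
        for f in DESIGN_FACTORS:
            if f != "effect_label":
                assert tab[f] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_by_two(self):
        # classic 2x2 with cell means (0, 0, 1, 1) split along A
        df = pd.DataFrame(
            {
                "A": ["a1", "a1", "a2", "a2"] * 2,
                "B": ["b1", "b2", "b1", "b2"] * 2,
                "y": [0, 0, 1, 1, 0.2, -0.2, 1.2, 0.8],
            }
        )
        tab = anova_eta2(df, "y", factors=("A", "B")).set_index("term")
        # by hand: SS_A = 8 * mean-diff^2 contribution = 2.0; SS_B = 0.02 etc.
        grand = df["y"].mean()
        ss_a = sum(
            len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("A")
        )
        ss_total = ((df["y"] - grand) ** 2).sum()
        assert tab.loc["A", "eta_squared"] == pytest.approx(ss_a / ss_total)

    def test_eta2_sums_to_one_and_affine_invariant(self):
        rng = np.random.default_rng(5)
        base = _toy_grid(lambda d: 0.0)
        base["power"] = rng.uniform(size=len(base))
        tab = anova_eta2(base, "power", include_two_way=True)
        assert tab["eta_squared"].sum() == pytest.approx(1.0)
        scaled = base.assign(power=3.0 * base["power"] - 1.0)
        tab2 = anova_eta2(scaled, "power", include_two_way=True)
        assert np.allclose(tab["eta_squared"], tab2["eta_squared"])

    def test_factor_order_invariance(self):
        rng = np.random.default_rng(6)
        base = _toy_grid(lambda d: 0.0)
        base["power"] = rng.uniform(size=len(base))
        t1 = anova_eta2(base, "power").set_index("term")["eta_squared"]
        t2 = anova_eta2(base, "power", factors=tuple(reversed(DESIGN_FACTORS)))
        t2 = t2.set_index("term")["eta_squared"]
        for f in DESIGN_FACTORS:
            assert t1[f] == pytest.approx(t2[f])

    def test_incomplete_factorial_rejected(self):
        df = _toy_grid(lambda d: 0.5).iloc[:-1]
        with pytest.raises(IncompleteFactorialError, match="missing"):
            anova_eta2(df, "power")


class TestTukey:
    def test_identical_means_not_significant(self):
        # outcome varies only with class size: n_waves group means are
        # exactly equal, so no pair is significant and adjusted p ~ 1
        df = _toy_grid(lambda d: 0.3 if d["class_size"] == 10 else 0.7)
        tab = tukey_hsd(df, "n_waves", "power")
        assert not tab["significant"].any()
        assert np.allclose(tab["adjusted_p"], 1.0)

    def test_shifted_group_detected(self):
        df = pd.DataFrame(
            {
                "A": np.repeat(["g1", "g2", "g3"], 20),
                "B": list(np.tile(["x", "y"], 30)),
                "y": np.concatenate(
                    [
                        np.linspace(-0.5, 0.5, 20),
                        np.linspace(-0.5, 0.5, 20),
                        np.linspace(-0.5, 0.5, 20) + 10.0,  # 10 residual SDs away
                    ]
                ),
            }
        )
        tab = tukey_hsd(df, "A", "y", factors=("A", "B"))
        sig = {(r.level_1, r.level_2): r.significant for r in tab.itertuples()}
        assert sig[("g1", "g3")] and sig[("g2", "g3")]
        assert not sig[("g1", "g2")]

    def test_two_levels_reduce_to_t_test(self):
        rng = np.random.default_rng(8)
        df = _toy_grid(lambda d: 0.0)
        df["power"] = rng.normal(size=len(df))
        tab = tukey_hsd(df, "prop_treatment", "power")
        assert len(tab) == 1
        row = tab.iloc[0]
        assert row["adjusted_p"] == pytest.approx(row["p_unadjusted"], rel=1e-6)

    def test_adjusted_p_dominates_unadjusted(self):
        rng = np.random.default_rng(9)
        df = _toy_grid(lambda d: 0.0)
        df["power"] = rng.normal(size=len(df))
        for factor in ("n_waves", "class_size"):
            tab = tukey_hsd(df, factor, "power")
            assert (tab["adjusted_p"] >= tab["p_unadjusted"] - 1e-12).all()

    def test_single_level_factor_rejected(self):
        df = _toy_grid(lambda d: 0.5)
        df["only"] = 1
        with pytest.raises(ValueError):
            tukey_hsd(df, "only", "power")


class TestThresholdPercentages:
    def test_all_above_threshold(self):
        df = _toy_grid(lambda d: 0.9)
        out = threshold_percentages(df, "power", lambda p: p < 0.8, ["effect_label"])
        assert np.allclose(out["percent"], 0.0)

    def test_counting(self):
        df = pd.DataFrame(
            {
                "g": ["a"] * 12,
                "power": [0.9] * 9 + [0.5] * 3,  # 3 of 12 below 0.8
            }
        )
        out = threshold_percentages(df, "power", lambda p: p < 0.8, ["g"])
        assert out["percent"].iloc[0] == pytest.approx(25.0)

    def test_empty_slice_reported_missing(self):
        df = pd.DataFrame(
            {"a": ["x", "x", "y"], "b": [1, 2, 1], "power": [0.9, 0.7, 0.6]}
        )
        out = threshold_percentages(df, "power", lambda p: p < 0.8, ["a", "b"])
        missing = out[(out["a"] == "y") & (out["b"] == 2)]
        assert len(missing) == 1 and np.isnan(missing["percent"].iloc[0])
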