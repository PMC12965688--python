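import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import skew

import dynexpect as dx
from dynexpect.leaky import LeakyExpectation


class TestDecayWeights:
    def test_closed_form(self):
        w = dx.decay_weights(8, 8.0)
        assert w[0] == pytest.approx(math.exp(-1 / 8))
        assert w[7] == pytest.approx(math.exp(-1.0))

    def test_strictly_positive_decreasing(self):
        w = dx.decay_weights(20, 3.0)
        assert (w > 0).all() and (np.diff(w) < 0).all()

    def test_large_omega_limit(self):
        w = dx.decay_weights(10, 1e9)
        assert w[0] / w[-1] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("omega", [0.0, -1.0])
    def test_invalid_omega(self, omega):
        with pytest.raises(ValueError):
            dx.decay_weights(5, omega)


class TestExpectationStrength:
    def test_constant_history(self):
        assert dx.expectation_strength([50, 50, 50], 8.0) == pytest.approx(50)

    def test_two_point_weighted_mean(self):
        # most recent 80, older 40; brute-force weighted mean
        w1, w2 = math.exp(-1 / 8), math.exp(-2 / 8)
        expected = (w1 * 80 + w2 * 40) / (w1 + w2)
        assert dx.expectation_strength([80, 40], 8.0) == pytest.approx(expected)
        assert expected == pytest.approx(61.25, abs=0.01)

    def test_single_rating(self):
        assert dx.expectation_strength([70], 8.0) == pytest.approx(70)

    def test_empty_history_is_undefined(self):
        assert math.isnan(dx.expectation_strength([], 8.0))

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=30),
           st.integers(0, 29), st.floats(1.0, 50.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_any_rating(self, hist, pos, omega):
        """Replacing one past rating with a larger value never lowers E_t."""
        pos = pos % len(hist)
        bumped = list(hist)
        bumped[pos] = min(bumped[pos] + 10.0, 110.0)
        assert (dx.expectation_strength(bumped, omega)
                >= dx.expectation_strength(hist, omega) - 1e-12)

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=30),
           st.floats(1.0, 50.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_within_history_range(self, hist, omega):
        e = dx.expectation_strength(hist, omega)
        assert min(hist) - 1e-9 <= e <= max(hist) + 1e-9


class TestExpectationPrecision:
    def test_zero_variance_maximal_precision(self):
        var, prec = dx.expectation_precision([55.0, 55.0, 55.0], 8.0,
                                             epsilon=1e-6)
        assert var == pytest.approx(0.0)
        # the fourth-root transform amplifies float residue of the weighted
        # mean, so the guard constant dominates only approximately
        assert prec == pytest.approx(1e6, rel=0.2)

    def test_two_point_weighted_variance(self):
        w1, w2 = math.exp(-1 / 8), math.exp(-2 / 8)
        mean = (w1 * 60 + w2 * 40) / (w1 + w2)
        expected = (w1 * (60 - mean) ** 2 + w2 * (40 - mean) ** 2) / (w1 + w2)
        var, _ = dx.expectation_precision([60.0, 40.0], 8.0)
        assert mean == pytest.approx(50.62, abs=0.01)
        assert var == pytest.approx(expected, rel=1e-12)
        assert var == pytest.approx(99.6, abs=0.1)

    def test_scale_equivariance(self):
        v1, _ = dx.expectation_precision([60.0, 40.0, 80.0], 8.0)
        v2, _ = dx.expectation_precision([120.0, 80.0, 160.0], 8.0)
        assert v2 == pytest.approx(4 * v1)

    def test_negated_mode_monotone(self):
        _, p_low = dx.expectation_precision([60.0, 40.0], 8.0,
                                            precision_mode="negated")
        _, p_high = dx.expectation_precision([51.0, 49.0], 8.0,
                                             precision_mode="negated")
        assert p_high > p_low


class TestComputeExpectations:
    def test_oracle_equivalence(self, agent_table, brute_oracle):
        """Forward-pass recursion equals the full-history brute force."""
        out = dx.compute_expectations(agent_table)
        for pid, sub in out.groupby("participant"):
            s, v = brute_oracle(sub["rating"], sub["cue"], 8.0)
            np.testing.assert_allclose(sub["E_strength_raw"], s, atol=1e-10)
            np.testing.assert_allclose(sub["E_var"], v, atol=1e-10)

    def test_other_cue_trials_do_not_leak(self):
        """Permuting other-cue trials between two same-cue trials leaves a
        cue's expectation series unchanged."""
        base = pd.DataFrame({
            "participant": 1, "run": 1, "trial": range(1, 9),
            "cue": ["LE", "HE", "HE", "LE", "HE", "LE", "HE", "LE"],
            "rating": [30.0, 70, 65, 35, 80, 20, 60, 40]})
        alt = base.copy()
        # swap the ratings of the two HE trials sitting between LE trials
        alt.loc[alt.index[1], "rating"], alt.loc[alt.index[2], "rating"] = 65.0, 70.0
        a = dx.compute_expectations(base)
        b = dx.compute_expectations(alt)
        le_a = a[a.cue == "LE"]["E_strength_raw"].to_numpy()
        le_b = b[b.cue == "LE"]["E_strength_raw"].to_numpy()
        np.testing.assert_allclose(le_a, le_b, atol=1e-12)

    def test_first_same_cue_trial_flagged_undefined(self, agent_table):
        out = dx.compute_expectations(agent_table)
        firsts = out.groupby(["participant", "cue"]).head(1)
        assert (~firsts["E_defined"]).all()
        assert firsts["E_strength_raw"].isna().all()

    def test_minmax_attains_bounds(self, agent_table):
        out = dx.compute_expectations(agent_table)
        for col in ("E_strength", "E_precision"):
            vals = out[col].dropna()
            assert vals.min() == pytest.approx(0.0)
            assert vals.max() == pytest.approx(1.0)
            assert vals.between(0, 1).all()

    def test_per_participant_scope_attains_bounds(self, agent_table):
        out = dx.compute_expectations(agent_table,
                                      normalization="per_participant")
        for _, sub in out.groupby("participant"):
            assert sub["E_strength"].dropna().max() == pytest.approx(1.0)
            assert sub["E_strength"].dropna().min() == pytest.approx(0.0)

    def test_constant_ratings_zero_variance(self):
        t = pd.DataFrame({"participant": 1, "run": 1, "trial": range(1, 11),
                          "cue": ["LE", "HE"] * 5, "rating": 40.0})
        out = dx.compute_expectations(t)
        assert np.allclose(out["E_var"].dropna(), 0.0, atol=1e-10)
        np.testing.assert_allclose(out["E_strength_raw"].dropna(), 40.0)

    def test_power_transform_reduces_skew(self, cohort_table):
        raw = cohort_table["E_var"].dropna()
        raw = raw[raw > 0]
        assert abs(skew(raw ** 0.25)) < abs(skew(raw))

    def test_tracks_generating_latent(self, cohort_table):
        """Analysis-side strength is an affine image of the agent's latent."""
        sub = cohort_table.dropna(subset=["E_strength", "E_strength_true"])
        r = np.corrcoef(sub["E_strength"], sub["E_strength_true"])[0, 1]
        assert r > 0.99

    def test_unsorted_table_rejected(self, agent_table):
        with pytest.raises(ValueError, match="sorted"):
            dx.compute_expectations(
                agent_table.sort_values("rating", kind="stable"))

    def test_intensity_update_source(self, agent_table):
        out = dx.compute_expectations(agent_table, update_source="intensity")
        assert out["E_strength_raw"].dropna().between(1, 2).all()

    def test_transform_requires_fit(self, agent_table):
        with pytest.raises(RuntimeError):
            LeakyExpectation().transform(agent_table)
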