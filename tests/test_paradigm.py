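import numpy as np
import pandas as pd
import pytest

import dynexpect as dx
from dynexpect.paradigm import DesignConstraintError, _max_run, _max_run_of_ones


def max_run(values):
    """Brute-force longest run of identical consecutive values."""
    best = cur = 1
    v = list(values)
    for a, b in zip(v, v[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best


class TestGenerateDesign:
    def test_default_design_counts(self, small_design):
        for _, sub in small_design.groupby("participant"):
            assert len(sub) == 160
            assert sub["run"].nunique() == 4
            counts = sub.groupby(["cue", "validity"]).size()
            assert counts[("LE", "valid")] == 60
            assert counts[("LE", "invalid")] == 20
            assert counts[("HE", "valid")] == 60
            assert counts[("HE", "invalid")] == 20

    def test_valid_trials_match_cue_intensity(self, small_design):
        valid = small_design[small_design.validity == "valid"]
        assert (valid.loc[valid.cue == "LE", "intensity"] == 1).all()
        assert (valid.loc[valid.cue == "HE", "intensity"] == 2).all()
        invalid = small_design[small_design.validity == "invalid"]
        assert (invalid.loc[invalid.cue == "LE", "intensity"] == 2).all()

    def test_full_contingency_has_no_invalid_trials(self):
        d = dx.generate_design(dx.DesignSpec(contingency=1.0, seed=1))
        assert (d.validity == "valid").all()

    def test_sequence_constraints_over_many_seeds(self):
        """Run-length constraints hold in every generated sequence."""
        for seed in range(50):
            d = dx.generate_design(dx.DesignSpec(seed=seed))
            for (_, _), run in d.groupby(["participant", "run"]):
                assert max_run(run.cue) <= 3
                assert max_run(run.intensity) <= 3
                inv = (run.validity == "invalid").to_numpy().astype(int)
                assert _max_run_of_ones(inv) <= 2

    def test_deterministic_under_seed(self):
        a = dx.generate_design(dx.DesignSpec(n_participants=3, seed=9))
        b = dx.generate_design(dx.DesignSpec(n_participants=3, seed=9))
        assert a.to_csv() == b.to_csv()

    def test_counterbalanced_shapes_alternate(self):
        d = dx.generate_design(dx.DesignSpec(n_participants=2, seed=0))
        m1 = d[d.participant == 1].groupby("cue")["cue_shape"].first()
        m2 = d[d.participant == 2].groupby("cue")["cue_shape"].first()
        assert m1["LE"] != m2["LE"] and m1["HE"] != m2["HE"]

    def test_unsatisfiable_constraints_raise(self):
        spec = dx.DesignSpec(max_consecutive_same=1, retry_budget=50, seed=0)
        with pytest.raises(DesignConstraintError, match="constraint"):
            dx.generate_design(spec)

    @pytest.mark.parametrize("kw", [{"contingency": 0.5},
                                    {"contingency": 1.2},
                                    {"trials_per_run": 41},
                                    {"contingency": 0.76}])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            dx.DesignSpec(**kw).validate()

    def test_max_run_helpers_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 2, rng.integers(1, 30))
            assert _max_run(x) == max_run(x)


class TestAgentRatings:
    def test_null_model_constant_ratings(self, small_design):
        params = dx.GenerativeParams(beta0=30.0, beta_intensity=0.0,
                                     beta_strength=0.0, beta_precision=0.0,
                                     beta_interaction=0.0, sd_participant=0.0,
                                     sd_residual=0.0)
        t = dx.simulate_agent_ratings(small_design, params, seed=0)
        np.testing.assert_allclose(t.rating, 30.0)

    def test_clip_fraction_small_at_defaults(self, agent_table):
        assert agent_table.attrs["clip_fraction"] < 0.05

    def test_deterministic_under_seed(self, small_design):
        a = dx.simulate_agent_ratings(small_design, seed=3)
        b = dx.simulate_agent_ratings(small_design, seed=3)
        assert a.to_csv() == b.to_csv()

    def test_he_strength_exceeds_le_when_hp_hurts_more(self, agent_table):
        """Weighted-mean consequence: if HP ratings exceed LP ratings, the
        latent strength after HE cues exceeds that after LE cues."""
        by_int = agent_table.groupby("intensity")["rating"].mean()
        assert by_int[2] > by_int[1]
        by_cue = agent_table.groupby("cue")["E_strength_true"].mean()
        assert by_cue["HE"] > by_cue["LE"]

    def test_latents_defined_after_first_cue_trials(self, agent_table):
        pos = agent_table.groupby(["participant", "cue"]).cumcount()
        assert agent_table.loc[pos == 0, "E_strength_true"].isna().all()
        assert agent_table.loc[pos >= 1, "E_strength_true"].notna().all()
        assert agent_table.loc[pos <= 1, "E_precision_true"].isna().all()
        assert agent_table.loc[pos >= 2, "E_precision_true"].notna().all()

    def test_latent_bounds(self, agent_table):
        assert agent_table["E_strength_true"].dropna().between(0, 1).all()
        assert agent_table["E_precision_true"].dropna().between(0, 1).all()


class TestNeuralFeatures:
    def test_exact_plant_without_noise(self, agent_table):
        plant = dx.MediationPlant(a_path=-0.5, b_path=-0.4, c_prime=0.2,
                                  sd_mediator=0.0, sd_outcome=0.0)
        t = dx.simulate_neural_features(agent_table, plant, seed=0)
        x = t["E_strength_true"]
        np.testing.assert_allclose(t["alpha_power"], -0.5 * x)
        np.testing.assert_allclose(t["lep_mag"],
                                   -0.4 * t["alpha_power"] + 0.2 * x)

    def test_zero_a_path_gives_unrelated_mediator(self, agent_table):
        plant = dx.MediationPlant(a_path=0.0, sd_mediator=1.0)
        t = dx.simulate_neural_features(agent_table, plant, seed=1)
        sub = t.dropna(subset=["E_strength_true"])
        r = np.corrcoef(sub["E_strength_true"], sub["alpha_power"])[0, 1]
        assert abs(r) < 0.15

    def test_predictor_selectable(self, agent_table):
        t = dx.simulate_neural_features(agent_table, predictor="precision",
                                        seed=2)
        assert t["alpha_power"].isna().equals(t["E_precision_true"].isna())

    def test_unknown_predictor_column(self, agent_table):
        with pytest.raises(KeyError):
            dx.simulate_neural_features(agent_table, predictor="nope")


class TestErpEpochs:
    def test_noiseless_latency_exact(self):
        ep, truth = dx.simulate_erp_epochs(n_trials=10, noise_sd=0.0,
                                           amplitude_jitter=0.0, seed=0)
        _, lat = dx.measure_n2_p2(ep, lowpass=None)
        assert lat["n2"] == pytest.approx(truth.attrs["n2_latency"], abs=2.0)
        assert lat["p2"] == pytest.approx(truth.attrs["p2_latency"], abs=2.0)

    def test_zero_amplitude_gives_zero(self):
        ep, _ = dx.simulate_erp_epochs(
            n_trials=5, noise_sd=0.0, amplitude_jitter=0.0,
            n2={"amplitude": 0.0}, p2={"amplitude": 0.0}, seed=0)
        amps, _ = dx.measure_n2_p2(ep, lowpass=None)
        np.testing.assert_allclose(amps.to_numpy(), 0.0, atol=1e-12)

    def test_truth_matches_data_scale(self):
        ep, truth = dx.simulate_erp_epochs(n_trials=20, noise_sd=0.0,
                                           seed=3)
        assert len(truth) == 20
        assert (truth["n2_amplitude"] <= 0).all()
        assert (truth["p2_amplitude"] >= 0).all()
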