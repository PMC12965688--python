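import numpy as np
import pandas as pd
import pytest

import dynexpect as dx


@pytest.fixture(scope="session")
def small_design():
    """Two participants, default four-run design."""
    return dx.generate_design(dx.DesignSpec(n_participants=2, seed=42))


@pytest.fixture(scope="session")
def agent_table(small_design):
    """Agent-simulated ratings with generation-time latents."""
    return dx.simulate_agent_ratings(small_design, seed=7)


@pytest.fixture(scope="session")
def cohort_table():
    """A moderate synthetic cohort (16 participants) with expectations."""
    design = dx.generate_design(dx.DesignSpec(n_participants=16, seed=5))
    table = dx.simulate_agent_ratings(design, seed=6)
    return dx.compute_expectations(table)


def brute_force_expectation(ratings, cues, omega):
    """Independent oracle: full-history loops for strength and variance."""
    ratings = np.asarray(ratings, dtype=float)
    cues = np.asarray(cues)
    n = ratings.size
    strength = np.full(n, np.nan)
    var = np.full(n, np.nan)
    for t in range(n):
        hist = [ratings[j] for j in range(t) if cues[j] == cues[t]]
        past = hist[::-1]                       # most recent first
        if past:
            w = np.exp(-np.arange(1, len(past) + 1) / omega)
            strength[t] = np.sum(w * past) / np.sum(w)
        past_e = [strength[j] for j in range(t)
                  if cues[j] == cues[t] and not np.isnan(strength[j])][::-1]
        if past_e:
            w = np.exp(-np.arange(1, len(past_e) + 1) / omega)
            mean = np.sum(w * np.asarray(past_e)) / np.sum(w)
            var[t] = np.sum(w * (np.asarray(past_e) - mean) ** 2) / np.sum(w)
    return strength, var


@pytest.fixture(scope="session")
def brute_oracle():
    return brute_force_expectation
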