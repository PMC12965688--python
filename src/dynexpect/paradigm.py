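"""Synthetic cued-pain experiments with planted generative effects.

Emulates the probabilistic cueing design used in cued-pain EEG studies: two
visual cues (low/high expectation, LE/HE) each predict their predominant
laser intensity (LP/HP, coded 1/2) with a fixed contingency (default 75%),
over four runs of 40 trials.  Sequences honour pseudorandomisation
constraints (bounded runs of identical cues/intensities, bounded runs of
invalid trials) by rejection resampling, so per-cue contingencies are exact
counts, not sampling frequencies.

A sequential generative agent then produces pain ratings trial by trial from
a linear model in stimulus intensity, its own leaky-integrator expectation
strength and precision, and their interaction, with participant random
intercepts - giving synthetic cohorts whose ground-truth effect sizes are
known.  Additional helpers plant mediation paths into neural feature columns
and build ERP-like epoch fixtures with known N2/P2 components.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .leaky import NOMINAL_MAX_VAR

__all__ = [
    "DesignSpec", "GenerativeParams", "MediationPlant",
    "DesignConstraintError", "generate_design", "simulate_agent_ratings",
    "simulate_neural_features", "simulate_erp_epochs",
]


class DesignConstraintError(RuntimeError):
    """Raised when no admissible trial sequence is found within the retry budget."""


@dataclass
class DesignSpec:
    """Structural parameters of the cued-pain design."""
    n_participants: int = 1
    n_runs: int = 4
    trials_per_run: int = 40
    contingency: float = 0.75
    max_consecutive_same: int = 3
    max_consecutive_invalid: int = 2
    counterbalance: bool = True
    seed: int = 0
    retry_budget: int = 10_000

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_runs < 1:
            raise ValueError("n_participants and n_runs must be >= 1")
        if self.trials_per_run < 2 or self.trials_per_run % 2:
            raise ValueError("trials_per_run must be even and >= 2")
        if not 0.5 < self.contingency <= 1.0:
            raise ValueError("contingency must lie in (0.5, 1]")
        n_cue = self.n_runs * self.trials_per_run // 2
        n_valid = self.contingency * n_cue
        if abs(n_valid - round(n_valid)) > 1e-9:
            raise ValueError(
                f"contingency {self.contingency} is not an exact count over "
                f"{n_cue} trials per cue")


@dataclass
class GenerativeParams:
    """Ground-truth coefficients of the rating-generating agent (NRS units).

    Slope defaults are the printed behavioural estimates for pain-intensity
    ratings (intensity 18.52, strength 26.91, precision 2.72, interaction
    -9.62); the intercept and variance components are chosen so that at
    those slopes almost no ratings (< 1%) touch the 0-100 bounds, keeping
    the clipped linear model effectively linear.
    """
    beta0: float = 12.0
    beta_intensity: float = 18.52
    beta_strength: float = 26.91
    beta_precision: float = 2.72
    beta_interaction: float = -9.62
    sd_participant: float = 8.0
    sd_residual: float = 10.0
    omega_true: float = 8.0

    def validate(self) -> None:
        if self.sd_participant < 0 or self.sd_residual < 0:
            raise ValueError("standard deviations must be >= 0")
        if not self.omega_true > 0:
            raise ValueError("omega_true must be > 0")


@dataclass
class MediationPlant:
    """Planted linear paths for the mediation data-generating process.

    The population indirect effect is ``a_path * b_path`` by construction.
    """
    a_path: float = -0.5
    b_path: float = -0.4
    c_prime: float = 0.2
    sd_mediator: float = 1.0
    sd_outcome: float = 1.0


def _max_run(x: np.ndarray) -> int:
    """Longest run of identical consecutive values."""
    if x.size == 0:
        return 0
    change = np.flatnonzero(x[1:] != x[:-1])
    edges = np.concatenate(([-1], change, [x.size - 1]))
    return int(np.max(np.diff(edges)))


def _spread_counts(total: int, n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` into ``n_bins`` integers differing by at most 1."""
    base = total // n_bins
    counts = np.full(n_bins, base)
    extra = rng.permutation(n_bins)[: total - base * n_bins]
    counts[extra] += 1
    return counts


def _sample_run(n_cue: int, n_invalid: tuple[int, int], spec: DesignSpec,
                rng: np.random.Generator) -> pd.DataFrame:
    """Rejection-sample one run satisfying all sequence constraints."""
    cue = np.array(["LE"] * n_cue + ["HE"] * n_cue)
    validity = np.concatenate([
        np.array(["invalid"] * n_invalid[0]
                 + ["valid"] * (n_cue - n_invalid[0])),
        np.array(["invalid"] * n_invalid[1]
                 + ["valid"] * (n_cue - n_invalid[1])),
    ])
    # intensity follows from cue and validity: a valid LE trial delivers LP (1)
    valid_mask = validity == "valid"
    intensity = np.where((cue == "HE") == valid_mask, 2, 1)
    fails = {"cue": 0, "intensity": 0, "invalid": 0}
    for _ in range(spec.retry_budget):
        order = rng.permutation(2 * n_cue)
        c, v, i = cue[order], validity[order], intensity[order]
        if _max_run(c) > spec.max_consecutive_same:
            fails["cue"] += 1
            continue
        if _max_run(i) > spec.max_consecutive_same:
            fails["intensity"] += 1
            continue
        inv = (v == "invalid").astype(int)
        if _max_run_of_ones(inv) > spec.max_consecutive_invalid:
            fails["invalid"] += 1
            continue
        return pd.DataFrame({"cue": c, "intensity": i, "validity": v})
    worst = max(fails, key=fails.get)
    raise DesignConstraintError(
        f"no admissible sequence within {spec.retry_budget} attempts; most "
        f"frequently violated constraint: {worst!r} ({fails})")


def _max_run_of_ones(x: np.ndarray) -> int:
    if not x.any():
        return 0
    padded = np.concatenate(([0], x, [0]))
    starts = np.flatnonzero(np.diff(padded) == 1)
    ends = np.flatnonzero(np.diff(padded) == -1)
    return int(np.max(ends - starts))


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Generate pseudorandomised trial sequences for all participants.

    Returns a long-format table with one row per trial and columns
    ``participant, run, trial, trial_in_run, cue, cue_shape, intensity,
    validity``.  Per cue and participant the valid:invalid ratio equals the
    contingency exactly; no more than ``max_consecutive_same`` consecutive
    trials share a cue or an intensity and no more than
    ``max_consecutive_invalid`` invalid trials occur in a row (within run).
    Deterministic under a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_cue_run = spec.trials_per_run // 2
    n_cue_total = spec.n_runs * n_cue_run
    n_invalid_total = round((1.0 - spec.contingency) * n_cue_total)
    frames = []
    for p in range(1, spec.n_participants + 1):
        inv_le = _spread_counts(n_invalid_total, spec.n_runs, rng)
        inv_he = _spread_counts(n_invalid_total, spec.n_runs, rng)
        shapes = ({"LE": "diamond", "HE": "square"}
                  if (not spec.counterbalance or p % 2) else
                  {"LE": "square", "HE": "diamond"})
        for r in range(1, spec.n_runs + 1):
            run = _sample_run(n_cue_run, (inv_le[r - 1], inv_he[r - 1]),
                              spec, rng)
            run.insert(0, "participant", p)
            run.insert(1, "run", r)
            run.insert(2, "trial_in_run",
                       np.arange(1, spec.trials_per_run + 1))
            run["cue_shape"] = run["cue"].map(shapes)
            frames.append(run)
    out = pd.concat(frames, ignore_index=True)
    out.insert(2, "trial", out.groupby("participant").cumcount() + 1)
    return out


def simulate_agent_ratings(design: pd.DataFrame,
                           params: GenerativeParams | None = None,
                           omega_model: float | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Generate pain ratings sequentially from a leaky-integrator agent.

    At each trial the agent computes cue-specific expectation strength and
    precision from the ratings it has *already produced*, maps them onto
    [0, 1] with fixed nominal bounds (strength: rating scale 0-100; precision:
    ``1 - Var**0.25 / 2500**0.25``, the maximal variance attainable on the
    scale), and emits

    ``rating = beta0 + beta_intensity*intensity + beta_strength*s
    + beta_precision*p + beta_interaction*s*p + participant intercept
    + noise``, clipped to [0, 100].

    Terms whose latent is undefined (strength on the first same-cue trial,
    precision through the second) contribute zero.  The returned table
    carries the generation-time latents in ``E_strength_true`` and
    ``E_precision_true`` and the realised clipping fraction in
    ``df.attrs["clip_fraction"]``.
    """
    params = params or GenerativeParams()
    params.validate()
    omega = params.omega_true if omega_model is None else float(omega_model)
    if not omega > 0:
        raise ValueError("omega_model must be > 0")
    rng = np.random.default_rng(seed)
    d = math.exp(-1.0 / omega)
    pmax = NOMINAL_MAX_VAR ** 0.25

    out = design.copy()
    n = len(out)
    ratings = np.empty(n)
    s_true = np.full(n, np.nan)
    p_true = np.full(n, np.nan)
    cues = out["cue"].to_numpy()
    intens = out["intensity"].to_numpy(dtype=float)
    clipped = 0
    for _, idx in out.groupby("participant", sort=False).indices.items():
        intercept = rng.normal(0.0, params.sd_participant)
        noise = rng.normal(0.0, params.sd_residual, size=idx.size)
        state: dict[object, list[float]] = {}
        for j, t in enumerate(idx):
            st = state.setdefault(cues[t], [0.0, 0.0, 0.0, 0.0, 0.0])
            num, den, s1, s2, sden = st
            mu = params.beta0 + params.beta_intensity * intens[t] + intercept
            e_t = math.nan
            if den > 0:
                e_t = num / den
                s = e_t / 100.0
                s_true[t] = s
                mu += params.beta_strength * s
                if sden > 0:
                    m = s1 / sden
                    var = max(s2 / sden - m * m, 0.0)
                    p_lat = 1.0 - var ** 0.25 / pmax
                    p_true[t] = p_lat
                    mu += (params.beta_precision * p_lat
                           + params.beta_interaction * s * p_lat)
            r = mu + noise[j]
            if r < 0.0 or r > 100.0:
                clipped += 1
                r = min(max(r, 0.0), 100.0)
            ratings[t] = r
            if not math.isnan(e_t):
                st[2] = d * (e_t + s1)
                st[3] = d * (e_t * e_t + s2)
                st[4] = d * (1.0 + sden)
            st[0] = d * (r + num)
            st[1] = d * (1.0 + den)
    out["rating"] = ratings
    out["E_strength_true"] = s_true
    out["E_precision_true"] = p_true
    out.attrs["clip_fraction"] = clipped / n
    if clipped / n >= 0.05:
        warnings.warn(f"{clipped / n:.1%} of generated ratings were clipped "
                      "to the 0-100 scale", stacklevel=2)
    return out


def simulate_neural_features(table: pd.DataFrame,
                             plant: MediationPlant | None = None,
                             seed: int = 0,
                             predictor: str = "strength",
                             mediator_col: str = "alpha_power",
                             outcome_col: str = "lep_mag") -> pd.DataFrame:
    """Plant a linear mediation path predictor -> mediator -> outcome.

    ``predictor`` is ``"strength"`` / ``"precision"`` (using the agent's
    generation-time latents) or any numeric column name.  Rows with an
    undefined predictor get NaN features.  Signs of the planted paths are
    free, so both a positive indirect path (strength via anticipatory alpha
    suppression) and a negative one (precision via alpha synchronisation)
    can be produced.
    """
    plant = plant or MediationPlant()
    col = {"strength": "E_strength_true",
           "precision": "E_precision_true"}.get(predictor, predictor)
    if col not in table.columns:
        raise KeyError(f"predictor column {col!r} not in table")
    rng = np.random.default_rng(seed)
    out = table.copy()
    x = out[col].to_numpy(dtype=float)
    m = plant.a_path * x + rng.normal(0.0, plant.sd_mediator, x.size)
    y = (plant.b_path * m + plant.c_prime * x
         + rng.normal(0.0, plant.sd_outcome, x.size))
    out[mediator_col] = m
    out[outcome_col] = y
    return out


def simulate_erp_epochs(n_trials: int = 160, fs: float = 500.0,
                        t_range: tuple[float, float] = (-500.0, 1000.0),
                        n2: dict | None = None, p2: dict | None = None,
                        noise_sd: float = 0.0,
                        amplitude_jitter: float = 0.3,
                        channels: tuple[str, ...] = ("Cz",),
                        seed: int = 0):
    """Build ERP-like epochs: a negative (N2) and positive (P2) Gaussian bump
    plus white noise, identical across channels.

    ``n2``/``p2`` are dicts with keys ``latency`` (ms), ``amplitude`` (uV;
    sign applied internally: N2 negative, P2 positive) and ``width`` (ms,
    Gaussian SD).  Per-trial amplitudes are scaled by
    ``max(0, 1 + amplitude_jitter * z)`` so that trial-wise amplitude
    estimates can be validated against a known target.

    Returns ``(EpochSet, truth)`` where ``truth`` is a DataFrame of planted
    per-trial N2/P2 amplitudes plus the planted latencies in ``truth.attrs``.
    """
    from .erp import EpochSet

    n2 = dict(latency=230.0, amplitude=10.0, width=30.0) | (n2 or {})
    p2 = dict(latency=380.0, amplitude=12.0, width=50.0) | (p2 or {})
    rng = np.random.default_rng(seed)
    times = np.arange(t_range[0], t_range[1] + 0.5 / fs * 1e3, 1e3 / fs)
    times = times[times <= t_range[1] + 1e-9]
    a_n2 = n2["amplitude"] * np.maximum(
        1.0 + amplitude_jitter * rng.standard_normal(n_trials), 0.0)
    a_p2 = p2["amplitude"] * np.maximum(
        1.0 + amplitude_jitter * rng.standard_normal(n_trials), 0.0)
    bump_n2 = np.exp(-0.5 * ((times - n2["latency"]) / n2["width"]) ** 2)
    bump_p2 = np.exp(-0.5 * ((times - p2["latency"]) / p2["width"]) ** 2)
    signal = (-a_n2[:, None] * bump_n2[None, :]
              + a_p2[:, None] * bump_p2[None, :])
    data = np.repeat(signal[:, None, :], len(channels), axis=1)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    epochs = EpochSet(data=data, fs=fs, t0=times[0], channels=list(channels))
    truth = pd.DataFrame({"n2_amplitude": -a_n2, "p2_amplitude": a_p2})
    truth.attrs["n2_latency"] = n2["latency"]
    truth.attrs["p2_latency"] = p2["latency"]
    return epochs, truth
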