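"""Cue-specific leaky-integration model of trial-wise pain expectations.

The model summarises how strongly a participant expects pain on each trial
(expectation *strength*) and how certain that prediction is (expectation
*precision*), given the history of pain ratings experienced after the same
predictive cue.  Strength is a recency-weighted mean of past same-cue ratings
with exponentially decaying weights ``w_k = exp(-k / omega)``; precision is a
monotone-decreasing function of the recency-weighted variance of past strength
estimates.  Both quantities are min-max normalised to [0, 1] before entering
statistical models.

Only same-cue history contributes: trials under the other cue never alter a
cue's expectation series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "decay_weights",
    "expectation_strength",
    "expectation_precision",
    "LeakyExpectation",
    "compute_expectations",
]

#: maximal possible variance of values confined to the 0-100 rating scale
NOMINAL_MAX_VAR = 2500.0


def decay_weights(k_max: int, omega: float) -> np.ndarray:
    """Exponential recency weights ``w_k = exp(-k/omega)`` for k = 1..k_max.

    ``k = 1`` is the most recent same-cue trial.  Weights are strictly
    positive and strictly decreasing in ``k``.
    """
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    if not omega > 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    k = np.arange(1, k_max + 1, dtype=float)
    return np.exp(-k / omega)


def expectation_strength(past_ratings: "np.ndarray | list[float]",
                         omega: float) -> float:
    """Recency-weighted mean of past same-cue ratings.

    ``past_ratings`` is ordered most-recent first (index 0 has weight
    ``exp(-1/omega)``).  Returns NaN for an empty history (undefined
    expectation rather than an exception).
    """
    p = np.asarray(past_ratings, dtype=float)
    if p.size == 0:
        return math.nan
    w = decay_weights(p.size, omega)
    return float(np.sum(w * p) / np.sum(w))


def expectation_precision(past_strengths: "np.ndarray | list[float]",
                          omega: float,
                          variance_exponent: float = 0.25,
                          precision_mode: str = "reciprocal",
                          epsilon: float = 1e-6) -> tuple[float, float]:
    """Weighted variance of past strength estimates and raw precision.

    ``past_strengths`` is ordered most-recent first.  The variance is the
    recency-weighted mean squared deviation around the recency-weighted mean
    of the past strengths.  The raw precision is derived from the transformed
    variance ``v* = Var**variance_exponent``:

    - ``reciprocal`` mode: ``1 / (v* + epsilon)`` (literal inverse);
    - ``negated`` mode: ``-v*`` (monotone-equivalent after min-max scaling).

    Returns ``(nan, nan)`` for an empty history.
    """
    e = np.asarray(past_strengths, dtype=float)
    if e.size == 0:
        return math.nan, math.nan
    w = decay_weights(e.size, omega)
    wsum = np.sum(w)
    mean = np.sum(w * e) / wsum
    var = float(np.sum(w * (e - mean) ** 2) / wsum)
    return var, _precision_from_var(var, variance_exponent, precision_mode,
                                    epsilon)


def _precision_from_var(var: float, variance_exponent: float,
                        precision_mode: str, epsilon: float) -> float:
    vstar = max(var, 0.0) ** variance_exponent
    if precision_mode == "reciprocal":
        return 1.0 / (vstar + epsilon)
    if precision_mode == "negated":
        return -vstar
    raise ValueError(f"unknown precision_mode {precision_mode!r}")


@dataclass
class _CueState:
    """O(1) running sums for one cue's leaky recursion.

    After each same-cue trial with rating P the strength sums update as
    ``N <- d*(P + N)``, ``D <- d*(1 + D)`` with ``d = exp(-1/omega)``, which
    reproduces the full weighted sums exactly.  The same recursion over the
    realised strength values feeds the weighted-variance computation.
    """
    d: float
    num: float = 0.0        # sum w_k * P_{t-k}
    den: float = 0.0        # sum w_k
    s1: float = 0.0         # sum w_k * E_{t-k}
    s2: float = 0.0         # sum w_k * E_{t-k}^2
    sden: float = 0.0       # sum w_k over defined past strengths

    def strength(self) -> float:
        return self.num / self.den if self.den > 0 else math.nan

    def variance(self) -> float:
        if self.sden <= 0:
            return math.nan
        m = self.s1 / self.sden
        return max(self.s2 / self.sden - m * m, 0.0)

    def update(self, rating: float, strength: float) -> None:
        if not math.isnan(strength):
            self.s1 = self.d * (strength + self.s1)
            self.s2 = self.d * (strength * strength + self.s2)
            self.sden = self.d * (1.0 + self.sden)
        self.num = self.d * (rating + self.num)
        self.den = self.d * (1.0 + self.den)


def _raw_series(ratings: np.ndarray, cues: np.ndarray,
                omega: float) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass over one participant's trials.

    Returns per-trial raw strength E_t and raw weighted variance Var_t
    (NaN where undefined: E_t on the first same-cue trial, Var_t until a
    past strength exists).
    """
    d = math.exp(-1.0 / omega)
    states: dict[object, _CueState] = {}
    n = ratings.size
    strength = np.full(n, np.nan)
    var = np.full(n, np.nan)
    for t in range(n):
        st = states.get(cues[t])
        if st is None:
            st = states[cues[t]] = _CueState(d)
        e_t = st.strength()
        strength[t] = e_t
        var[t] = st.variance()
        st.update(float(ratings[t]), e_t)
    return strength, var


class LeakyExpectation(BaseEstimator, TransformerMixin):
    """Transformer appending leaky-integrator expectation columns to a trial table.

    Parameters
    ----------
    omega : float, default 8.0
        Memory decay constant in trials; larger values weight older trials
        more heavily.
    variance_exponent : float, default 0.25
        Power transform applied to the weighted variance before inversion,
        reducing the right skew of the raw variance distribution.
    precision_mode : {"reciprocal", "negated"}, default "reciprocal"
        How raw precision is derived from the transformed variance.
    epsilon_scale : float, default 1e-6
        In reciprocal mode the guard constant is ``epsilon_scale`` times the
        scale (maximum) of the transformed variance in the fitted data,
        protecting the zero-variance trials early in each cue sequence.
    normalization : {"pooled", "per_participant"}, default "pooled"
        Scope of the min-max scaling of strength and precision: across all
        participants and trials of the fitted dataset, or within participant.
    update_source : {"rating", "intensity"}, default "rating"
        Which column drives the update: experienced pain ratings (the primary
        model) or the delivered intensity codes (sensitivity analysis).
    rating_col, cue_col, participant_col : str
        Column names in the trial table.

    Appended columns: ``E_strength_raw``, ``E_var``, ``E_precision_raw``,
    ``E_strength``, ``E_precision`` (normalised) and ``E_defined`` (False on
    the first same-cue trial, whose strength is undefined; precision is NaN
    until at least one past strength exists, i.e., through the second
    same-cue trial).
    """

    def __init__(self, omega: float = 8.0, variance_exponent: float = 0.25,
                 precision_mode: str = "reciprocal",
                 epsilon_scale: float = 1e-6,
                 normalization: str = "pooled",
                 update_source: str = "rating",
                 rating_col: str = "rating", cue_col: str = "cue",
                 participant_col: str = "participant"):
        self.omega = omega
        self.variance_exponent = variance_exponent
        self.precision_mode = precision_mode
        self.epsilon_scale = epsilon_scale
        self.normalization = normalization
        self.update_source = update_source
        self.rating_col = rating_col
        self.cue_col = cue_col
        self.participant_col = participant_col

    # -- internals ---------------------------------------------------------
    def _validate(self, table: pd.DataFrame) -> None:
        if not self.omega > 0:
            raise ValueError("omega must be > 0")
        if not 0 < self.variance_exponent <= 1:
            raise ValueError("variance_exponent must be in (0, 1]")
        if self.normalization not in ("pooled", "per_participant"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.update_source not in ("rating", "intensity"):
            raise ValueError(f"unknown update_source {self.update_source!r}")
        for c in (self.rating_col if self.update_source == "rating"
                  else "intensity", self.cue_col, self.participant_col):
            if c not in table.columns:
                raise KeyError(f"trial table lacks column {c!r}")
        if {"run", "trial"} <= set(table.columns):
            key = table[[self.participant_col, "run", "trial"]]
            if key.duplicated().any():
                raise ValueError("duplicated (participant, run, trial) rows")
            srt = key.sort_values([self.participant_col, "run", "trial"])
            if not (srt.index == key.index).all():
                raise ValueError("table must be sorted by participant, run, "
                                 "trial")

    def _compute_raw(self, table: pd.DataFrame) -> pd.DataFrame:
        src = (self.rating_col if self.update_source == "rating"
               else "intensity")
        strength = np.full(len(table), np.nan)
        var = np.full(len(table), np.nan)
        for _, idx in table.groupby(self.participant_col,
                                    sort=False).indices.items():
            s, v = _raw_series(table[src].to_numpy(dtype=float)[idx],
                               table[self.cue_col].to_numpy()[idx],
                               self.omega)
            strength[idx] = s
            var[idx] = v
        out = table.copy()
        out["E_strength_raw"] = strength
        out["E_var"] = var
        vstar = np.where(np.isnan(var), np.nan,
                         np.maximum(var, 0.0) ** self.variance_exponent)
        scale = np.nanmax(vstar) if np.isfinite(np.nanmax(vstar)) else 1.0
        eps = self.epsilon_scale * (scale if scale > 0 else 1.0)
        if self.precision_mode == "reciprocal":
            prec = 1.0 / (vstar + eps)
        elif self.precision_mode == "negated":
            prec = -vstar
        else:
            raise ValueError(f"unknown precision_mode {self.precision_mode!r}")
        out["E_precision_raw"] = prec
        out["E_defined"] = ~np.isnan(strength)
        return out

    @staticmethod
    def _minmax_bounds(values: pd.Series,
                       groups: pd.Series | None) -> pd.DataFrame | tuple:
        if groups is None:
            return float(values.min()), float(values.max())
        agg = values.groupby(groups).agg(["min", "max"])
        return agg

    # -- sklearn API -------------------------------------------------------
    def fit(self, table: pd.DataFrame, y=None) -> "LeakyExpectation":
        """Learn the min-max normalisation bounds from ``table``."""
        self._validate(table)
        raw = self._compute_raw(table)
        if self.normalization == "pooled":
            self.strength_bounds_ = self._minmax_bounds(
                raw["E_strength_raw"], None)
            self.precision_bounds_ = self._minmax_bounds(
                raw["E_precision_raw"], None)
        else:
            g = raw[self.participant_col]
            self.strength_bounds_ = self._minmax_bounds(raw["E_strength_raw"], g)
            self.precision_bounds_ = self._minmax_bounds(raw["E_precision_raw"], g)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Return ``table`` with raw and normalised expectation columns."""
        if not hasattr(self, "strength_bounds_"):
            raise RuntimeError("LeakyExpectation is not fitted")
        self._validate(table)
        out = self._compute_raw(table)

        def norm(values, bounds, groups=None):
            if isinstance(bounds, tuple):
                lo, hi = bounds
                rng = hi - lo
                return (values - lo) / rng if rng > 0 else values * 0.0
            lo = groups.map(bounds["min"])
            hi = groups.map(bounds["max"])
            rng = hi - lo
            z = (values - lo) / rng.where(rng > 0)
            return z.fillna(0.0).where(~values.isna())

        g = (out[self.participant_col]
             if self.normalization == "per_participant" else None)
        out["E_strength"] = norm(out["E_strength_raw"], self.strength_bounds_, g)
        out["E_precision"] = norm(out["E_precision_raw"], self.precision_bounds_, g)
        return out


def compute_expectations(table: pd.DataFrame, omega: float = 8.0,
                         **kwargs) -> pd.DataFrame:
    """Fit-and-transform convenience wrapper around :class:`LeakyExpectation`."""
    return LeakyExpectation(omega=omega, **kwargs).fit_transform(table)
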