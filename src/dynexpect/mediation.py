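"""Trial-level multilevel mediation (X -> M -> Y within participants).

Per participant, ordinary least squares gives the path coefficients
``a_i`` (M ~ X), ``b_i`` and ``c'_i`` (Y ~ M + X) and ``c_i`` (Y ~ X);
the population indirect effect is ``mean(a_i * b_i)``, which equals
``mean(a) * mean(b) + cov_n(a, b)`` and therefore carries the
across-participant covariance correction of 1-1-1 mediation.  Per
participant, OLS guarantees ``c_i = c'_i + a_i b_i`` exactly, so the total
effect decomposes additively at the population level as well.

Inference resamples participants with replacement: percentile bootstrap
confidence intervals and two-tailed p-values as the doubled proportion of
bootstrap estimates crossing zero.  Batteries of (predictor, mediator)
pairs are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .mapping import bh_fdr

__all__ = ["MediationResult", "MultilevelMediation", "multilevel_mediate",
           "mediate_battery"]


class MediationRankError(ValueError):
    """Too few participants with a full-rank within-participant design."""


@dataclass
class MediationResult:
    """Population path estimates and bootstrap inference for one X-M-Y triple."""
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    p: float
    n_participants: int
    n_boot: int
    seed: int | None
    predictor: str | None = None
    mediator: str | None = None
    p_fdr: float | None = None
    paths_by_participant: pd.DataFrame | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in
                ("predictor", "mediator", "a", "b", "c", "c_prime",
                 "indirect", "ci_low", "ci_high", "p", "p_fdr",
                 "n_participants")}


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Least squares; None when the design is rank deficient."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return None
    return coef


class MultilevelMediation(BaseEstimator):
    """Participant-level mediation estimator with bootstrap inference.

    Parameters
    ----------
    n_boot : int, default 10000
        Bootstrap resamples of participants.
    seed : int or None
        RNG seed; fixed seeds make the bootstrap byte-reproducible.
    standardize : bool, default False
        z-score X, M, Y within participant before path estimation.
    min_trials : int, default 20
        Minimal trials per participant.
    min_participants : int, default 10
    """

    def __init__(self, n_boot: int = 10_000, seed: int | None = None,
                 standardize: bool = False, min_trials: int = 20,
                 min_participants: int = 10):
        self.n_boot = n_boot
        self.seed = seed
        self.standardize = standardize
        self.min_trials = min_trials
        self.min_participants = min_participants

    def fit(self, X, M, Y, groups, covariates=None) -> "MultilevelMediation":
        df = pd.DataFrame({"x": np.asarray(X, dtype=float),
                           "m": np.asarray(M, dtype=float),
                           "y": np.asarray(Y, dtype=float),
                           "g": np.asarray(groups)})
        ncov = 0
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] != len(df):
                cov = cov.T
            ncov = cov.shape[1]
            for j in range(ncov):
                df[f"cov{j}"] = cov[:, j]
        df = df.dropna()
        if df["g"].nunique() < self.min_participants:
            raise MediationRankError(
                f"need >= {self.min_participants} participants")
        paths = []
        for pid, sub in df.groupby("g", sort=True):
            if len(sub) < self.min_trials:
                warnings.warn(f"participant {pid}: fewer than "
                              f"{self.min_trials} trials; excluded",
                              stacklevel=2)
                continue
            x, m, y = (sub[c].to_numpy() for c in ("x", "m", "y"))
            if self.standardize:
                x, m, y = (_z(v) for v in (x, m, y))
            ones = np.ones_like(x)
            covs = [sub[f"cov{j}"].to_numpy() for j in range(ncov)]
            a_fit = _ols(np.column_stack([ones, x, *covs]), m)
            bc_fit = _ols(np.column_stack([ones, m, x, *covs]), y)
            c_fit = _ols(np.column_stack([ones, x, *covs]), y)
            if a_fit is None or bc_fit is None or c_fit is None:
                warnings.warn(f"participant {pid}: rank-deficient design; "
                              "excluded", stacklevel=2)
                continue
            paths.append({"participant": pid, "a": a_fit[1], "b": bc_fit[1],
                          "c_prime": bc_fit[2], "c": c_fit[1]})
        if len(paths) < self.min_participants:
            raise MediationRankError(
                f"only {len(paths)} usable participants "
                f"(< {self.min_participants})")
        pdf = pd.DataFrame(paths).set_index("participant")
        ab = (pdf["a"] * pdf["b"]).to_numpy()
        rng = np.random.default_rng(self.seed)
        npart = len(pdf)
        idx = rng.integers(0, npart, size=(self.n_boot, npart))
        boot = ab[idx].mean(axis=1)
        ci_low, ci_high = np.quantile(boot, [0.025, 0.975])
        p = 2.0 * min(float(np.mean(boot <= 0.0)),
                      float(np.mean(boot >= 0.0)))
        p = min(max(p, 1.0 / self.n_boot), 1.0)
        self.boot_ = boot
        self.result_ = MediationResult(
            a=float(pdf["a"].mean()), b=float(pdf["b"].mean()),
            c=float(pdf["c"].mean()), c_prime=float(pdf["c_prime"].mean()),
            indirect=float(ab.mean()), ci_low=float(ci_low),
            ci_high=float(ci_high), p=p, n_participants=npart,
            n_boot=self.n_boot, seed=self.seed, paths_by_participant=pdf)
        return self


def _z(v: np.ndarray) -> np.ndarray:
    s = v.std()
    return (v - v.mean()) / s if s > 0 else v - v.mean()


def multilevel_mediate(X, M, Y, groups, covariates=None,
                       n_boot: int = 10_000,
                       seed: int | None = None, **kwargs) -> MediationResult:
    """Functional wrapper around :class:`MultilevelMediation`."""
    est = MultilevelMediation(n_boot=n_boot, seed=seed, **kwargs)
    return est.fit(X, M, Y, groups, covariates=covariates).result_


def mediate_battery(table: pd.DataFrame, predictors: list[str],
                    mediators: list[str], outcome: str,
                    group_col: str = "participant", q: float = 0.05,
                    n_boot: int = 10_000, seed: int | None = None,
                    **kwargs) -> pd.DataFrame:
    """Run mediation for every (predictor, mediator) pair; BH-FDR the p-values.

    Returns one row per pair with paths, bootstrap CI, p and p_fdr.
    """
    results = []
    rng = np.random.default_rng(seed)
    for x_col in predictors:
        for m_col in mediators:
            res = multilevel_mediate(
                table[x_col], table[m_col], table[outcome], table[group_col],
                n_boot=n_boot, seed=int(rng.integers(2**31)), **kwargs)
            res.predictor = x_col
            res.mediator = m_col
            results.append(res)
    p_adj, _ = bh_fdr([r.p for r in results], q)
    for r, pa in zip(results, p_adj):
        r.p_fdr = float(pa)
    return pd.DataFrame([r.to_row() for r in results])
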