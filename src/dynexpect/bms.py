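"""Bayesian model selection across participants.

Fixed-effects comparison simply sums per-participant log evidences and
reports pairwise log Bayes factors.  Random-effects comparison treats the
model identity as a random effect in the population: a Dirichlet prior over
model frequencies is updated by variational Bayes (participant-wise model
assignment responsibilities and Dirichlet counts iterated to convergence),
and exceedance probabilities - the posterior probability that each model is
the most frequent one - are obtained by Monte Carlo draws from the Dirichlet
posterior.

A BIC-based log-evidence proxy (from :mod:`dynexpect.learning`) feeds these
routines; likewise the dynamic-versus-static comparison of mixed models uses
``exp(dBIC/2)`` as a Bayes-factor proxy, so only directions and orders of
magnitude are meaningful, not absolute Bayes factors under other priors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp
from sklearn.base import BaseEstimator

__all__ = ["fixed_effects_compare", "RandomEffectsBMS", "random_effects_bms",
           "lmm_bf_dynamic_vs_static"]


def _as_matrix(log_evidence) -> tuple[np.ndarray, list]:
    if isinstance(log_evidence, pd.DataFrame):
        return log_evidence.to_numpy(dtype=float), list(log_evidence.columns)
    arr = np.asarray(log_evidence, dtype=float)
    return arr, [f"model_{j}" for j in range(arr.shape[1])]


def fixed_effects_compare(log_evidence) -> dict:
    """Summed log evidence per model and pairwise log Bayes factors.

    ``log_evidence`` is a participants x models array or DataFrame.  The
    (i, j) entry of ``log_bf`` is the summed log evidence of model i minus
    that of model j.
    """
    lme, names = _as_matrix(log_evidence)
    total = lme.sum(axis=0)
    return {"models": names,
            "summed_log_evidence": dict(zip(names, total.tolist())),
            "log_bf": pd.DataFrame(total[:, None] - total[None, :],
                                   index=names, columns=names)}


class RandomEffectsBMS(BaseEstimator):
    """Random-effects Bayesian model selection (Dirichlet-multinomial VB).

    Parameters
    ----------
    alpha0 : float, default 1.0
        Symmetric Dirichlet prior count per model.
    max_iter, tol : VB stopping rule (change in alpha below ``tol``).
    n_mc : Monte Carlo draws for exceedance probabilities.
    seed : RNG seed for the Monte Carlo step.

    Fitted attributes: ``alpha_`` (Dirichlet counts), ``expected_freq_``,
    ``exceedance_`` (each summing to one), ``responsibilities_``
    (participants x models), ``n_iter_``, ``converged_``.
    """

    def __init__(self, alpha0: float = 1.0, max_iter: int = 500,
                 tol: float = 1e-6, n_mc: int = 1_000_000,
                 seed: int = 20260302):
        self.alpha0 = alpha0
        self.max_iter = max_iter
        self.tol = tol
        self.n_mc = n_mc
        self.seed = seed

    def fit(self, log_evidence, y=None) -> "RandomEffectsBMS":
        lme, names = _as_matrix(log_evidence)
        if lme.ndim != 2 or lme.shape[1] < 1:
            raise ValueError("log_evidence must be participants x models")
        if not np.all(np.isfinite(lme)):
            raise ValueError("log evidences must be finite")
        n, k = lme.shape
        self.model_names_ = names
        if k == 1:
            self.alpha_ = np.array([self.alpha0 + n])
            self.expected_freq_ = np.array([1.0])
            self.exceedance_ = np.array([1.0])
            self.responsibilities_ = np.ones((n, 1))
            self.n_iter_, self.converged_ = 0, True
            return self
        alpha = np.full(k, self.alpha0, dtype=float)
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            logu = lme + (digamma(alpha) - digamma(alpha.sum()))[None, :]
            u = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
            alpha_new = self.alpha0 + u.sum(axis=0)
            if np.max(np.abs(alpha_new - alpha)) < self.tol:
                alpha = alpha_new
                self.converged_ = True
                break
            alpha = alpha_new
        self.n_iter_ = it
        self.alpha_ = alpha
        self.responsibilities_ = u
        self.expected_freq_ = alpha / alpha.sum()
        rng = np.random.default_rng(self.seed)
        draws = rng.dirichlet(alpha, size=self.n_mc)
        win = np.argmax(draws, axis=1)
        self.exceedance_ = np.bincount(win, minlength=k) / self.n_mc
        return self

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"model": self.model_names_,
                             "dirichlet_alpha": self.alpha_,
                             "expected_frequency": self.expected_freq_,
                             "exceedance_probability": self.exceedance_})


def random_effects_bms(log_evidence, **kwargs) -> RandomEffectsBMS:
    """Functional wrapper: fit :class:`RandomEffectsBMS` on a log-evidence matrix."""
    return RandomEffectsBMS(**kwargs).fit(log_evidence)


def lmm_bf_dynamic_vs_static(table: pd.DataFrame,
                             outcome: str = "subjective_expectation",
                             strength_col: str = "E_strength",
                             cue_col: str = "cue",
                             participant_col: str = "participant") -> dict:
    """BIC-based Bayes-factor proxy: dynamic strength vs static cue label.

    Fits two random-intercept mixed models of ``outcome`` - one on the
    continuous model-derived strength, one on the dichotomous cue identity -
    and returns ``exp((BIC_static - BIC_dynamic)/2)`` as the evidence ratio
    in favour of the dynamic model.
    """
    from .mixedlm import _ml_random_intercept

    sub = table.dropna(subset=[outcome, strength_col, cue_col])
    y = sub[outcome].to_numpy(dtype=float)
    groups = sub[participant_col].to_numpy()
    bics = {}
    for name, col in (("dynamic", strength_col), ("static", cue_col)):
        x = sub[col]
        if not np.issubdtype(np.asarray(x).dtype, np.number):
            x = pd.Categorical(x).codes.astype(float)
        X = np.column_stack([np.ones(len(sub)), np.asarray(x, dtype=float)])
        fit = _ml_random_intercept(X, y, groups)
        k = X.shape[1] + 2                      # betas + two variance comps
        bics[name] = -2.0 * fit["loglik"] + k * np.log(len(sub))
    log_bf = (bics["static"] - bics["dynamic"]) / 2.0
    return {"bf_dynamic_over_static": float(np.exp(log_bf)),
            "log_bf": float(log_bf), "bic": bics}
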