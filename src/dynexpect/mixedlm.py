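"""Random-intercept Gaussian mixed models with HPD / posterior-probability inference.

The inferential workhorse of the package.  Outcomes (ratings or trial-wise
neural features) are modelled as

    y_ij = x_ij' beta + u_j + e_ij,   u_j ~ N(0, tau^2),  e_ij ~ N(0, sigma^2)

with participant random intercepts.  Two inference routes are provided:

- ``gibbs`` (primary): a blocked Gibbs sampler with a flat prior on the
  fixed effects and half-Cauchy(0, 2.5 * sd(y)) priors on both standard
  deviations (via the Huang-Wand inverse-gamma mixture, which keeps every
  conditional conjugate).  Fixed effects are summarised by the posterior
  mean (Est), a 95% highest-posterior-density interval and Pp, the
  posterior mass on the sign of Est; the decision rule used downstream is
  "HPD excludes 0 and Pp > 97.5%".
- ``ml_bootstrap``: profiled maximum likelihood plus a parametric bootstrap,
  yielding an HPD-analogue percentile interval.

The module also houses the between-participant correlation validation of
model-derived expectation strength and the repeated-measures ANOVA power
computation used for sample-size planning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = ["BayesianMixedLM", "MixedModelResult", "fit_mixed", "hpd_interval",
           "validate_correlation", "rmanova_power", "rmanova_power_n"]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _design(table: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list]:
    """Intercept + named columns; 'a:b' builds a product term."""
    cols = [np.ones(len(table))]
    names = ["Intercept"]
    for t in terms:
        if ":" in t:
            a, b = t.split(":", 1)
            cols.append(table[a].to_numpy(dtype=float)
                        * table[b].to_numpy(dtype=float))
        else:
            cols.append(table[t].to_numpy(dtype=float))
        names.append(t)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def _group_stats(X, y, groups):
    codes, _ = pd.factorize(groups)
    g = codes.max() + 1
    n_g = np.bincount(codes).astype(float)
    Sx = np.zeros((g, X.shape[1]))
    Sy = np.zeros(g)
    np.add.at(Sx, codes, X)
    np.add.at(Sy, codes, y)
    return codes, n_g, Sx, Sy


# ---------------------------------------------------------------------------
# profiled maximum likelihood
# ---------------------------------------------------------------------------

def _ml_random_intercept(X: np.ndarray, y: np.ndarray,
                         groups: np.ndarray) -> dict:
    """ML fit of the random-intercept model by profiling the variance ratio.

    For a fixed ratio lambda = tau^2/sigma^2, each group's inverse
    covariance is ``(I - c_g J)/sigma^2`` with ``c_g = lambda/(1+n_g
    lambda)``, so the GLS normal equations reduce to grouped sufficient
    statistics; sigma^2 then has a closed form and only the scalar
    log-ratio is optimised numerically.
    """
    n, p = X.shape
    codes, n_g, Sx, Sy = _group_stats(X, y, groups)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def profile(log_lam):
        lam = math.exp(log_lam)
        c = lam / (1.0 + n_g * lam)
        A = XtX - (Sx * c[:, None]).T @ Sx
        b = Xty - Sx.T @ (c * Sy)
        beta = np.linalg.solve(A, b)
        # weighted RSS = y'V^-1 y - beta' X'V^-1 y  (V in sigma^2 units)
        r = (yty - np.sum(c * Sy**2)) - beta @ b
        s2 = max(r / n, 1e-300)
        ll = -0.5 * (n * math.log(2 * math.pi * s2)
                     + np.sum(np.log1p(n_g * lam)) + n)
        return -ll, beta, s2, A

    res = optimize.minimize_scalar(lambda t: profile(t)[0],
                                   bounds=(-14.0, 14.0), method="bounded",
                                   options={"xatol": 1e-8})
    nll, beta, s2, A = profile(res.x)
    lam = math.exp(res.x)
    cov = np.linalg.inv(A) * s2
    se = np.sqrt(np.diag(cov))
    return {"beta": beta, "se": se, "sigma2": s2, "tau2": lam * s2,
            "loglik": -nll, "lambda": lam, "cov": cov, "n": n,
            "n_groups": n_g.size}


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def hpd_interval(draws: np.ndarray, prob: float = 0.95,
                 method: str = "narrowest") -> tuple[float, float]:
    """HPD interval of a univariate sample.

    ``narrowest`` scans all contiguous windows containing ``prob`` of the
    sorted draws; ``equal`` returns the equal-tailed interval.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    m = x.size
    if method == "equal":
        lo = (1.0 - prob) / 2.0
        return float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo))
    k = max(int(math.ceil(prob * m)), 2)
    widths = x[k - 1:] - x[: m - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def _rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (chains x draws)."""
    c, m = chains.shape
    half = m // 2
    seq = chains[:, : 2 * half].reshape(2 * c, half)
    w = seq.var(axis=1, ddof=1).mean()
    b = half * seq.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    return float(math.sqrt((half - 1) / half + b / (w * half)))


@dataclass
class MixedModelResult:
    """Fixed-effect summaries plus variance components of one fitted LMM."""
    effects: pd.DataFrame                    # Est, hpd_low, hpd_high, Pp, rhat
    sigma_participant: float
    sigma_residual: float
    n_obs: int
    n_groups: int
    method: str
    diagnostics: dict = field(default_factory=dict)

    def compelling(self, pp_threshold: float = 0.975) -> pd.Series:
        """Decision rule: 95% HPD excludes 0 and Pp exceeds the threshold."""
        e = self.effects
        return ((e["hpd_low"] * e["hpd_high"] > 0)
                & (e["Pp"] > pp_threshold))


class BayesianMixedLM(BaseEstimator):
    """Random-intercept LMM estimator with Gibbs or ML-bootstrap inference.

    Parameters
    ----------
    outcome : str
        Name of the outcome column.
    terms : list of str
        Fixed-effect columns; ``"a:b"`` denotes a product (interaction)
        term.  An intercept is always included.
    group : str, default "participant"
        Grouping column for the random intercept.
    method : {"gibbs", "ml_bootstrap"}
    n_draws : int, default 1000
        Post-warmup draws per chain (Gibbs) or bootstrap replicates.
    n_chains : int, default 4
    warmup : int or None
        Warmup draws per chain; defaults to ``n_draws // 2``.
    hpd_method : {"narrowest", "equal"}
    seed : int RNG seed.
    """

    def __init__(self, outcome: str, terms: list[str],
                 group: str = "participant", method: str = "gibbs",
                 n_draws: int = 1000, n_chains: int = 4,
                 warmup: int | None = None, hpd_method: str = "narrowest",
                 prior_scale: float = 2.5, seed: int = 0):
        self.outcome = outcome
        self.terms = terms
        self.group = group
        self.method = method
        self.n_draws = n_draws
        self.n_chains = n_chains
        self.warmup = warmup
        self.hpd_method = hpd_method
        self.prior_scale = prior_scale
        self.seed = seed

    # -- Gibbs sampler -----------------------------------------------------
    def _gibbs(self, X, y, groups, rng):
        n, p = X.shape
        codes, n_g, Sx, Sy = _group_stats(X, y, groups)
        g = n_g.size
        XtX = X.T @ X
        Xty = X.T @ y
        yty = float(y @ y)
        XtX_inv = np.linalg.inv(XtX)
        chol = np.linalg.cholesky(XtX_inv)
        A2 = (self.prior_scale * float(np.std(y))) ** 2 or 1.0
        warm = self.n_draws // 2 if self.warmup is None else self.warmup

        draws = np.empty((self.n_chains, self.n_draws, p))
        vdraws = np.empty((self.n_chains, self.n_draws, 2))   # tau2, sigma2
        for ch in range(self.n_chains):
            beta = XtX_inv @ Xty
            u = np.zeros(g)
            sigma2 = float(np.var(y)) or 1.0
            tau2 = sigma2 / 2.0
            a_s = a_t = 1.0
            for it in range(warm + self.n_draws):
                # fixed effects | u, sigma2
                b = Xty - Sx.T @ u
                mean = XtX_inv @ b
                beta = mean + math.sqrt(sigma2) * (chol @ rng.standard_normal(p))
                # random intercepts | beta, sigma2, tau2
                resid_sum = Sy - Sx @ beta
                prec = n_g / sigma2 + 1.0 / tau2
                u = resid_sum / sigma2 / prec + rng.standard_normal(g) / np.sqrt(prec)
                # translation sweep: the intercept and the random-intercept
                # mean are only jointly identified; resampling the shared
                # shift keeps the chain mixing (flat prior on the intercept)
                shift = rng.normal(float(u.mean()), math.sqrt(tau2 / g))
                beta[0] += shift
                u -= shift
                resid_sum = Sy - Sx @ beta
                # residual variance (Huang-Wand half-Cauchy mixture)
                ssr = (yty - 2.0 * beta @ Xty + beta @ XtX @ beta
                       - 2.0 * u @ resid_sum + np.sum(n_g * u**2))
                ssr = max(ssr, 1e-12)
                sigma2 = 1.0 / rng.gamma((1.0 + n) / 2.0,
                                         1.0 / (1.0 / a_s + ssr / 2.0))
                a_s = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / A2 + 1.0 / sigma2))
                # intercept variance
                su2 = float(u @ u)
                tau2 = 1.0 / rng.gamma((1.0 + g) / 2.0,
                                       1.0 / (1.0 / a_t + su2 / 2.0))
                a_t = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / A2 + 1.0 / tau2))
                if it >= warm:
                    draws[ch, it - warm] = beta
                    vdraws[ch, it - warm] = (tau2, sigma2)
        return draws, vdraws

    # -- API ---------------------------------------------------------------
    def fit(self, table: pd.DataFrame, y=None) -> "BayesianMixedLM":
        cols = [self.outcome, self.group] + [c for t in self.terms
                                             for c in t.split(":")]
        sub = table.dropna(subset=[c for c in dict.fromkeys(cols)])
        X, names = _design(sub, self.terms)
        yv = sub[self.outcome].to_numpy(dtype=float)
        groups = sub[self.group].to_numpy()
        if pd.unique(groups).size < 2:
            raise ValueError("grouping factor needs >= 2 levels")
        rng = np.random.default_rng(self.seed)

        if self.method == "gibbs":
            draws, vdraws = self._gibbs(X, yv, groups, rng)
            flat = draws.reshape(-1, X.shape[1])
            est = flat.mean(axis=0)
            rows = []
            for j, name in enumerate(names):
                lo, hi = hpd_interval(flat[:, j], 0.95, self.hpd_method)
                sgn = math.copysign(1.0, est[j])
                pp = float(np.mean(np.sign(flat[:, j]) == sgn))
                rows.append({"effect": name, "Est": est[j], "hpd_low": lo,
                             "hpd_high": hi, "Pp": max(pp, 0.5),
                             "rhat": _rhat(draws[:, :, j])})
            eff = pd.DataFrame(rows).set_index("effect")
            bad = eff["rhat"] > 1.05
            if bad.any():
                warnings.warn("sampler may not have mixed (R-hat > 1.05 for "
                              f"{list(eff.index[bad])})", stacklevel=2)
            tau2 = float(np.mean(vdraws[:, :, 0]))
            sigma2 = float(np.mean(vdraws[:, :, 1]))
            self.draws_ = flat
            self.result_ = MixedModelResult(
                effects=eff, sigma_participant=math.sqrt(tau2),
                sigma_residual=math.sqrt(sigma2), n_obs=len(sub),
                n_groups=int(pd.unique(groups).size), method="gibbs",
                diagnostics={"max_rhat": float(eff["rhat"].max())})
        elif self.method == "ml_bootstrap":
            fit0 = _ml_random_intercept(X, yv, groups)
            codes, n_g, _, _ = _group_stats(X, yv, groups)
            boot = np.empty((self.n_draws, X.shape[1]))
            mu0 = X @ fit0["beta"]
            for b in range(self.n_draws):
                u = rng.normal(0.0, math.sqrt(fit0["tau2"]), n_g.size)
                yb = mu0 + u[codes] + rng.normal(
                    0.0, math.sqrt(fit0["sigma2"]), len(yv))
                boot[b] = _ml_random_intercept(X, yb, groups)["beta"]
            rows = []
            for j, name in enumerate(names):
                lo, hi = hpd_interval(boot[:, j], 0.95, self.hpd_method)
                sgn = math.copysign(1.0, fit0["beta"][j])
                pp = float(np.mean(np.sign(boot[:, j]) == sgn))
                rows.append({"effect": name, "Est": fit0["beta"][j],
                             "hpd_low": lo, "hpd_high": hi,
                             "Pp": max(pp, 0.5), "rhat": np.nan})
            self.draws_ = boot
            self.result_ = MixedModelResult(
                effects=pd.DataFrame(rows).set_index("effect"),
                sigma_participant=math.sqrt(fit0["tau2"]),
                sigma_residual=math.sqrt(fit0["sigma2"]), n_obs=len(sub),
                n_groups=int(pd.unique(groups).size), method="ml_bootstrap",
                diagnostics={"loglik": fit0["loglik"]})
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return self


def fit_mixed(table: pd.DataFrame, outcome: str, terms: list[str],
              group: str = "participant", **kwargs) -> MixedModelResult:
    """Fit a random-intercept LMM and return its :class:`MixedModelResult`.

    Rows with NaN in the outcome or any term column (undefined-expectation
    trials) are excluded.
    """
    est = BayesianMixedLM(outcome=outcome, terms=terms, group=group, **kwargs)
    return est.fit(table).result_


# ---------------------------------------------------------------------------
# correlation validation
# ---------------------------------------------------------------------------

def validate_correlation(table: pd.DataFrame, strength_col: str = "E_strength",
                         rating_col: str = "subjective_expectation",
                         cue_col: str = "cue",
                         participant_col: str = "participant") -> pd.DataFrame:
    """Between-participant Pearson correlation of averaged model strength and
    averaged subjective ratings, per cue."""
    rows = []
    for cue, sub in table.dropna(subset=[strength_col, rating_col]).groupby(
            cue_col, sort=True):
        means = sub.groupby(participant_col)[[strength_col, rating_col]].mean()
        r, p = stats.pearsonr(means[strength_col], means[rating_col])
        rows.append({"cue": cue, "r": r, "p": p, "n": len(means)})
    return pd.DataFrame(rows).set_index("cue")


# ---------------------------------------------------------------------------
# repeated-measures power computation
# ---------------------------------------------------------------------------

def rmanova_power(n: int, f: float, alpha: float, m_conditions: int,
                  rho: float = 0.5, nonsphericity_eps: float = 1.0) -> float:
    """Power of the within-factors repeated-measures F test.

    Noncentrality ``lambda = f^2 n m eps / (1 - rho)``, numerator df
    ``(m-1) eps``, denominator df ``(n-1)(m-1) eps``; power is the survival
    probability of the noncentral F at the central-F critical value.
    """
    lam = f * f * n * m_conditions * nonsphericity_eps / (1.0 - rho)
    df1 = (m_conditions - 1) * nonsphericity_eps
    df2 = (n - 1) * (m_conditions - 1) * nonsphericity_eps
    if df2 < 1:
        return 0.0
    fcrit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def rmanova_power_n(f: float, alpha: float, target_power: float,
                    m_conditions: int, rho: float = 0.5,
                    nonsphericity_eps: float = 1.0,
                    n_max: int = 1_000_000) -> int:
    """Smallest sample size whose repeated-measures F power reaches target.

    Linear scan from the smallest n with positive denominator df; power is
    monotone nondecreasing in n so the first hit is the answer.
    """
    if not f > 0:
        raise ValueError("f must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    n = 2
    while rmanova_power(n, f, alpha, m_conditions, rho,
                        nonsphericity_eps) == 0.0:
        n += 1
    lo = n
    # exponential bracket, then linear confirmation downwards
    while rmanova_power(n, f, alpha, m_conditions, rho,
                        nonsphericity_eps) < target_power:
        n *= 2
        if n > n_max:
            raise ValueError(f"target power unattainable within n <= {n_max}")
    while n > lo and rmanova_power(n - 1, f, alpha, m_conditions, rho,
                                   nonsphericity_eps) >= target_power:
        n -= 1
    return n
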