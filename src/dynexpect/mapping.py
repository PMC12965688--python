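"""Mass-univariate electrode mapping with FDR and contiguity filtering.

Stage one of the two-stage sensor-space pipeline: the same random-intercept
LMM is fitted independently at every channel, per-effect p-values are
corrected across channels by Benjamini-Hochberg FDR, and significant
channels are kept only when they form spatially coherent clusters (connected
components of at least three channels under the montage adjacency).  The
surviving clusters are then candidates for the Bayesian refit
(:func:`dynexpect.mixedlm.fit_mixed`), which alone carries inferential
weight.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .mixedlm import _design, _ml_random_intercept
from .montage import montage_adjacency

__all__ = ["bh_fdr", "mass_univariate_map", "cluster_channels"]


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR.

    Returns ``(p_adjusted, reject)``; adjusted p-values use the standard
    cumulative-minimum formula, rejections the step-up rule at level ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def cluster_channels(significant: dict[str, bool],
                     adjacency: dict[str, set],
                     min_size: int = 3) -> dict[str, int]:
    """Connected components of significant channels; small ones dropped.

    Returns channel -> cluster id (1-based); channels in no retained cluster
    are absent.
    """
    sig = {c for c, s in significant.items() if s}
    seen: set[str] = set()
    clusters = []
    for c in sorted(sig):
        if c in seen:
            continue
        comp, frontier = {c}, [c]
        while frontier:
            cur = frontier.pop()
            for nb in adjacency.get(cur, ()):
                if nb in sig and nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        seen |= comp
        if len(comp) >= min_size:
            clusters.append(sorted(comp))
    out = {}
    for k, comp in enumerate(sorted(clusters), start=1):
        for c in comp:
            out[c] = k
    return out


def mass_univariate_map(features: pd.DataFrame, design: pd.DataFrame,
                        terms: list[str], group: str = "participant",
                        adjacency: dict[str, set] | None = None,
                        q: float = 0.05, min_cluster: int = 3) -> pd.DataFrame:
    """Channel-by-channel LMM map with BH-FDR and cluster filtering.

    Parameters
    ----------
    features : DataFrame (n_trials x n_channels)
        One column per channel (trial-wise band power or similar), aligned
        row-wise with ``design``.
    design : DataFrame
        Predictor columns named in ``terms`` plus the grouping column.
    terms : list of str
        Fixed-effect terms (``"a:b"`` = interaction); the FDR family is the
        set of channels within one effect.
    adjacency : channel -> neighbour set; defaults to the packaged
        32-channel 10-20 template (channels absent from it raise).
    q : FDR level; min_cluster : minimal retained cluster size.

    Returns a long DataFrame with columns ``channel, effect, t, p, p_fdr,
    significant, cluster``.
    """
    channels = list(features.columns)
    if adjacency is None:
        adjacency = montage_adjacency(channels)
    missing = set(channels) - set(adjacency)
    if missing:
        raise KeyError(f"adjacency lacks channels: {sorted(missing)}")
    covered = set().union(*adjacency.values()) | set(adjacency)
    if not set(channels) <= covered:
        warnings.warn("adjacency leaves some channels isolated", stacklevel=2)

    X, names = _design(design, terms)
    groups = design[group].to_numpy()
    rows = []
    for c in channels:
        y = features[c].to_numpy(dtype=float)
        ok = np.isfinite(y)
        fit = _ml_random_intercept(X[ok], y[ok], groups[ok])
        t = fit["beta"] / fit["se"]
        p = 2.0 * (1.0 - _norm_cdf(np.abs(t)))
        for j, name in enumerate(names):
            if name == "Intercept":
                continue
            rows.append({"channel": c, "effect": name, "t": t[j], "p": p[j]})
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    out["significant"] = False
    out["cluster"] = 0
    for eff, idx in out.groupby("effect").indices.items():
        p_adj, reject = bh_fdr(out.loc[idx, "p"].to_numpy(), q)
        out.loc[idx, "p_fdr"] = p_adj
        sig = dict(zip(out.loc[idx, "channel"], reject))
        labels = cluster_channels(sig, adjacency, min_cluster)
        out.loc[idx, "significant"] = [labels.get(c, 0) > 0
                                       for c in out.loc[idx, "channel"]]
        out.loc[idx, "cluster"] = [labels.get(c, 0)
                                   for c in out.loc[idx, "channel"]]
    return out


def _norm_cdf(x):
    from scipy.special import ndtr
    return ndtr(x)
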