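"""Approximate 2-D layout and neighbourhood structure of a 32-channel 10-20 montage.

Positions are schematic head-flattened coordinates (nose up, unit head
radius) sufficient to define spatial adjacency for cluster-based filtering;
they are not digitised electrode locations.  Channels are neighbours when
their planar distance falls below a template threshold chosen so that
interior electrodes have 4-8 neighbours (a second-order template
neighbourhood).
"""

from __future__ import annotations

import numpy as np

__all__ = ["CHANNELS_32", "channel_positions", "montage_adjacency"]

#: schematic (x, y) positions: x positive to the right, y positive anterior
_POSITIONS = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "AFz": (0.0, 0.85),
    "F7": (-0.81, 0.59), "F3": (-0.42, 0.56), "Fz": (0.0, 0.55),
    "F4": (0.42, 0.56), "F8": (0.81, 0.59),
    "FC5": (-0.64, 0.29), "FC1": (-0.22, 0.28), "FC2": (0.22, 0.28),
    "FC6": (0.64, 0.29),
    "T7": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.64, -0.29), "CP1": (-0.22, -0.28), "CP2": (0.22, -0.28),
    "CP6": (0.64, -0.29),
    "P7": (-0.81, -0.59), "P3": (-0.42, -0.56), "Pz": (0.0, -0.55),
    "P4": (0.42, -0.56), "P8": (0.81, -0.59),
    "PO3": (-0.33, -0.78), "POz": (0.0, -0.8), "PO4": (0.33, -0.78),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
}

CHANNELS_32 = list(_POSITIONS)

_NEIGHBOR_DIST = 0.62


def channel_positions(channels: list[str] | None = None) -> dict:
    """Schematic (x, y) position per channel."""
    channels = channels or CHANNELS_32
    missing = set(channels) - set(_POSITIONS)
    if missing:
        raise KeyError(f"unknown channels: {sorted(missing)}")
    return {c: _POSITIONS[c] for c in channels}


def montage_adjacency(channels: list[str] | None = None,
                      max_dist: float = _NEIGHBOR_DIST) -> dict[str, set]:
    """Symmetric neighbour sets from the schematic layout."""
    pos = channel_positions(channels)
    names = list(pos)
    xy = np.array([pos[c] for c in names])
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    adj = {c: set() for c in names}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i != j and d[i, j] <= max_dist:
                adj[a].add(b)
    return adj
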