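"""Electrode montages and channel adjacency.

The study layout is 62 scalp electrodes on an extended 10-20 grid plus both
ear electrodes (A1, A2), 64 channels total.  Positions come from the bundled
standard 10-05 montage shipped with MNE.  For channel counts other than 64 a
generic quasi-uniform spherical layout is generated so that interpolation and
cluster tests work at any scale.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import ChannelError

SCALP_62 = [
    "Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
]
EAR_CHANNELS = ["A1", "A2"]
STUDY_64 = SCALP_62 + EAR_CHANNELS

_POSITION_CACHE: dict = {}


def standard_positions(ch_names: list[str]) -> np.ndarray:
    """3-D head-frame positions (meters) for standard 10-05 channel names."""
    if not _POSITION_CACHE:
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            montage = mne.channels.make_standard_montage("standard_1005")
        _POSITION_CACHE.update(montage.get_positions()["ch_pos"])
    pos = []
    for name in ch_names:
        if name not in _POSITION_CACHE:
            raise ChannelError(f"channel {name!r} not in the standard 10-05 montage")
        pos.append(_POSITION_CACHE[name])
    return np.asarray(pos, dtype=float)


def fibonacci_sphere(n: int, radius: float = 0.095) -> np.ndarray:
    """Quasi-uniform points on the upper two-thirds of a sphere (scalp-like)."""
    k = np.arange(n)
    golden = (1 + 5**0.5) / 2
    # restrict z to [-1/3, 1] so points resemble a scalp cap
    z = 1 - (k + 0.5) / n * (4 / 3)
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    phi = 2 * np.pi * k / golden
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_layout(n_channels: int) -> tuple[list[str], np.ndarray]:
    """Channel names and positions: the study's 64-channel cap, or a generic one."""
    if n_channels == 64:
        return list(STUDY_64), standard_positions(STUDY_64)
    names = [f"CH{i + 1:02d}" for i in range(n_channels)]
    return names, fibonacci_sphere(n_channels)


def build_adjacency(positions: np.ndarray, factor: float = 0.4) -> np.ndarray:
    """Boolean channel adjacency from electrode distances.

    Positions are projected to the unit sphere; two channels are neighbors
    when their distance is at most ``factor`` times the maximal
    inter-electrode distance.  On a 64-channel 10-20 cap with the default
    factor this yields roughly 6-8 neighbors per channel.
    """
    pos = np.asarray(positions, dtype=float)
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ChannelError("electrode at the origin cannot be projected")
    unit = pos / norms
    d = np.linalg.norm(unit[:, None, :] - unit[None, :, :], axis=-1)
    adj = d <= factor * d.max()
    np.fill_diagonal(adj, False)
    if not _is_connected(adj):
        warnings.warn("montage adjacency graph is disconnected", stacklevel=2)
    return adj


def neighbor_lists(adjacency: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(row) for row in adjacency]


def _is_connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    while stack:
        i = stack.pop()
        if seen[i]:
            continue
        seen[i] = True
        stack.extend(np.flatnonzero(adj[i] & ~seen).tolist())
    return bool(seen.all())
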