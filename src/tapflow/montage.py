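"""Equidistant EEG montages with named functional groups.

The recordings this package emulates use a 64-channel cap with
equidistant electrodes whose exact coordinates are not published, so the
built-in layout places ``n`` quasi-equidistant points on the upper part
of a spherical head (Fibonacci lattice on a cap) and names functional
groups — left/right sensorimotor, occipital, fronto-central and
mid-frontal — by proximity to canonical 10-20 landmarks.

Coordinates are head coordinates in metres: +x right, +y anterior,
+z up; head radius 0.09 m.
"""

from __future__ import annotations

import numpy as np

HEAD_RADIUS_M = 0.09

# canonical unit-sphere anchors for the named groups (x right, y anterior, z up)
_GROUP_ANCHORS = {
    "left_sensorimotor": (-0.55, 0.0, 0.84),
    "right_sensorimotor": (0.55, 0.0, 0.84),
    "occipital": (0.0, -0.90, 0.44),
    "fronto_central": (0.0, 0.45, 0.89),
    "mid_frontal": (0.0, 0.85, 0.53),
}

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def equidistant_positions(n_channels: int = 64) -> np.ndarray:
    """Quasi-equidistant electrode positions on the upper head sphere.

    A Fibonacci lattice on the spherical cap z >= -0.05 (slightly below
    the equator, as physical caps extend past the vertex ring).

    Returns an ``(n_channels, 3)`` array in metres.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels for a montage")
    i = np.arange(n_channels)
    # z from just below the equator up to near the vertex
    z = -0.05 + (0.999 - -0.05) * (i + 0.5) / n_channels
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    theta = _GOLDEN_ANGLE * i
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts * HEAD_RADIUS_M


class Montage:
    """Electrode labels, positions and named functional groups."""

    def __init__(self, n_channels: int = 64, group_size: int | None = None):
        self.positions = equidistant_positions(n_channels)
        self.names = [f"ch{i + 1:02d}" for i in range(n_channels)]
        if group_size is None:
            group_size = max(2, n_channels // 16)
        self.groups: dict[str, list[str]] = {}
        unit = self.positions / HEAD_RADIUS_M
        for gname, anchor in _GROUP_ANCHORS.items():
            d = np.linalg.norm(unit - np.asarray(anchor), axis=1)
            idx = np.argsort(d)[:group_size]
            self.groups[gname] = [self.names[j] for j in sorted(idx)]

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def group_indices(self, group: str) -> list[int]:
        return [self.names.index(ch) for ch in self.groups[group]]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def nearest_neighbor_distances(self) -> np.ndarray:
        d = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)
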