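"""Phenomenological electrode layouts.

A deterministic 60-electrode cap on a spherical head, used both by the
synthetic-EEG generator (topography construction) and by the cluster test's
spatial neighbourhood.  The layout is a Fibonacci spiral covering the upper
hemisphere of a 9.2 cm sphere; with the conventional 5 cm neighbourhood
cutoff this yields a mean of ~6.4 neighbours per electrode (median 7,
range 3-8), in line with a standard 60-channel 10-10 montage.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fibonacci_cap_layout", "HEAD_RADIUS_CM"]

HEAD_RADIUS_CM = 9.2
_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_cap_layout(
    n_channels: int = 60,
    radius_cm: float = HEAD_RADIUS_CM,
    max_polar_deg: float = 90.0,
) -> tuple[list[str], np.ndarray]:
    """Deterministic electrode cap on a sphere.

    Electrodes are spread with equal solid-angle density down to
    ``max_polar_deg`` from the vertex (90 deg = down to the equator, roughly
    the extent of a full-head EEG cap).

    Returns
    -------
    ch_names : list of str
        Labels ``E01``..  (generic; the layout is not a named montage).
    ch_pos : ndarray, shape (n_channels, 3)
        Cartesian positions in centimetres; +z is the vertex.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be positive")
    i = np.arange(n_channels)
    cos_max = np.cos(np.deg2rad(max_polar_deg))
    cos_theta = 1.0 - (1.0 - cos_max) * (i + 0.5) / n_channels
    theta = np.arccos(cos_theta)
    phi = i * _GOLDEN_ANGLE
    pos = radius_cm * np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), cos_theta]
    )
    names = [f"E{k + 1:02d}" for k in range(n_channels)]
    return names, pos
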