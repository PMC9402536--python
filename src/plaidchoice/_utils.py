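"""Shared helpers: angle arithmetic, seed derivation, numerics."""

from __future__ import annotations

import zlib

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_degrees(theta):
    """Wrap angle(s) to [0, 360)."""
    return np.asarray(theta, dtype=float) % 360.0


def circular_difference(a, b):
    """Signed smallest difference a - b in degrees, in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def von_mises_shape(theta_deg, preferred_deg, kappa):
    """Unnormalized Von Mises tuning shape exp(kappa*(cos(theta - mu) - 1)).

    Peaks at 1 when theta == preferred; kappa controls bandwidth.
    """
    delta = np.deg2rad(np.asarray(theta_deg, dtype=float) - preferred_deg)
    return np.exp(kappa * (np.cos(delta) - 1.0))


def derive_seed(seed: int, label: str) -> int:
    """Deterministic sub-seed below 2**31 from a master seed and a stage label."""
    return (int(seed) * 1_000_003 + zlib.crc32(label.encode("utf-8"))) % (2**31)


def as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr
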