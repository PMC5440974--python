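"""Shared geometric conventions and sampling helpers.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``, row increasing downward;
* angles are in degrees, 0 deg along the +col axis, positive
  counter-clockwise on screen (i.e. toward decreasing row);
* *directions* live in (-180, 180] (full circle); *orientations* are
  180-degree periodic and live in (-90, 90].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "direction_deg",
    "unit_vector",
    "fold_orientation",
    "fold_direction",
    "angle_between",
    "orientation_difference",
    "sample_shifted",
]


def direction_deg(drow: float, dcol: float) -> float:
    """Angle in degrees of the displacement ``(drow, dcol)`` in (-180, 180]."""
    a = float(np.degrees(np.arctan2(-np.asarray(drow), np.asarray(dcol))))
    if a <= -180.0:
        a += 360.0
    return a


def _snap_half(v: float) -> float:
    """Snap to the nearest multiple of 0.5 within trig rounding error, so
    e.g. cos(60 deg) and sin(30 deg) give the same exact 0.5 component."""
    w = round(v * 2.0) / 2.0
    return w if abs(v - w) < 1e-12 else v


def unit_vector(angle_deg: float) -> tuple[float, float]:
    """Unit displacement ``(drow, dcol)`` for an angle in degrees."""
    rad = np.radians(angle_deg)
    return (_snap_half(-float(np.sin(rad))), _snap_half(float(np.cos(rad))))


def fold_orientation(angle_deg):
    """Fold angles into the orientation range (-90, 90]."""
    a = np.mod(np.asarray(angle_deg, dtype=float) + 90.0, 180.0) - 90.0
    a = np.where(a == -90.0, 90.0, a)
    if np.isscalar(angle_deg):
        return float(a)
    return a


def fold_direction(angle_deg):
    """Fold angles into the direction range (-180, 180]."""
    a = np.mod(np.asarray(angle_deg, dtype=float) + 180.0, 360.0) - 180.0
    a = np.where(a == -180.0, 180.0, a)
    if np.isscalar(angle_deg):
        return float(a)
    return a


def angle_between(a_deg: float, b_deg: float) -> float:
    """Unsigned difference between two directions, folded to [0, 180]."""
    d = abs(float(a_deg) - float(b_deg)) % 360.0
    return 360.0 - d if d > 180.0 else d


def orientation_difference(a_deg: float, b_deg: float) -> float:
    """Unsigned difference between two orientations, folded to [0, 90]."""
    d = abs(float(a_deg) - float(b_deg)) % 180.0
    return 180.0 - d if d > 90.0 else d


def sample_shifted(image: np.ndarray, drow: float, dcol: float,
                   nearest: bool = False) -> np.ndarray:
    """Sample ``image[r + drow, c + dcol]`` for every pixel ``(r, c)``.

    Bilinear interpolation by default (``nearest=True`` rounds the offset
    instead, for quantities such as orientation angles that must not be
    averaged).  Samples whose interpolation support extends outside the
    image are NaN.
    """
    if nearest:
        drow, dcol = round(drow), round(dcol)
    # snap offsets within rounding error of an integer (e.g. r*cos(90 deg))
    # so axis-aligned directions use exact single-pixel samples
    if abs(drow - round(drow)) < 1e-9:
        drow = round(drow)
    if abs(dcol - round(dcol)) < 1e-9:
        dcol = round(dcol)
    h, w = image.shape
    r0 = int(np.floor(drow))
    c0 = int(np.floor(dcol))
    fr = drow - r0
    fc = dcol - c0

    def view(dr: int, dc: int) -> np.ndarray:
        out = np.full((h, w), np.nan)
        rs, re = max(0, dr), min(h, h + dr)
        cs, ce = max(0, dc), min(w, w + dc)
        if rs < re and cs < ce:
            out[rs - dr:re - dr, cs - dc:ce - dc] = image[rs:re, cs:ce]
        return out

    # zero-weight corners are skipped entirely so they cannot poison the
    # interpolation with out-of-bounds NaNs
    if fr == 0.0 and fc == 0.0:
        return view(r0, c0)
    if fr == 0.0:
        return (1 - fc) * view(r0, c0) + fc * view(r0, c0 + 1)
    if fc == 0.0:
        return (1 - fr) * view(r0, c0) + fr * view(r0 + 1, c0)
    return ((1 - fr) * (1 - fc) * view(r0, c0)
            + (1 - fr) * fc * view(r0, c0 + 1)
            + fr * (1 - fc) * view(r0 + 1, c0)
            + fr * fc * view(r0 + 1, c0 + 1))
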