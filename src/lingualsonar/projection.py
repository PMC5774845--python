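"""Eckert IV equal-area pseudocylindrical map projection.

Beam patterns live on the sphere; contour areas and ellipse fits are done
under an equal-area projection so that energy per unit map area is
meaningful at every elevation.  Angles are degrees (azimuth = longitude,
elevation = latitude); the projection uses unit radius, so map units are
radians-scaled.
"""

from __future__ import annotations

import numpy as np

__all__ = ["eckert4_forward", "eckert4_inverse"]

_CX = 2.0 / np.sqrt(4.0 * np.pi + np.pi ** 2)
_CY = 2.0 * np.sqrt(np.pi / (4.0 + np.pi))
_CT = 2.0 + np.pi / 2.0


def _aux_angle(lat_rad: np.ndarray, tol: float = 1e-10,
               max_iter: int = 50) -> np.ndarray:
    """Solve θ + sinθcosθ + 2sinθ = (2 + π/2)·sinφ by Newton iteration."""
    s = _CT * np.sin(lat_rad)
    theta = np.asarray(lat_rad / 2.0, dtype=float).copy()
    for _ in range(max_iter):
        f = theta + np.sin(theta) * np.cos(theta) + 2.0 * np.sin(theta) - s
        fp = 1.0 + np.cos(2.0 * theta) + 2.0 * np.cos(theta)
        step = f / np.where(np.abs(fp) < 1e-12, 1e-12, fp)
        theta = theta - step
        if np.all(np.abs(step) < tol):
            break
    return theta


def eckert4_forward(az_deg, el_deg):
    """Project (azimuth°, elevation°) to Eckert IV map coordinates (x, y)."""
    lam = np.radians(np.asarray(az_deg, dtype=float))
    phi = np.radians(np.asarray(el_deg, dtype=float))
    if np.any(np.abs(phi) > np.pi / 2 + 1e-12):
        raise ValueError("elevation outside [-90, 90]")
    theta = _aux_angle(phi)
    x = _CX * lam * (1.0 + np.cos(theta))
    y = _CY * np.sin(theta)
    return x, y


def eckert4_inverse(x, y):
    """Invert Eckert IV map coordinates back to (azimuth°, elevation°)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sin_t = y / _CY
    if np.any(np.abs(sin_t) > 1.0 + 1e-9):
        raise ValueError("point outside the projection domain")
    theta = np.arcsin(np.clip(sin_t, -1.0, 1.0))
    phi = np.arcsin(np.clip(
        (theta + np.sin(theta) * np.cos(theta) + 2.0 * np.sin(theta)) / _CT,
        -1.0, 1.0))
    lam = x / (_CX * (1.0 + np.cos(theta)))
    return np.degrees(lam), np.degrees(phi)
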