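"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the sphere
scattering series is the textbook partial-wave solution, and the rank-sum
oracle enumerates the null distribution by brute force.
"""

from itertools import combinations

import numpy as np
from numpy.polynomial.legendre import legval
from scipy.special import spherical_jn, spherical_yn


def rigid_sphere_monopole_field(a: float, r0: float, k: float, r_field: float,
                                gamma: np.ndarray, n_max: int = 60
                                ) -> np.ndarray:
    """Total pressure of a unit monopole near a rigid sphere.

    Monopole ``exp(ikd)/(4 pi d)`` at distance ``r0`` from the center of a
    rigid sphere of radius ``a``; evaluated at radius ``r_field > r0`` and
    polar angle ``gamma`` from the source axis.  Partial-wave series:

        p = (ik/4π) Σ (2n+1) [ j_n(kr0) − (j_n'(ka)/h_n'(ka)) h_n(kr0) ]
                               h_n(k r_field) P_n(cos γ)
    """
    x = np.cos(np.asarray(gamma, dtype=float))
    total = np.zeros_like(x, dtype=complex)
    for n in range(n_max + 1):
        jn_r0 = spherical_jn(n, k * r0)
        hn_r0 = jn_r0 + 1j * spherical_yn(n, k * r0)
        jnp_a = spherical_jn(n, k * a, derivative=True)
        hnp_a = jnp_a + 1j * spherical_yn(n, k * a, derivative=True)
        hn_rf = spherical_jn(n, k * r_field) \
            + 1j * spherical_yn(n, k * r_field)
        coef = np.zeros(n + 1)
        coef[n] = 1.0
        total += ((2 * n + 1)
                  * (jn_r0 - (jnp_a / hnp_a) * hn_r0) * hn_rf
                  * legval(x, coef))
    return 1j * k / (4.0 * np.pi) * total


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney U by enumerating all label assignments.

    Assumes no ties across the pooled sample.  Returns (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(subset):
        xs = pooled[list(subset)]
        rest = np.delete(pooled, list(subset))
        return int(sum(np.sum(xs_i > rest) for xs_i in xs))

    u_obs = int(sum(np.sum(xi > y) for xi in x))
    us = [u_of(s) for s in combinations(range(len(pooled)), n1)]
    us = np.asarray(us)
    # two-sided: double the smaller tail probability (capped at 1)
    mean_u = n1 * (len(pooled) - n1) / 2.0
    dev = abs(u_obs - mean_u)
    p = np.mean(np.abs(us - mean_u) >= dev - 1e-12)
    return float(u_obs), float(min(1.0, p))


def gaussian_beam_db(az, el, az0=0.0, el0=0.0, az_width=24.0, el_width=36.0,
                     floor_db=-40.0):
    """Anisotropic Gaussian beam: −3 dB at half the given full widths."""
    az = np.asarray(az, dtype=float)
    el = np.asarray(el, dtype=float)
    lev = (-3.0 * ((az - az0) / (az_width / 2.0)) ** 2
           - 3.0 * ((el - el0) / (el_width / 2.0)) ** 2)
    return np.maximum(lev, floor_db)


def cap_mic_directions(n: int = 34, cap_deg: float = 90.0,
                       axis_jitter_seed: int | None = None):
    """Quasi-uniform (Fibonacci) directions within a cap about +x, degrees."""
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    cmin = np.cos(np.radians(cap_deg))
    x = cmin + (1.0 - cmin) * (1.0 - (i + 0.5) / n)
    r = np.sqrt(1.0 - x ** 2)
    y = r * np.cos(golden * i)
    z = r * np.sin(golden * i)
    az = np.degrees(np.arctan2(y, x))
    el = np.degrees(np.arcsin(np.clip(z, -1, 1)))
    return az, el
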