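"""Direct least-squares ellipse fitting (numerically stable formulation).

Fits the conic ``a x² + b xy + c y² + d x + e y + f = 0`` subject to the
ellipse constraint ``4ac − b² = 1`` by the partitioned generalized
eigenproblem of Halir & Flusser, which is exact for noise-free conic data
and immune to the singular scatter matrices of the original formulation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_conic_ellipse", "conic_to_geometric"]


def fit_conic_ellipse(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Return conic coefficients (a, b, c, d, e, f) of the best ellipse.

    Raises ``ValueError`` for fewer than 5 points or when the constrained
    solution is not an ellipse.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < 5:
        raise ValueError("ellipse fit needs at least 5 points")
    # center/scale for conditioning
    mx, my = x.mean(), y.mean()
    s = max(x.std(), y.std(), 1e-12)
    xs, ys = (x - mx) / s, (y - my) / s

    d1 = np.column_stack([xs ** 2, xs * ys, ys ** 2])
    d2 = np.column_stack([xs, ys, np.ones_like(xs)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    c1_inv = np.array([[0.0, 0.0, 0.5], [0.0, -1.0, 0.0], [0.5, 0.0, 0.0]])
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate point configuration") from exc
    m = c1_inv @ (s1 + s2 @ t)
    eigval, eigvec = np.linalg.eig(m)
    # ellipse solution: the eigenvector with 4ac - b^2 > 0
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.where(np.isreal(eigval) & (cond > 0))[0]
    if len(ok) == 0:
        raise ValueError("best-fitting conic is not an ellipse")
    a1 = np.real(eigvec[:, ok[0]])
    coef_s = np.concatenate([a1, t @ a1])

    # undo the normalization: conic in scaled coords u=(x-mx)/s, v=(y-my)/s
    a, b, c, d, e, f = coef_s
    conic = np.array([
        a / s ** 2,
        b / s ** 2,
        c / s ** 2,
        (-2 * a * mx - b * my) / s ** 2 + d / s,
        (-2 * c * my - b * mx) / s ** 2 + e / s,
        (a * mx ** 2 + b * mx * my + c * my ** 2) / s ** 2
        - (d * mx + e * my) / s + f,
    ])
    return conic / np.linalg.norm(conic[:3])


def conic_to_geometric(conic: np.ndarray
                       ) -> tuple[float, float, float, float, float]:
    """Conic (a,b,c,d,e,f) → center (x0, y0), semi-axes (r1 ≥ r2), angle.

    ``angle`` (radians) is the orientation of the major axis; for circles
    (axes equal within 1e-9 relative) the angle is reported as 0 by
    convention.
    """
    a, b, c, d, e, f = conic
    disc = 4 * a * c - b ** 2
    if disc <= 0:
        raise ValueError("conic is not an ellipse")
    x0 = (b * e - 2 * c * d) / disc
    y0 = (b * d - 2 * a * e) / disc
    # constant after recentering
    f0 = f + a * x0 ** 2 + b * x0 * y0 + c * y0 ** 2 + d * x0 + e * y0
    m = np.array([[a, b / 2], [b / 2, c]])
    eigval, eigvec = np.linalg.eigh(m)
    if np.any(eigval * (-f0) <= 0):
        raise ValueError("degenerate ellipse")
    radii = np.sqrt(-f0 / eigval)
    order = np.argsort(-radii)
    radii = radii[order]
    vec = eigvec[:, order[0]]
    if abs(radii[0] - radii[1]) <= 1e-9 * radii[0]:
        angle = 0.0
    else:
        angle = float(np.arctan2(vec[1], vec[0]))
        if angle <= -np.pi / 2:
            angle += np.pi
        elif angle > np.pi / 2:
            angle -= np.pi
    return float(x0), float(y0), float(radii[0]), float(radii[1]), angle
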