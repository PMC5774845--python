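"""Reconstruction of click beam patterns from microphone-array measurements.

A flying bat's click is received by microphones scattered over the room
walls.  Per microphone, the energy spectral density (ESD) of the click is
compensated for spherical spreading, atmospheric absorption and microphone
response, projected into a bat-centred azimuth–elevation frame derived from
head markers (or from the flight trajectory when markers drop out), and
interpolated over the sphere with radial basis functions.  The −3 dB contour
of the normalized pattern, extracted under the Eckert IV equal-area
projection, is summarized by its best-fitting ellipse; the ellipse center
defines the beam center at each frequency.  Five spatial-sampling criteria
gate which clicks are good enough to analyze.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

from .acoustics import AcousticMedium, DirectionGrid
from .ellipse import conic_to_geometric, fit_conic_ellipse
from .projection import eckert4_forward, eckert4_inverse

__all__ = [
    "MicrophoneSpec",
    "BatPose",
    "ClickObservation",
    "ReconstructedBeam",
    "EllipseFit",
    "QualityCriteria",
    "QualityReport",
    "ContourError",
    "head_pose_from_markers",
    "head_pose_fallback",
    "compensate_esd",
    "project_mics_to_bat_frame",
    "SphericalRBF",
    "rbf_interpolate",
    "contour_minus3db",
    "fit_ellipse",
    "beam_center",
    "quality_filter",
    "reconstruct_click",
]

MIC_BAND_HZ = (10_000.0, 100_000.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MicrophoneSpec:
    """One microphone of the room array.

    ``sensitivity`` is a (frequencies_hz, db) pair defined over the
    10–100 kHz band (None = flat 0 dB).  ``directivity`` is ``"flat"``
    (default, no correction) or ``("baffled_piston", radius_m)`` for a
    circular-membrane receiver model.
    """

    mic_id: int
    position: np.ndarray              # m, room frame
    facing: np.ndarray                # unit vector
    sensitivity: tuple | None = None
    directivity: object = "flat"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        fac = np.asarray(self.facing, dtype=float).reshape(3)
        n = np.linalg.norm(fac)
        if n == 0:
            raise ValueError("facing vector must be nonzero")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "facing", fac / n)

    def sensitivity_db(self, frequency) -> np.ndarray:
        f = np.asarray(frequency, dtype=float)
        if np.any(f < MIC_BAND_HZ[0]) or np.any(f > MIC_BAND_HZ[1]):
            raise ValueError(
                "frequency outside the 10-100 kHz sensitivity band")
        if self.sensitivity is None:
            return np.zeros_like(f)
        sf, sdb = self.sensitivity
        return np.interp(f, np.asarray(sf, dtype=float),
                         np.asarray(sdb, dtype=float))

    def directivity_db(self, angle_rad, frequency,
                       medium: AcousticMedium | None = None) -> np.ndarray:
        """Receiving directivity at off-axis angle, dB (≤ 0)."""
        f = np.asarray(frequency, dtype=float)
        if self.directivity == "flat":
            return np.zeros(np.broadcast(np.asarray(angle_rad), f).shape)
        kind, radius = self.directivity
        if kind != "baffled_piston":
            raise ValueError(f"unknown directivity model {self.directivity!r}")
        from scipy.special import j1
        medium = medium or AcousticMedium()
        ka = 2 * np.pi * f / medium.c * radius
        x = ka * np.sin(angle_rad)
        amp = np.ones_like(x * 1.0)
        nz = np.abs(x) > 1e-12
        amp[nz] = 2 * j1(x[nz]) / x[nz]
        return 20.0 * np.log10(np.maximum(np.abs(amp), 1e-6))


@dataclass(frozen=True)
class BatPose:
    """Bat head position and orientation in the room frame.

    ``aim`` is the head aim (rostral x of the bat frame), ``normal`` the
    head-up direction (dorsal z); ``left = normal × aim`` completes the
    right-handed bat frame.
    """

    position: np.ndarray
    aim: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        aim = np.asarray(self.aim, dtype=float).reshape(3)
        nrm = np.asarray(self.normal, dtype=float).reshape(3)
        aim = aim / np.linalg.norm(aim)
        nrm = nrm - (nrm @ aim) * aim          # orthogonalize
        n = np.linalg.norm(nrm)
        if n < 1e-12:
            raise ValueError("head normal parallel to head aim")
        nrm = nrm / n
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "aim", aim)
        object.__setattr__(self, "normal", nrm)

    @property
    def left(self) -> np.ndarray:
        return np.cross(self.normal, self.aim)

    @property
    def rotation(self) -> np.ndarray:
        """3×3 matrix whose rows are the bat-frame axes (x, y, z)."""
        return np.stack([self.aim, self.left, self.normal])


@dataclass(frozen=True)
class ClickObservation:
    """One click: per-microphone ESD spectra plus the pose at emission."""

    click_id: int
    side: str                          # "left" | "right"
    time: float
    mic_ids: np.ndarray
    esd_db: np.ndarray                 # (n_mics, n_freq), raw received dB
    frequencies: np.ndarray            # Hz
    pose: BatPose
    pose_source: str = "markers"       # "markers" | "trajectory-fallback"
    noise_floor_db: float = -60.0

    def __post_init__(self) -> None:
        mids = np.asarray(self.mic_ids, dtype=np.int64)
        esd = np.atleast_2d(np.asarray(self.esd_db, dtype=float))
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "mic_ids", mids)
        object.__setattr__(self, "esd_db", esd)
        object.__setattr__(self, "frequencies", f)
        if len(mids) < 1:
            raise ValueError("click needs at least one microphone entry")
        if esd.shape != (len(mids), len(f)):
            raise ValueError("esd_db must be (n_mics, n_freq)")
        if np.any(f < MIC_BAND_HZ[0]) or np.any(f > MIC_BAND_HZ[1]):
            raise ValueError("click frequencies outside the 10-100 kHz band")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass(frozen=True)
class ReconstructedBeam:
    """RBF-interpolated normalized beam pattern of one click."""

    energy_db: np.ndarray              # (n_freq, n_el, n_az), max 0 dB
    frequencies: np.ndarray
    grid: DirectionGrid
    sample_az: np.ndarray              # mic directions, bat frame, deg
    sample_el: np.ndarray
    sample_db: np.ndarray              # (n_mics, n_freq), same normalization
    metadata: dict = field(default_factory=dict)

    def level(self, frequency: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.frequencies - frequency)))
        if abs(self.frequencies[i] - frequency) > 1.0:
            raise KeyError(f"frequency {frequency} Hz not reconstructed")
        return self.energy_db[i]


@dataclass(frozen=True)
class EllipseFit:
    """Best-fitting ellipse to a −3 dB contour under Eckert IV.

    Center is reported in angular coordinates (deg, via the inverse
    projection); extents are angular widths with the projection stretch
    compensated; ``aspect_ratio`` is elevation extent / azimuth extent.
    """

    center_az: float
    center_el: float
    az_extent: float                   # full angular width, deg
    el_extent: float
    rotation_deg: float                # major-axis orientation, map frame
    semi_axes_map: tuple               # (major, minor), map units

    @property
    def aspect_ratio(self) -> float:
        return self.el_extent / self.az_extent


class ContourError(RuntimeError):
    """Raised when no usable −3 dB contour exists."""


# ---------------------------------------------------------------------------
# head pose
# ---------------------------------------------------------------------------


def head_pose_from_markers(a, b, c, position=None) -> BatPose:
    """Head pose from the three head-stage markers.

    ``a`` is the front marker, ``b``/``c`` the rear pair.  The aim points
    from the rear-pair midpoint to ``a``; the head normal is the cross
    product (a−b) × (a−c), flipped if needed so it has a positive room-z
    (dorsal) component.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    aim = a - 0.5 * (b + c)
    normal = np.cross(a - b, a - c)
    if np.linalg.norm(normal) < 1e-12 * max(np.linalg.norm(a - b), 1e-300):
        raise ValueError("markers are collinear; head pose undefined")
    if normal[2] < 0:
        normal = -normal
    return BatPose(position if position is not None else a, aim, normal)


def head_pose_fallback(times, positions, t, window: float = 0.1) -> BatPose:
    """Head pose approximated from the flight trajectory.

    The aim is the horizontal (x–y plane) projection of the trajectory
    tangent at ``t``, from a quadratic fit to the samples within ``window``
    seconds; the head normal is the floor-plane normal (room +z).
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    sel = np.abs(times - t) <= window
    if sel.sum() < 3 or times[sel].min() > t or times[sel].max() < t:
        raise ValueError("need >= 3 trajectory samples bracketing t")
    ts = times[sel] - t
    coef = np.polynomial.polynomial.polyfit(ts, positions[sel], deg=2)
    velocity = coef[1]                 # derivative at t
    pos = coef[0]
    tangent = np.array([velocity[0], velocity[1], 0.0])
    if np.linalg.norm(tangent) < 1e-9:
        raise ValueError("stationary trajectory segment; aim undefined")
    return BatPose(pos, tangent, np.array([0.0, 0.0, 1.0]))


# ---------------------------------------------------------------------------
# compensation and bat-frame projection
# ---------------------------------------------------------------------------


def compensate_esd(raw_esd_db, mic: MicrophoneSpec, range_m: float,
                   frequency, medium: AcousticMedium | None = None, *,
                   r_ref: float = 0.1, off_axis_rad: float = 0.0,
                   absorption: bool = True) -> np.ndarray:
    """Back out propagation and instrument effects from a raw ESD.

    Adds ``20 log10(range/r_ref)`` spherical spreading and ``α(f)·range``
    atmospheric absorption (ISO 9613-1), subtracts the microphone
    sensitivity, and divides out the receiving directivity at the
    microphone→bat off-axis angle.  ``r_ref`` is the reference range of the
    compensated level.
    """
    medium = medium or AcousticMedium()
    if range_m <= r_ref:
        raise ValueError(f"range {range_m} m must exceed the reference "
                         f"range {r_ref} m")
    f = np.asarray(frequency, dtype=float)
    out = np.asarray(raw_esd_db, dtype=float) + 20.0 * np.log10(
        range_m / r_ref)
    if absorption:
        out = out + medium.absorption_db_per_m(f) * range_m
    out = out - mic.sensitivity_db(f)
    out = out - mic.directivity_db(off_axis_rad, f, medium)
    return out


def project_mics_to_bat_frame(mic_positions, pose: BatPose
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Microphone directions in the bat frame: (azimuth°, elevation°, range m).

    Azimuth is positive to the bat's left, elevation positive dorsal.
    """
    pos = np.atleast_2d(np.asarray(mic_positions, dtype=float))
    rel = (pos - pose.position) @ pose.rotation.T
    rng = np.linalg.norm(rel, axis=1)
    if np.any(rng < 1e-9):
        raise ValueError("microphone coincident with the bat position")
    az = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
    el = np.degrees(np.arcsin(np.clip(rel[:, 2] / rng, -1.0, 1.0)))
    return az, el, rng


# ---------------------------------------------------------------------------
# spherical RBF interpolation
# ---------------------------------------------------------------------------


def _unit_vectors(az_deg, el_deg) -> np.ndarray:
    az = np.radians(np.asarray(az_deg, dtype=float))
    el = np.radians(np.asarray(el_deg, dtype=float))
    return np.stack([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az),
                     np.sin(el)], axis=-1)


class SphericalRBF:
    """Exact Gaussian radial-basis interpolation on the sphere.

    The kernel acts on chordal distance (a monotone function of the
    great-circle angle, so the spherical geometry is respected) with scale
    ``eps = scale_factor × median nearest-neighbour spacing``.  Being
    strictly positive definite, the Gaussian kernel interpolates exactly
    without the long-range ringing that polyharmonic kernels exhibit on
    sparse spherical samples with a high dynamic range.
    """

    def __init__(self, az_deg, el_deg, values, *,
                 scale_factor: float = 2.0) -> None:
        self.nodes = _unit_vectors(az_deg, el_deg)
        v = np.asarray(values, dtype=float).ravel()
        n = len(v)
        if n != len(self.nodes):
            raise ValueError("values must match sample count")
        chord = np.linalg.norm(self.nodes[:, None, :] - self.nodes[None],
                               axis=-1)
        off = chord[~np.eye(n, dtype=bool)]
        if off.size and off.min() < 1e-9:
            raise ValueError("duplicate sample directions")
        self.eps = scale_factor * float(np.median(np.sort(chord, axis=1)[:, 1]))
        a = np.zeros((n + 1, n + 1))
        a[:n, :n] = np.exp(-(chord / self.eps) ** 2)
        a[:n, n] = 1.0
        a[n, :n] = 1.0
        sol = np.linalg.solve(a, np.concatenate([v, [0.0]]))
        self.weights = sol[:n]
        self.constant = sol[n]

    def __call__(self, az_deg, el_deg) -> np.ndarray:
        pts = _unit_vectors(az_deg, el_deg)
        shape = pts.shape[:-1]
        chord = np.linalg.norm(pts.reshape(-1, 1, 3) - self.nodes[None],
                               axis=-1)
        out = np.exp(-(chord / self.eps) ** 2) @ self.weights + self.constant
        return out.reshape(shape)

    def min_angle_deg(self, az_deg, el_deg) -> np.ndarray:
        """Great-circle angle from each query direction to its nearest node."""
        pts = _unit_vectors(az_deg, el_deg)
        shape = pts.shape[:-1]
        cosang = (pts.reshape(-1, 3) @ self.nodes.T).max(axis=1)
        return np.degrees(np.arccos(np.clip(cosang, -1, 1))).reshape(shape)


def rbf_interpolate(sample_az, sample_el, sample_db,
                    grid: DirectionGrid | None = None, *,
                    coverage_deg: float = 30.0,
                    floor_db: float = -60.0,
                    scale_factor: float = 2.0
                    ) -> tuple[np.ndarray, float, np.ndarray]:
    """Interpolate scattered directional levels (dB) onto a grid.

    Interpolation runs in the linear energy domain — the natural domain of
    an energy spectral density — which keeps the interpolant bounded where
    many samples sit near the noise floor.  Grid cells farther than
    ``coverage_deg`` from every sample are extrapolation, not measurement:
    they are filled with ``floor_db`` and excluded from normalization.

    Returns ``(grid_db, offset_db, mask)``: the map renormalized to 0 dB
    max over covered cells, the subtracted peak level so that
    ``sample_db - offset_db`` is on the map's scale, and the boolean
    coverage mask.
    """
    grid = grid or DirectionGrid.default()
    sample_az = np.asarray(sample_az, dtype=float)
    sample_db = np.asarray(sample_db, dtype=float)
    if len(sample_az) < 5:
        raise ValueError("need at least 5 directional samples")
    if np.ptp(sample_az) <= 90.0:
        raise ValueError("samples must span more than 90 degrees of azimuth")
    rbf = SphericalRBF(sample_az, sample_el, 10.0 ** (sample_db / 10.0),
                       scale_factor=scale_factor)
    azg, elg = np.meshgrid(grid.azimuth, grid.elevation)
    lin = np.maximum(rbf(azg, elg), 10.0 ** (floor_db / 10.0) * 1e-3)
    mask = rbf.min_angle_deg(azg, elg) <= coverage_deg
    if not mask.any():
        raise ValueError("no grid cell within coverage of the samples")
    peak = float(lin[mask].max())
    level = np.where(mask, 10.0 * np.log10(lin / peak), floor_db)
    level = np.maximum(level, floor_db)
    return level, 10.0 * np.log10(peak), mask


def reconstruct_click(click: ClickObservation, mics: dict,
                      medium: AcousticMedium | None = None,
                      grid: DirectionGrid | None = None,
                      frequencies=None, *, r_ref: float = 0.1,
                      absorption: bool = True,
                      sample_shift: tuple = (0.0, 0.0)) -> ReconstructedBeam:
    """Full single-click reconstruction.

    ``mics`` maps microphone id → :class:`MicrophoneSpec`.  ``frequencies``
    selects a subset of the click's spectrum (default: all).
    ``sample_shift`` (Δaz, Δel in degrees) is applied to the microphone
    directions before interpolation — the hook used by iterative beam-axis
    alignment.
    """
    medium = medium or AcousticMedium()
    grid = grid or DirectionGrid.default()
    if frequencies is None:
        frequencies = click.frequencies
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    f_idx = [int(np.argmin(np.abs(click.frequencies - f)))
             for f in frequencies]

    mic_list = [mics[i] for i in click.mic_ids]
    positions = np.array([m.position for m in mic_list])
    az, el, rng = project_mics_to_bat_frame(positions, click.pose)
    az = az + sample_shift[0]
    # keep shifted samples strictly off the poles, where azimuth degenerates
    # and distinct microphones would collapse onto one direction
    el = np.clip(el + sample_shift[1], -89.5, 89.5)

    comp = np.empty((len(mic_list), len(frequencies)))
    for j, (mic, r) in enumerate(zip(mic_list, rng)):
        off_axis = _mic_off_axis(mic, click.pose.position)
        comp[j] = compensate_esd(click.esd_db[j, f_idx], mic, r, frequencies,
                                 medium, r_ref=r_ref, off_axis_rad=off_axis,
                                 absorption=absorption)

    maps = np.empty((len(frequencies),) + grid.shape)
    samples = np.empty_like(comp)
    for i in range(len(frequencies)):
        maps[i], offset, _ = rbf_interpolate(az, el, comp[:, i], grid)
        samples[:, i] = comp[:, i] - offset
    return ReconstructedBeam(maps, frequencies, grid, az, el, samples,
                             {"click_id": click.click_id, "side": click.side,
                              "pose_source": click.pose_source})


def _mic_off_axis(mic: MicrophoneSpec, bat_position: np.ndarray) -> float:
    to_bat = np.asarray(bat_position) - mic.position
    n = np.linalg.norm(to_bat)
    if n < 1e-9:
        return 0.0
    return float(np.arccos(np.clip(mic.facing @ (to_bat / n), -1.0, 1.0)))


# ---------------------------------------------------------------------------
# contouring and ellipse metrics
# ---------------------------------------------------------------------------


def contour_minus3db(level_db: np.ndarray, grid: DirectionGrid,
                     threshold: float = -3.0
                     ) -> tuple[np.ndarray, bool]:
    """Extract the −3 dB iso-contour enclosing the beam maximum.

    Returns ``(polygon, boundary_flag)``: the contour as an (N, 2) array of
    Eckert IV map coordinates, and a flag set when the chosen contour is
    open (touches the grid boundary) — a symptom of under-coverage that
    feeds the quality criteria.  Raises :class:`ContourError` when the map
    never crosses the threshold.
    """
    lev = np.asarray(level_db, dtype=float)
    if abs(lev.max()) > 1e-6:
        raise ValueError("level map must be normalized to 0 dB max")
    if lev.min() > threshold:
        raise ContourError(
            f"beam never falls below {threshold} dB on the grid")
    contours = measure.find_contours(lev, threshold)
    if not contours:
        raise ContourError("no iso-contour found")
    imax = np.unravel_index(np.argmax(lev), lev.shape)
    peak = np.array([imax[0], imax[1]], dtype=float)

    best, best_closed = None, False
    from matplotlib.path import Path
    for cont in contours:
        closed = np.allclose(cont[0], cont[-1])
        if closed and Path(cont).contains_point(peak):
            best, best_closed = cont, True
            break
    if best is None:
        # open contour: pick the one passing nearest the peak
        dists = [np.min(np.linalg.norm(c - peak, axis=1)) for c in contours]
        best = contours[int(np.argmin(dists))]
        best_closed = False

    az = np.interp(best[:, 1], np.arange(len(grid.azimuth)), grid.azimuth)
    el = np.interp(best[:, 0], np.arange(len(grid.elevation)),
                   grid.elevation)
    x, y = eckert4_forward(az, el)
    return np.column_stack([x, y]), (not best_closed)


def fit_ellipse(points_xy: np.ndarray) -> EllipseFit:
    """Best-fitting ellipse to projected contour points.

    The conic fit runs in Eckert IV map coordinates; the center is mapped
    back through the inverse projection, and the azimuth/elevation extents
    are measured as angular widths of the inverse-projected ellipse
    boundary, which compensates the projection stretch.
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    if len(pts) < 5:
        raise ValueError("ellipse fit needs at least 5 contour points")
    conic = fit_conic_ellipse(pts[:, 0], pts[:, 1])
    x0, y0, r1, r2, ang = conic_to_geometric(conic)
    c_az, c_el = eckert4_inverse(x0, y0)
    t = np.linspace(0.0, 2.0 * np.pi, 181)
    bx = x0 + r1 * np.cos(t) * np.cos(ang) - r2 * np.sin(t) * np.sin(ang)
    by = y0 + r1 * np.cos(t) * np.sin(ang) + r2 * np.sin(t) * np.cos(ang)
    b_az, b_el = eckert4_inverse(bx, np.clip(by, *_y_domain()))
    return EllipseFit(float(c_az), float(c_el),
                      float(np.ptp(b_az)), float(np.ptp(b_el)),
                      float(np.degrees(ang)), (r1, r2))


def _y_domain() -> tuple[float, float]:
    from .projection import _CY
    return -_CY, _CY


def beam_center(level_db: np.ndarray, grid: DirectionGrid
                ) -> tuple[float, float]:
    """Beam center: center of the −3 dB best-fitting ellipse, (az°, el°)."""
    poly, _ = contour_minus3db(level_db, grid)
    fit = fit_ellipse(poly)
    return fit.center_az, fit.center_el


def mean_bright_direction(level_db: np.ndarray, grid: DirectionGrid,
                          threshold: float = -1.0) -> tuple[float, float]:
    """Mean direction of all grid points above ``threshold`` dB.

    The cross-check used to validate the ellipse-center definition of the
    beam center: for well-sampled beams the two agree closely.
    """
    lev = np.asarray(level_db, dtype=float)
    mask = lev > threshold
    u = grid.unit_vectors()[mask]
    m = u.mean(axis=0)
    m = m / np.linalg.norm(m)
    return (float(np.degrees(np.arctan2(m[1], m[0]))),
            float(np.degrees(np.arcsin(np.clip(m[2], -1, 1)))))


# ---------------------------------------------------------------------------
# quality criteria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QualityCriteria:
    """Thresholds of the five spatial-sampling quality predicates.

    Defaults are declared approximations chosen so that densely sampled
    synthetic clicks pass; every threshold is exposed in configuration.
    """

    min_az_span: float = 120.0         # (1) azimuthal span of mics, deg
    min_el_span: float = 60.0          # (2) elevational span, deg
    max_mic_interior: bool = True      # (3) peak mic off the hull boundary
    min_neighbors: int = 5             # (4) mics near the peak mic ...
    neighbor_radius: float = 30.0      #     ... within this angle, deg
    min_snr: float = 10.0              # (5) peak level above noise floor, dB


@dataclass(frozen=True)
class QualityReport:
    passed: bool
    az_span_ok: bool
    el_span_ok: bool
    peak_interior_ok: bool
    neighbors_ok: bool
    snr_ok: bool
    details: dict = field(default_factory=dict)


def quality_filter(click: ClickObservation, mics: dict,
                   criteria: QualityCriteria | None = None) -> QualityReport:
    """Evaluate the five spatial-sampling quality criteria for one click."""
    if criteria is None:
        raise ValueError("quality criteria configuration is required")
    positions = np.array([mics[i].position for i in click.mic_ids])
    az, el, _ = project_mics_to_bat_frame(positions, click.pose)

    az_span = float(np.ptp(az))
    el_span = float(np.ptp(el))
    c1 = az_span >= criteria.min_az_span
    c2 = el_span >= criteria.min_el_span

    peak = int(np.argmax(click.esd_db.max(axis=1)))
    x, y = eckert4_forward(az, el)
    hull = ConvexHull(np.column_stack([x, y]))
    c3 = (peak not in set(hull.vertices)) or not criteria.max_mic_interior

    u = _unit_vectors(az, el)
    ang = np.degrees(np.arccos(np.clip(u @ u[peak], -1.0, 1.0)))
    n_near = int(np.sum(ang <= criteria.neighbor_radius)) - 1
    c4 = n_near >= criteria.min_neighbors

    snr = float(click.esd_db.max() - click.noise_floor_db)
    c5 = snr >= criteria.min_snr

    return QualityReport(bool(c1 and c2 and c3 and c4 and c5),
                         c1, c2, c3, c4, c5,
                         {"az_span": az_span, "el_span": el_span,
                          "peak_mic": peak, "n_neighbors": n_near,
                          "snr_db": snr})
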