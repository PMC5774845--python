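"""Forward models of sonar beam formation.

Three emitter models are provided on a common azimuth–elevation grid:

* **piston** — circular piston in an infinite baffle, the conventional model
  for mouth-emitting biosonar: ``D(theta) = 2 J1(ka sin theta)/(ka sin theta)``
  about the head aim, concentric at every frequency.
* **free-field transmission array** — mouth-aperture elements radiating as
  unit monopoles, coherently combined with tongue-path phase shifts
  ``exp(i k r_n)``; the whole-package "fast mode".
* **boundary-element transmission array** — same combiner, but each element
  field is the exterior Helmholtz solution for a monopole radiating next to
  the rigid head surface (see :mod:`lingualsonar.bem`).

The combiner implements the coherent summation

    P_total = sum_n P_n exp(i k r_n)

with phase-only tongue factors (no 1/r_n amplitude weighting): the element
ranges enter through phase alone.  Beam patterns are stored as normalized
energy in dB re maximum, per frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from scipy.special import j1

from . import bem
from .geometry import ArraySpec, ElementRanges, HeadMesh, TonguePosition, \
    element_ranges

__all__ = [
    "AcousticMedium",
    "DirectionGrid",
    "ElementField",
    "BeamPattern",
    "DEFAULT_FREQUENCIES",
    "piston_beam",
    "freefield_element_field",
    "freefield_array_beam",
    "bem_element_field",
    "combine_elements",
    "transmission_array_beam",
    "multifreq_beam",
]

#: default multi-frequency sweep, Hz (25–55 kHz in 5 kHz steps)
DEFAULT_FREQUENCIES = tuple(float(f) for f in range(25_000, 60_000, 5_000))

_DB_FLOOR = -120.0


# ---------------------------------------------------------------------------
# medium
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcousticMedium:
    """Air at the flight-room condition.

    ``sound_speed=None`` derives c from temperature (dry-air approximation
    331.3 + 0.606 T, consistent with the tabulated value within 1 m/s over
    indoor temperatures).
    """

    temperature_c: float = 20.0
    rel_humidity: float = 50.0
    pressure_kpa: float = 101.325
    sound_speed: float | None = 343.0

    @property
    def c(self) -> float:
        if self.sound_speed is not None:
            return float(self.sound_speed)
        return 331.3 + 0.606 * self.temperature_c

    def wavenumber(self, frequency: float) -> float:
        if frequency <= 0:
            raise ValueError("frequency must be positive")
        return 2.0 * np.pi * frequency / self.c

    def wavelength(self, frequency: float) -> float:
        return self.c / frequency

    def absorption_db_per_m(self, frequency) -> np.ndarray:
        """Pure-tone atmospheric absorption coefficient (ISO 9613-1), dB/m."""
        f = np.asarray(frequency, dtype=float)
        t = self.temperature_c + 273.15
        t0, t01 = 293.15, 273.16
        pr = 101.325
        p = self.pressure_kpa
        # molar concentration of water vapour (%)
        psat = pr * 10.0 ** (-6.8346 * (t01 / t) ** 1.261 + 4.6151)
        h = self.rel_humidity * (psat / pr) / (p / pr)
        fr_o = (p / pr) * (24.0 + 4.04e4 * h * (0.02 + h) / (0.391 + h))
        fr_n = (p / pr) * (t / t0) ** -0.5 * (
            9.0 + 280.0 * h * np.exp(-4.170 * ((t / t0) ** (-1.0 / 3.0) - 1.0)))
        alpha = 8.686 * f ** 2 * (
            1.84e-11 * (pr / p) * (t / t0) ** 0.5
            + (t / t0) ** -2.5 * (
                0.01275 * np.exp(-2239.1 / t) / (fr_o + f ** 2 / fr_o)
                + 0.1068 * np.exp(-3352.0 / t) / (fr_n + f ** 2 / fr_n)))
        return alpha


# ---------------------------------------------------------------------------
# direction grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DirectionGrid:
    """Far-field azimuth–elevation sampling, degrees.

    Azimuth is positive to the animal's left, elevation positive dorsal;
    ``far_field_radius`` (m) is the evaluation radius used by the
    boundary-element model.
    """

    azimuth: np.ndarray
    elevation: np.ndarray
    far_field_radius: float = 10.0

    def __post_init__(self) -> None:
        az = np.asarray(self.azimuth, dtype=float)
        el = np.asarray(self.elevation, dtype=float)
        object.__setattr__(self, "azimuth", az)
        object.__setattr__(self, "elevation", el)
        if np.any(np.diff(az) <= 0) or np.any(np.diff(el) <= 0):
            raise ValueError("grid samples must be strictly increasing")
        if az.min() < -180 or az.max() > 180 or abs(el).max() > 90:
            raise ValueError("azimuth must lie in [-180, 180], "
                             "elevation in [-90, 90]")

    @classmethod
    def default(cls, step: float = 1.0, az_span: float = 180.0,
                el_span: float = 90.0) -> "DirectionGrid":
        az = np.arange(-az_span, az_span + step / 2, step)
        el = np.arange(-el_span, el_span + step / 2, step)
        return cls(az, el)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.elevation), len(self.azimuth)

    def unit_vectors(self) -> np.ndarray:
        """(n_el, n_az, 3) unit direction vectors in the head frame."""
        az = np.radians(self.azimuth)[None, :]
        el = np.radians(self.elevation)[:, None]
        return np.stack([np.cos(el) * np.cos(az),
                         np.cos(el) * np.sin(az),
                         np.sin(el) * np.ones_like(az)], axis=-1)


# ---------------------------------------------------------------------------
# field / pattern containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementField:
    """Complex far-field pressure of one array element at one frequency."""

    pressure: np.ndarray           # (n_el, n_az) complex
    frequency: float
    grid: DirectionGrid

    def __post_init__(self) -> None:
        p = np.asarray(self.pressure, dtype=np.complex128)
        object.__setattr__(self, "pressure", p)
        if p.shape != self.grid.shape:
            raise ValueError("pressure shape does not match grid")
        if not np.all(np.isfinite(p)):
            raise ValueError("element field contains non-finite values")


@dataclass(frozen=True)
class BeamPattern:
    """Normalized beam energy, dB re maximum, per frequency."""

    energy_db: np.ndarray          # (n_freq, n_el, n_az)
    frequencies: np.ndarray        # Hz
    grid: DirectionGrid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = np.atleast_3d(np.asarray(self.energy_db, dtype=float))
        f = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        object.__setattr__(self, "energy_db", e)
        object.__setattr__(self, "frequencies", f)
        if e.shape[0] != len(f) or e.shape[1:] != self.grid.shape:
            raise ValueError("energy_db shape does not match frequencies/grid")
        if not np.allclose(e.max(axis=(1, 2)), 0.0, atol=1e-9):
            raise ValueError("beam pattern must be normalized to 0 dB max "
                             "at every frequency")

    def level(self, frequency: float) -> np.ndarray:
        """Normalized energy map (dB) at the nearest stored frequency."""
        i = int(np.argmin(np.abs(self.frequencies - frequency)))
        if abs(self.frequencies[i] - frequency) > 1.0:
            raise KeyError(f"frequency {frequency} Hz not stored")
        return self.energy_db[i]

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {"energy_db": (("frequency", "elevation", "azimuth"),
                           self.energy_db)},
            coords={"frequency": self.frequencies,
                    "elevation": self.grid.elevation,
                    "azimuth": self.grid.azimuth})
        ds.attrs.update({k: str(v) for k, v in self.metadata.items()})
        ds.attrs["far_field_radius"] = self.grid.far_field_radius
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "BeamPattern":
        ds = xr.load_dataset(path, engine="scipy")
        grid = DirectionGrid(ds.azimuth.values, ds.elevation.values,
                             float(ds.attrs.get("far_field_radius", 10.0)))
        meta = {k: v for k, v in ds.attrs.items() if k != "far_field_radius"}
        return cls(ds.energy_db.values, ds.frequency.values, grid, meta)

    def to_long_dataframe(self):
        """CSV-friendly long format (frequency, azimuth, elevation, dB)."""
        return (self.to_dataset().to_dataframe().reset_index()
                [["frequency", "azimuth", "elevation", "energy_db"]])


def _normalize_db(power: np.ndarray) -> np.ndarray:
    """10 log10(power / max), floored to avoid -inf at exact nulls."""
    p = np.maximum(power / power.max(), 10.0 ** (_DB_FLOOR / 10.0))
    return 10.0 * np.log10(p)


# ---------------------------------------------------------------------------
# piston model
# ---------------------------------------------------------------------------


def piston_directivity(ka: float, theta: np.ndarray) -> np.ndarray:
    """Amplitude directivity 2 J1(ka sin θ)/(ka sin θ) of a baffled piston."""
    x = ka * np.sin(theta)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = 2.0 * j1(x[nz]) / x[nz]
    return out


def piston_beam(radius: float, frequency: float,
                medium: AcousticMedium | None = None,
                grid: DirectionGrid | None = None) -> BeamPattern:
    """Beam pattern of a circular piston in an infinite baffle.

    The piston axis is the head aim (+x); the pattern is axisymmetric about
    it, so the map depends only on the off-axis angle
    ``theta = arccos(cos el · cos az)``.
    """
    if radius <= 0 or frequency <= 0:
        raise ValueError("radius and frequency must be positive")
    medium = medium or AcousticMedium()
    grid = grid or DirectionGrid.default()
    ka = medium.wavenumber(frequency) * radius
    u = grid.unit_vectors()
    theta = np.arccos(np.clip(u[..., 0], -1.0, 1.0))
    amp = piston_directivity(ka, theta)
    # the infinite baffle blocks the rear half-space
    amp = np.where(u[..., 0] >= 0.0, amp, 1e-6)
    return BeamPattern(_normalize_db(amp[None] ** 2), [frequency], grid,
                       {"model": "piston", "radius_m": radius, "ka": ka})


# ---------------------------------------------------------------------------
# free-field array model
# ---------------------------------------------------------------------------


#: obliquity exponent of the baffled fast-mode element model
OBLIQUITY_EXPONENT = 2.0


def baffled_element_amplitude(u: np.ndarray, normal: np.ndarray,
                              exponent: float = OBLIQUITY_EXPONENT
                              ) -> np.ndarray:
    """Obliquity amplitude ``((1 + u·n)/2)^p`` of a baffled aperture element.

    Emulates the head's shadowing of backward radiation in the fast mode;
    the default exponent gives main-lobe widths comparable to the rigid
    head's directivity at mid-band.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    return (0.5 * (1.0 + u @ n)) ** exponent


def freefield_element_field(position_mm: np.ndarray, frequency: float,
                            medium: AcousticMedium,
                            grid: DirectionGrid,
                            normal: np.ndarray | None = None,
                            obliquity: float = OBLIQUITY_EXPONENT
                            ) -> ElementField:
    """Far-field of one free-field element at ``position_mm`` (head frame, mm).

    Only the geometric phase ``exp(-i k x_n · u)`` relative to the head
    origin is retained (common far-field spherical factor dropped).  With
    ``normal=None`` the element is a pure unit monopole.  With an outward
    surface normal given, the baffled obliquity factor emulates the
    shadowing of backward radiation by the head — the fast-mode stand-in
    for the boundary-element element field.
    """
    k = medium.wavenumber(frequency)
    x = np.asarray(position_mm, dtype=float) * 1e-3
    u = grid.unit_vectors()
    amp = 1.0
    if normal is not None:
        amp = baffled_element_amplitude(u, normal, obliquity)
    phase = -k * (u @ x)
    return ElementField(amp * np.exp(1j * phase), frequency, grid)


def combine_elements(fields: list[ElementField], ranges: ElementRanges,
                     frequency: float, medium: AcousticMedium | None = None,
                     metadata: dict | None = None) -> BeamPattern:
    """Coherent summation of element fields with tongue-path phase shifts.

    Implements ``P_total = sum_n P_n exp(i k r_n)`` — the tongue-to-element
    ranges r_n (mm) enter as pure phase factors.
    """
    medium = medium or AcousticMedium()
    if len(fields) != len(ranges.r_n):
        raise ValueError("need exactly one range per element field")
    grid = fields[0].grid
    for f in fields:
        if f.grid is not grid and (
                not np.array_equal(f.grid.azimuth, grid.azimuth)
                or not np.array_equal(f.grid.elevation, grid.elevation)):
            raise ValueError("element fields must share one direction grid")
        if f.frequency != frequency:
            raise ValueError("element fields must share the frequency")
    k = medium.wavenumber(frequency)
    phases = np.exp(1j * k * ranges.r_n * 1e-3)
    total = np.tensordot(phases, np.stack([f.pressure for f in fields]),
                         axes=(0, 0))
    meta = {"model": "transmission_array", "n_elements": len(fields)}
    meta.update(metadata or {})
    return BeamPattern(_normalize_db(np.abs(total[None]) ** 2), [frequency],
                       grid, meta)


def freefield_array_beam(array: ArraySpec, tongue: TonguePosition,
                         frequency: float,
                         medium: AcousticMedium | None = None,
                         grid: DirectionGrid | None = None) -> BeamPattern:
    """Free-field phased-array beam (no scatterer), one frequency."""
    medium = medium or AcousticMedium()
    grid = grid or DirectionGrid.default()
    fields = [freefield_element_field(p, frequency, medium, grid)
              for p in array.positions]
    ranges = element_ranges(tongue, array)
    bp = combine_elements(fields, ranges, frequency, medium,
                          {"engine": "freefield", "side": array.side,
                           "mode": array.mode})
    return bp


# ---------------------------------------------------------------------------
# boundary-element model
# ---------------------------------------------------------------------------


def surface_anchor(mesh: HeadMesh, point_mm: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Nearest mesh vertex and its outward normal for a point near the mesh.

    Array elements sit on mouth-line vertices, so the nearest vertex is the
    exact anchor; returns (vertex, unit normal, distance in mm).
    """
    from scipy.spatial import cKDTree
    pt = np.asarray(point_mm, dtype=float).reshape(3)
    tree = cKDTree(mesh.vertices)
    dist, idx = tree.query(pt)
    tm = mesh.as_trimesh()
    normal = np.asarray(tm.vertex_normals[idx], dtype=float)
    return mesh.vertices[idx], normal / np.linalg.norm(normal), float(dist)


def bem_element_field(mesh: HeadMesh, element_position_mm: np.ndarray,
                      frequency: float,
                      medium: AcousticMedium | None = None,
                      grid: DirectionGrid | None = None, *,
                      source_offset: float | None = None,
                      n_chief: int = 6) -> ElementField:
    """Far field of one array element radiating next to the rigid head.

    The element source is a unit monopole offset one mesh edge length
    outward along the local surface normal (``source_offset`` overrides,
    mm); the head surface is rigid (zero normal velocity).  The mesh must
    resolve the wavelength: mean edge ≤ λ/5 (error), warn above λ/6.
    """
    medium = medium or AcousticMedium()
    grid = grid or DirectionGrid.default()
    k = medium.wavenumber(frequency)
    lam_mm = medium.wavelength(frequency) * 1e3
    edge = mesh.edge_length()
    if edge > lam_mm / 5.0:
        raise ValueError(
            f"mesh edge length {edge:.2f} mm exceeds λ/5 = {lam_mm / 5:.2f} "
            f"mm at {frequency / 1e3:.0f} kHz; re-mesh finer")
    if edge > lam_mm / 6.0:
        warnings.warn(
            f"mesh edge length {edge:.2f} mm above λ/6 at "
            f"{frequency / 1e3:.0f} kHz; accuracy may degrade", stacklevel=2)

    pos = np.asarray(element_position_mm, dtype=float).reshape(3)
    anchor, normal, dist = surface_anchor(mesh, pos)
    if dist > edge:
        raise ValueError(
            f"element at {pos} is {dist:.2f} mm from the surface "
            f"(> one edge length {edge:.2f} mm)")
    offset = edge if source_offset is None else source_offset
    src_mm = anchor + offset * normal

    sol = bem.solve_rigid_scattering(mesh.vertices * 1e-3, mesh.triangles,
                                     src_mm * 1e-3, k, n_chief=n_chief)
    pts = grid.far_field_radius * grid.unit_vectors().reshape(-1, 3)
    p = sol.field_at(pts).reshape(grid.shape)
    return ElementField(p, frequency, grid)


# ---------------------------------------------------------------------------
# multi-frequency wrappers
# ---------------------------------------------------------------------------


def transmission_array_beam(array: ArraySpec, tongue: TonguePosition,
                            frequencies=DEFAULT_FREQUENCIES,
                            medium: AcousticMedium | None = None,
                            grid: DirectionGrid | None = None, *,
                            mesh: HeadMesh | None = None,
                            engine: str = "freefield",
                            element_model: str = "baffled") -> BeamPattern:
    """Multi-frequency transmission-array beam pattern.

    ``engine='freefield'`` (fast mode) ignores the head as a scatterer;
    ``engine='bem'`` requires ``mesh`` and runs one boundary-element solve
    per element per frequency.  The fast mode is flagged in metadata.

    In fast mode, ``element_model='baffled'`` (default) applies the cardioid
    obliquity about each element's surface normal, emulating the head's
    shadowing of backward radiation; ``'monopole'`` uses bare point sources.
    """
    medium = medium or AcousticMedium()
    grid = grid or DirectionGrid.default()
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if len(frequencies) == 0:
        raise ValueError("frequency list must be nonempty")
    ranges = element_ranges(tongue, array)
    normals = array.normals
    if element_model == "baffled" and normals is None and engine == "freefield":
        raise ValueError("element_model='baffled' needs element normals "
                         "(place the array on a mesh, or pass "
                         "element_model='monopole')")
    maps = []
    for f in frequencies:
        if engine == "freefield":
            fields = [
                freefield_element_field(
                    p, f, medium, grid,
                    normal=(normals[i] if element_model == "baffled"
                            else None))
                for i, p in enumerate(array.positions)]
        elif engine == "bem":
            if mesh is None:
                raise ValueError("engine='bem' requires a head mesh")
            fields = [bem_element_field(mesh, p, f, medium, grid)
                      for p in array.positions]
        else:
            raise ValueError(f"unknown engine {engine!r}")
        maps.append(combine_elements(fields, ranges, f, medium).energy_db[0])
    meta = {"model": "transmission_array", "engine": engine,
            "element_model": (element_model if engine == "freefield"
                              else "bem"),
            "scatterer": engine == "bem", "side": array.side,
            "mode": array.mode, "n_elements": array.n_elements,
            "tongue_mm": tuple(np.round(tongue.location, 3))}
    return BeamPattern(np.stack(maps), frequencies, grid, meta)


def multifreq_beam(model: str, frequencies=DEFAULT_FREQUENCIES,
                   medium: AcousticMedium | None = None,
                   grid: DirectionGrid | None = None,
                   **params) -> BeamPattern:
    """Evaluate a named model over a frequency sweep.

    ``model`` is ``'piston'`` (needs ``radius``), ``'freefield'`` or
    ``'bem'`` (need ``array`` and ``tongue``; bem also needs ``mesh``).
    """
    medium = medium or AcousticMedium()
    grid = grid or DirectionGrid.default()
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if len(frequencies) == 0:
        raise ValueError("frequency list must be nonempty")
    if model == "piston":
        maps = [piston_beam(params["radius"], f, medium, grid).energy_db[0]
                for f in frequencies]
        return BeamPattern(np.stack(maps), frequencies, grid,
                           {"model": "piston", "radius_m": params["radius"]})
    if model in ("freefield", "bem"):
        return transmission_array_beam(
            params["array"], params["tongue"], frequencies, medium, grid,
            mesh=params.get("mesh"), engine=model)
    raise ValueError(f"unknown model {model!r}")
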