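"""Beam-axis alignment of individual clicks and average beam construction.

Bats click in many directions, so individual beam measurements scatter over
the azimuth–elevation domain.  To pool them, each click's microphone
coordinates are iteratively shifted until the center of the −3 dB
best-fitting ellipse at the 35 kHz reference frequency falls on the map
origin; the aligned per-microphone samples of all clicks of one side are
then merged, averaged in 10°×10° bins, and interpolated into a smooth
average beam pattern.  The averaging pools *samples*, not per-click maps,
so the average is far more densely sampled than any individual click.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acoustics import DirectionGrid
from .beamrecon import (ClickObservation, ContourError, ReconstructedBeam,
                        beam_center, contour_minus3db, fit_ellipse,
                        rbf_interpolate, reconstruct_click)

__all__ = ["AlignmentResult", "AlignedClick", "AverageBeam",
           "align_click", "merge_average", "beam_metrics",
           "REFERENCE_FREQUENCY"]

#: alignment reference frequency, Hz
REFERENCE_FREQUENCY = 35_000.0


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of the iterative beam-axis alignment of one click."""

    click_id: int
    az_shift: float                # cumulative azimuth shift, deg
    el_shift: float                # cumulative elevation shift, deg
    rotation_deg: float
    iterations: int
    converged: bool
    residual_deg: float            # |ellipse center| after the last step


@dataclass(frozen=True)
class AlignedClick:
    """Aligned per-microphone samples of one click, all frequencies."""

    result: AlignmentResult
    side: str
    sample_az: np.ndarray          # shifted coordinates, deg
    sample_el: np.ndarray
    sample_db: np.ndarray          # (n_mics, n_freq), normalized per freq
    frequencies: np.ndarray


@dataclass(frozen=True)
class AverageBeam:
    """Binned and interpolated average beam pattern of one click side."""

    bin_mean_db: np.ndarray        # (n_freq, n_el_bins, n_az_bins), NaN=empty
    bin_count: np.ndarray          # (n_el_bins, n_az_bins) pooled over freqs
    bin_az: np.ndarray             # bin centers, deg
    bin_el: np.ndarray
    energy_db: np.ndarray          # smooth surface, (n_freq, grid shape)
    frequencies: np.ndarray
    grid: DirectionGrid
    side: str
    n_clicks: int
    metadata: dict = field(default_factory=dict)

    def level(self, frequency: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.frequencies - frequency)))
        if abs(self.frequencies[i] - frequency) > 1.0:
            raise KeyError(f"frequency {frequency} Hz not available")
        return self.energy_db[i]

    def to_dataset(self):
        import xarray as xr
        return xr.Dataset(
            {"energy_db": (("frequency", "elevation", "azimuth"),
                           self.energy_db),
             "bin_mean_db": (("frequency", "bin_el", "bin_az"),
                             self.bin_mean_db),
             "bin_count": (("bin_el", "bin_az"),
                           self.bin_count.astype(np.int32))},
            coords={"frequency": self.frequencies,
                    "elevation": self.grid.elevation,
                    "azimuth": self.grid.azimuth,
                    "bin_el": self.bin_el, "bin_az": self.bin_az},
            attrs={"side": self.side, "n_clicks": self.n_clicks})

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def align_click(click: ClickObservation, mics: dict,
                grid: DirectionGrid | None = None,
                reference_frequency: float = REFERENCE_FREQUENCY, *,
                tol: float = 0.5, max_iter: int = 20,
                rotate: bool = False, medium=None,
                frequencies=None) -> AlignedClick:
    """Iteratively center one click's beam axis on the map origin.

    Each iteration reconstructs the beam at the reference frequency from
    the shifted microphone coordinates, fits the −3 dB ellipse, and shifts
    all coordinates by minus its center; iteration stops when the center is
    within ``tol`` degrees of the origin or after ``max_iter`` rounds.
    With ``rotate=True`` the mic constellation is additionally rotated
    about the origin so the ellipse major axis aligns with the map x-axis
    (the rotation target the alignment description leaves open; shifting
    alone is the default).
    """
    grid = grid or DirectionGrid.default()
    shift = np.zeros(2)
    rotation = 0.0
    converged = False
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        rb = reconstruct_click(click, mics, medium, grid,
                               [reference_frequency], sample_shift=shift)
        try:
            c_az, c_el = beam_center(rb.level(reference_frequency), grid)
        except (ContourError, ValueError) as exc:
            raise ContourError(
                f"click {click.click_id}: no −3 dB ellipse at "
                f"{reference_frequency / 1e3:.0f} kHz ({exc})") from exc
        residual = float(np.hypot(c_az, c_el))
        if residual < tol:
            converged = True
            break
        shift = shift - [c_az, c_el]

    final = reconstruct_click(click, mics, medium, grid,
                              frequencies, sample_shift=tuple(shift))
    az, el = final.sample_az, final.sample_el
    if rotate and converged:
        az, el, rotation = _level_major_axis(final, az, el, grid,
                                             reference_frequency)
    result = AlignmentResult(click.click_id, float(shift[0]),
                             float(shift[1]), rotation, it, converged,
                             residual)
    return AlignedClick(result, click.side, az, el, final.sample_db,
                        final.frequencies)


def _level_major_axis(beam: ReconstructedBeam, az, el,
                      grid: DirectionGrid, f_ref: float
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Rotate sample coordinates about the origin to level the major axis."""
    from .projection import eckert4_forward, eckert4_inverse
    poly, _ = contour_minus3db(beam.level(f_ref), grid)
    fit = fit_ellipse(poly)
    ang = np.radians(fit.rotation_deg)
    c, s = np.cos(-ang), np.sin(-ang)
    x, y = eckert4_forward(az, el)
    az2, el2 = eckert4_inverse(c * x - s * y, np.clip(s * x + c * y,
                                                      -1.3265, 1.3265))
    return az2, el2, float(-fit.rotation_deg)


def alignment_table(aligned: list[AlignedClick]):
    """Alignment results as a DataFrame (one row per click), CSV-ready."""
    import pandas as pd
    rows = [{"click_id": a.result.click_id, "side": a.side,
             "az_shift_deg": a.result.az_shift,
             "el_shift_deg": a.result.el_shift,
             "rotation_deg": a.result.rotation_deg,
             "iterations": a.result.iterations,
             "converged": a.result.converged,
             "residual_deg": a.result.residual_deg}
            for a in aligned]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------


def merge_average(aligned: list[AlignedClick], side: str,
                  bin_deg: float = 10.0,
                  grid: DirectionGrid | None = None) -> AverageBeam:
    """Merge aligned clicks of one side into an average beam pattern.

    Per frequency, the normalized per-microphone dB samples of every
    aligned click are pooled, averaged in ``bin_deg`` azimuth–elevation
    bins (empty bins stay missing, never zero-filled), and the bin means
    are interpolated into a smooth surface renormalized to 0 dB.
    """
    clicks = [a for a in aligned if a.side == side]
    if not clicks:
        raise ValueError(f"no aligned clicks on side {side!r}")
    grid = grid or DirectionGrid.default()
    freqs = clicks[0].frequencies
    for a in clicks:
        if not np.array_equal(a.frequencies, freqs):
            raise ValueError("aligned clicks must share the frequency axis")

    az = np.concatenate([a.sample_az for a in clicks])
    el = np.concatenate([a.sample_el for a in clicks])
    vals = np.vstack([a.sample_db for a in clicks])   # (n_total, n_freq)

    az_edges = np.arange(-180.0, 180.0 + bin_deg / 2, bin_deg)
    el_edges = np.arange(-90.0, 90.0 + bin_deg / 2, bin_deg)
    bin_az = 0.5 * (az_edges[:-1] + az_edges[1:])
    bin_el = 0.5 * (el_edges[:-1] + el_edges[1:])
    ia = np.clip(np.digitize(az, az_edges) - 1, 0, len(bin_az) - 1)
    ie = np.clip(np.digitize(el, el_edges) - 1, 0, len(bin_el) - 1)
    flat = ie * len(bin_az) + ia
    nbins = len(bin_el) * len(bin_az)
    count = np.bincount(flat, minlength=nbins).reshape(len(bin_el),
                                                       len(bin_az))

    mean_db = np.full((len(freqs), len(bin_el), len(bin_az)), np.nan)
    for i in range(len(freqs)):
        tot = np.bincount(flat, weights=vals[:, i], minlength=nbins)
        with np.errstate(invalid="ignore"):
            m = tot.reshape(count.shape) / np.where(count > 0, count, np.nan)
        mean_db[i] = m

    surf = np.empty((len(freqs),) + grid.shape)
    occupied = count > 0
    baz, bel = np.meshgrid(bin_az, bin_el)
    for i in range(len(freqs)):
        # bin centers form a dense regular set: a tight kernel scale avoids
        # radially oversmoothing the beam anisotropy
        level, _, _ = rbf_interpolate(baz[occupied], bel[occupied],
                                      mean_db[i][occupied], grid,
                                      coverage_deg=1.5 * bin_deg,
                                      scale_factor=1.0)
        surf[i] = level
    return AverageBeam(mean_db, count, bin_az, bin_el, surf, freqs, grid,
                       side, len(clicks),
                       {"bin_deg": bin_deg})


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def beam_metrics(levels: np.ndarray, frequencies, grid: DirectionGrid,
                 reference_frequency: float = REFERENCE_FREQUENCY) -> dict:
    """Per-frequency beam center, −3 dB widths and aspect ratio.

    ``levels`` is (n_freq, n_el, n_az) of normalized dB maps.  The returned
    ``center_az_rel`` curve is referenced to the center at the reference
    frequency (0° at 35 kHz), the quantity used to characterize the
    frequency-dependent beam direction shift.
    """
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    out = {"frequency": frequencies, "center_az": [], "center_el": [],
           "az_width": [], "el_width": [], "aspect_ratio": []}
    for i in range(len(frequencies)):
        poly, _ = contour_minus3db(levels[i], grid)
        fit = fit_ellipse(poly)
        out["center_az"].append(fit.center_az)
        out["center_el"].append(fit.center_el)
        out["az_width"].append(fit.az_extent)
        out["el_width"].append(fit.el_extent)
        out["aspect_ratio"].append(fit.aspect_ratio)
    for k in ("center_az", "center_el", "az_width", "el_width",
              "aspect_ratio"):
        out[k] = np.asarray(out[k])
    i_ref = int(np.argmin(np.abs(frequencies - reference_frequency)))
    out["center_az_rel"] = out["center_az"] - out["center_az"][i_ref]
    out["center_el_rel"] = out["center_el"] - out["center_el"][i_ref]
    return out
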