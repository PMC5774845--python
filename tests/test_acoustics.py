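import numpy as np
import pytest

from lingualsonar import geometry as geo
from lingualsonar.acoustics import (AcousticMedium, BeamPattern,
                                    DirectionGrid, combine_elements,
                                    freefield_array_beam,
                                    freefield_element_field, multifreq_beam,
                                    piston_beam, transmission_array_beam)


class TestMedium:
    def test_derived_sound_speed_close_to_tabulated(self):
        m = AcousticMedium(sound_speed=None)
        assert abs(m.c - 343.0) < 1.0

    def test_absorption_increases_with_frequency(self, medium):
        f = np.array([20e3, 35e3, 55e3, 80e3])
        a = medium.absorption_db_per_m(f)
        assert np.all(np.diff(a) > 0)
        # ultrasound in room air: order 0.5–5 dB/m across the click band
        assert 0.1 < a[0] < 2.0 and 1.0 < a[-1] < 10.0

    def test_zero_frequency_rejected(self, medium):
        with pytest.raises(ValueError):
            medium.wavenumber(0.0)


class TestPiston:
    def test_on_axis_is_reference_level(self, medium):
        bp = piston_beam(0.004, 35e3, medium)
        i0 = np.argmin(np.abs(bp.grid.elevation))
        j0 = np.argmin(np.abs(bp.grid.azimuth))
        assert bp.energy_db[0, i0, j0] == pytest.approx(0.0, abs=1e-9)

    def test_axisymmetric_in_azimuth_sign(self, medium):
        bp = piston_beam(0.004, 35e3, medium)
        i0 = np.argmin(np.abs(bp.grid.elevation))
        row = bp.energy_db[0, i0]
        np.testing.assert_allclose(row, row[::-1], atol=1e-9)

    def test_first_null_at_bessel_zero(self, medium):
        # ka = 5: first null of 2J1(x)/x at x = 3.8317 -> theta = 50.03 deg
        grid = DirectionGrid.default(step=0.5)
        f = 35e3
        radius = 5.0 / medium.wavenumber(f)
        bp = piston_beam(radius, f, medium, grid)
        i0 = np.argmin(np.abs(grid.elevation))
        row = bp.energy_db[0, i0]
        sel = (grid.azimuth > 40) & (grid.azimuth < 60)
        null_az = grid.azimuth[sel][np.argmin(row[sel])]
        assert abs(null_az - np.degrees(np.arcsin(3.8317 / 5.0))) <= 0.5

    def test_width_strictly_decreases_with_frequency(self):
        from lingualsonar.alignavg import beam_metrics
        bp = multifreq_beam("piston", radius=0.005)
        m = beam_metrics(bp.energy_db, bp.frequencies, bp.grid)
        assert np.all(np.diff(m["az_width"]) < 0)


class TestFreefieldArray:
    def test_single_element_omnidirectional(self, medium, grid1):
        arr = geo.ArraySpec(np.array([[5.0, 1.0, 0.0]]), "left", "discrete")
        t = geo.TonguePosition(np.zeros(3))
        bp = freefield_array_beam(arr, t, 35e3, medium, grid1)
        assert np.allclose(bp.energy_db, 0.0, atol=1e-9)

    def test_half_wavelength_pair_broadside_pattern(self, medium):
        # two elements lambda/2 apart, equal ranges: |cos((pi/2) sin az)|^2
        grid = DirectionGrid.default(step=1.0)
        f = 35e3
        lam = medium.wavelength(f)
        d_mm = lam / 2 * 1e3
        pos = np.array([[0.0, d_mm / 2, 0.0], [0.0, -d_mm / 2, 0.0]])
        fields = [freefield_element_field(p, f, medium, grid) for p in pos]
        bp = combine_elements(fields, geo.ElementRanges([10.0, 10.0]), f,
                              medium)
        i0 = np.argmin(np.abs(grid.elevation))
        row_power = 10 ** (bp.energy_db[0, i0] / 10.0)
        expected = np.cos(np.pi / 2
                          * np.sin(np.radians(grid.azimuth))) ** 2
        np.testing.assert_allclose(row_power, expected, atol=1e-6)

    @pytest.mark.parametrize("n,d_frac,dphi", [
        (8, 0.5, np.pi / 3), (8, 0.5, -np.pi / 4), (6, 0.4, np.pi / 6),
        (10, 0.6, np.pi / 2), (8, 0.5, 0.25)])
    def test_classical_steering_law(self, medium, n, d_frac, dphi):
        # phase gradient dphi steers to sin(az) = dphi / (k d) on the
        # elevation-0 cut of a y-axis linear array
        grid = DirectionGrid.default(step=0.25, el_span=2.0)
        f = 35e3
        k = medium.wavenumber(f)
        d = d_frac * medium.wavelength(f)
        pos = np.stack([np.zeros(n), np.arange(n) * d * 1e3 + 1.0,
                        np.zeros(n)], axis=-1)
        fields = [freefield_element_field(p, f, medium, grid) for p in pos]
        r = 50.0 + np.arange(n) * (dphi / k) * 1e3      # mm
        r = r - r.min() + 10.0
        bp = combine_elements(fields, geo.ElementRanges(r), f, medium)
        i0 = np.argmin(np.abs(grid.elevation))
        # restrict to the frontal half-plane: an unbaffled linear array has
        # an exact mirror lobe at 180 - az
        front = np.abs(grid.azimuth) <= 90.0
        row = bp.energy_db[0, i0][front]
        az_peak = grid.azimuth[front][np.argmax(row)]
        expected = np.degrees(np.arcsin(dphi / (k * d)))
        assert abs(az_peak - expected) <= 0.25

    def test_equal_ranges_mirror_symmetric_about_broadside(self, medium,
                                                           grid1):
        pos = np.stack([np.zeros(4), np.arange(4) * 2.0 + 1.0,
                        np.zeros(4)], -1)
        arr = geo.ArraySpec(pos, "left", "discrete")
        t = geo.TonguePosition(np.array([0.0, 4.0, 30.0]))
        r = np.linalg.norm(pos - t.location, axis=1)
        fields = [freefield_element_field(p, 35e3, medium, grid1)
                  for p in pos]
        bp = combine_elements(fields, geo.ElementRanges(np.full(4, 20.0)),
                              35e3, medium)
        lev = bp.energy_db[0]
        # mirror about the x-z plane (azimuth sign flip)
        np.testing.assert_allclose(lev, lev[:, ::-1], atol=1e-9)


class TestCombiner:
    def test_single_field_identity(self, medium, grid1):
        f = freefield_element_field(np.array([3.0, 2.0, 1.0]), 35e3, medium,
                                    grid1)
        bp = combine_elements([f], geo.ElementRanges([7.0]), 35e3, medium)
        ref = 10 * np.log10(np.abs(f.pressure) ** 2
                            / (np.abs(f.pressure) ** 2).max())
        np.testing.assert_allclose(bp.energy_db[0], ref, atol=1e-9)

    def test_global_range_offset_invariance(self, medium, grid1):
        pos = [np.array([2.0, 3.0, 0.0]), np.array([5.0, -1.0, 1.0])]
        fields = [freefield_element_field(p, 35e3, medium, grid1)
                  for p in pos]
        r = np.array([8.0, 11.0])
        bp1 = combine_elements(fields, geo.ElementRanges(r), 35e3, medium)
        bp2 = combine_elements(fields, geo.ElementRanges(r + 2.5), 35e3,
                               medium)
        np.testing.assert_allclose(bp1.energy_db, bp2.energy_db, atol=1e-9)

    def test_half_wavelength_cancellation(self, medium, grid1):
        f = 35e3
        lam_mm = medium.wavelength(f) * 1e3
        fld = freefield_element_field(np.array([2.0, 1.0, 0.0]), f, medium,
                                      grid1)
        in_phase = np.abs(2 * fld.pressure)
        anti = np.abs(fld.pressure
                      * (1 + np.exp(1j * medium.wavenumber(f)
                                    * lam_mm / 2 * 1e-3)))
        peak = np.unravel_index(np.argmax(in_phase), in_phase.shape)
        ratio_db = 20 * np.log10(anti[peak] / in_phase[peak] + 1e-300)
        assert ratio_db <= -40.0

    def test_grid_mismatch_rejected(self, medium, grid1):
        other = DirectionGrid.default(step=2.0)
        f1 = freefield_element_field(np.array([1.0, 0.0, 0.0]), 35e3,
                                     medium, grid1)
        f2 = freefield_element_field(np.array([1.0, 0.0, 0.0]), 35e3,
                                     medium, other)
        with pytest.raises(ValueError):
            combine_elements([f1, f2], geo.ElementRanges([5.0, 5.0]), 35e3,
                             medium)


class TestBeamPatternContainer:
    def test_normalization_enforced(self, grid1):
        bad = np.zeros((1,) + grid1.shape) - 5.0
        with pytest.raises(ValueError):
            BeamPattern(bad, [35e3], grid1)

    def test_netcdf_round_trip(self, medium, grid1, tmp_path):
        bp = piston_beam(0.004, 35e3, medium, grid1)
        path = tmp_path / "beam.nc"
        bp.to_netcdf(path)
        back = BeamPattern.from_netcdf(path)
        np.testing.assert_allclose(back.energy_db, bp.energy_db, atol=1e-6)
        np.testing.assert_allclose(back.frequencies, bp.frequencies)

    def test_long_dataframe_shape(self, medium):
        grid = DirectionGrid.default(step=30.0)
        bp = piston_beam(0.004, 35e3, medium, grid)
        df = bp.to_long_dataframe()
        assert len(df) == grid.shape[0] * grid.shape[1]
        assert set(df.columns) == {"frequency", "azimuth", "elevation",
                                   "energy_db"}


class TestTransmissionArraySignatures:
    def test_one_sided_single_dominant_frontal_lobe(self, head, medium,
                                                    grid1):
        arr = geo.place_elements(head, "left", "discrete", n=6)
        t = geo.default_tongue(head, lateral=3.0, depth_frac=0.75)
        bp = transmission_array_beam(arr, t, [35e3], medium, grid1)
        lev = bp.energy_db[0]
        imax = np.unravel_index(np.argmax(lev), lev.shape)
        assert grid1.azimuth[imax[1]] > 0          # emitting (left) side
        # no comparable lobe on the opposite side
        right_half = lev[:, grid1.azimuth < 0]
        assert right_half.max() < -3.0

    def test_both_sided_midline_tongue_mirror_symmetric(self, head, medium,
                                                        grid1):
        arr = geo.place_elements(head, "both", "discrete", n=6)
        t = geo.default_tongue(head, lateral=0.0, depth_frac=0.75)
        bp = transmission_array_beam(arr, t, [35e3], medium, grid1)
        lev = bp.energy_db[0]
        np.testing.assert_allclose(lev, lev[:, ::-1], atol=1e-6)

    def test_empty_frequency_list_rejected(self, head, medium, grid1):
        arr = geo.place_elements(head, "left", "discrete", n=4)
        t = geo.default_tongue(head)
        with pytest.raises(ValueError):
            transmission_array_beam(arr, t, [], medium, grid1)
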