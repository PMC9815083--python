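"""Phase-image mass pipeline: background, segmentation, mass, density."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from picophys import (
    CellSpec, PhaseImage, QpiSettings, density_timecourse, dry_mass_density,
    integrate_dry_mass, measure_cells, render_phase_image, segment_objects,
    spherocylinder_volume, subtract_background,
)
from picophys.qpi import read_phase_tiff, records_to_frame, write_phase_tiff


class TestSubtractBackground:
    @pytest.mark.parametrize("percentile", [0, 5, 50])
    def test_constant_image_becomes_zero(self, percentile):
        img = PhaseImage(np.full((16, 16), 3.7), 0.045)
        assert np.allclose(subtract_background(img, percentile).opd, 0.0)

    def test_zero_image_unchanged(self):
        img = PhaseImage(np.zeros((8, 8)), 0.045)
        assert np.all(subtract_background(img).opd == 0.0)

    def test_offset_removed_from_synthetic_cell(self):
        cell = [CellSpec(2.0, 0.8, 0.2, position=(3.0, 3.0))]
        clean = render_phase_image(cell, image_shape=(128, 128), noise_sd=0.0)
        offset = PhaseImage(clean.opd + 0.05, clean.pixel_size)
        corrected = subtract_background(offset, 5.0)
        np.testing.assert_allclose(corrected.opd, clean.opd, atol=1e-9)

    def test_percentile_out_of_range(self):
        img = PhaseImage(np.zeros((4, 4)), 0.045)
        with pytest.raises(ValueError):
            subtract_background(img, 60.0)


class TestSegmentObjects:
    def test_two_disjoint_cells_two_labels(self):
        cells = [CellSpec(2.0, 0.8, 0.2, position=(2.0, 2.0)),
                 CellSpec(2.0, 0.8, 0.2, position=(6.0, 6.0))]
        img = render_phase_image(cells, image_shape=(180, 180), noise_sd=0.0)
        labels = segment_objects(img, threshold=0.005)
        assert labels.max() == 2

    def test_threshold_above_max_gives_no_labels(self):
        img = PhaseImage(np.full((16, 16), 0.01), 0.045)
        assert segment_objects(img, threshold=1.0).max() == 0

    def test_min_area_removes_speck(self):
        cell = [CellSpec(2.0, 0.8, 0.2, position=(3.0, 3.0))]
        img = render_phase_image(cell, image_shape=(180, 180), noise_sd=0.0)
        opd = img.opd.copy()
        opd[5, 5] = 1.0  # single-pixel speck
        labels = segment_objects(PhaseImage(opd, img.pixel_size),
                                 threshold=0.005, min_area_px=10)
        assert labels.max() == 1
        assert labels[5, 5] == 0


class TestIntegrateDryMass:
    def test_hand_arithmetic(self):
        """0.1 um OPD on 100 px at 0.045 um with alpha 0.18 -> 0.1125 pg."""
        opd = np.zeros((20, 20))
        opd[:10, :10] = 0.1
        img = PhaseImage(opd, 0.045)
        m = integrate_dry_mass(img, opd > 0, 0.18)
        assert m == pytest.approx(0.1 * 100 * 0.045 ** 2 / 0.18)
        assert m == pytest.approx(0.1125)

    def test_zero_opd_zero_mass(self):
        img = PhaseImage(np.zeros((8, 8)), 0.045)
        assert integrate_dry_mass(img, np.ones((8, 8), bool)) == 0.0

    def test_empty_mask_warns(self):
        img = PhaseImage(np.ones((8, 8)), 0.045)
        with pytest.warns(UserWarning, match="empty mask"):
            assert integrate_dry_mass(img, np.zeros((8, 8), bool)) == 0.0

    def test_rendered_rod_mass_matches_analytic(self):
        """Mass of a rendered spherocylinder = density * analytic volume."""
        rho = 0.2
        cell = CellSpec(3.0, 1.0, rho, position=(4.0, 4.0),
                        orientation=0.4)
        img = render_phase_image([cell], image_shape=(200, 200), noise_sd=0.0)
        m = integrate_dry_mass(img, img.opd > 0, cell.refraction_increment)
        assert m == pytest.approx(rho * spherocylinder_volume(3.0, 1.0),
                                  rel=0.02)

    def test_additive_over_disjoint_masks(self):
        img = PhaseImage(np.random.default_rng(0).uniform(0, 1, (16, 16)), 0.045)
        top = np.zeros((16, 16), bool); top[:8] = True
        m_all = integrate_dry_mass(img, np.ones((16, 16), bool))
        assert (integrate_dry_mass(img, top)
                + integrate_dry_mass(img, ~top)) == pytest.approx(m_all)


class TestVolumeAndDensity:
    def test_sphere_limit(self):
        assert spherocylinder_volume(1.0, 1.0) == pytest.approx(np.pi / 6)

    def test_closed_form(self):
        assert spherocylinder_volume(3.0, 1.0) == pytest.approx(2.0944, abs=1e-4)

    @given(l=st.floats(0.5, 10), w=st.floats(0.1, 5), k=st.floats(1.1, 3))
    @settings(max_examples=50, deadline=None)
    def test_cubic_homogeneity(self, l, w, k):
        if l < w:
            l, w = w, l
        assert spherocylinder_volume(k * l, k * w) == pytest.approx(
            k ** 3 * spherocylinder_volume(l, w), rel=1e-9)

    def test_length_below_width_rejected(self):
        with pytest.raises(ValueError):
            spherocylinder_volume(0.5, 1.0)

    @pytest.mark.parametrize("m,v,rho", [(0.3, 1.5, 0.2), (0.0, 1.0, 0.0)])
    def test_density_ratio(self, m, v, rho):
        assert dry_mass_density(m, v) == pytest.approx(rho)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            dry_mass_density(0.3, 0.0)


class TestPipelineRecovery:
    @pytest.mark.parametrize("rho", [0.13, 0.20, 0.28])
    def test_density_recovered_across_envelope(self, rho):
        """measure_cells recovers the generating density within 5% across
        the observed 0.13-0.28 pg/um^3 range."""
        cell = CellSpec(3.0, 0.9, rho, position=(4.0, 4.0), orientation=0.3)
        img = render_phase_image([cell], image_shape=(200, 200), noise_sd=0.0)
        rec, = measure_cells(img, QpiSettings(segmentation_threshold=0.002))
        assert rec.density_pg_um3 == pytest.approx(rho, rel=0.05)

    def test_tiff_round_trip(self, bead_image, tmp_path):
        path = tmp_path / "bead.tif"
        write_phase_tiff(bead_image, path)
        back = read_phase_tiff(path)
        assert back.pixel_size == bead_image.pixel_size
        np.testing.assert_allclose(back.opd, bead_image.opd, atol=1e-7)


class TestDensityTimecourse:
    def _records(self, densities, cell_id=1):
        return pd.DataFrame({
            "cell_id": cell_id, "t_min": 5.0 * np.arange(len(densities)),
            "density_pg_um3": densities})

    def test_constant_density_cv_zero(self):
        out = density_timecourse(self._records([0.2] * 10))
        assert out.loc[0, "cv"] == 0.0
        assert not out.loc[0, "flagged"]

    def test_noise_cv_recovered(self, rng):
        """3% multiplicative measurement noise shows up as CV ~= 0.03."""
        dens = 0.2 * rng.lognormal(0.0, 0.03, size=2000)
        out = density_timecourse(self._records(dens))
        assert out.loc[0, "cv"] == pytest.approx(0.03, rel=0.15)

    def test_five_hours_at_five_minutes_is_61_rows(self):
        recs = self._records([0.2] * 61)
        assert recs["t_min"].iloc[-1] == 300.0
        assert density_timecourse(recs).loc[0, "n"] == 61

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="2 time points"):
            density_timecourse(self._records([0.2]))


def test_records_to_frame_schema(bead_image):
    recs = measure_cells(bead_image)
    frame = records_to_frame(recs)
    assert list(frame.columns) == ["cell_id", "t_min", "mass_pg", "volume_um3",
                                   "density_pg_um3", "length_um", "width_um"]
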