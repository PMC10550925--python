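"""PLF index arithmetic and invariances, pH calibration, antigen remaining."""

import numpy as np
import pytest

from phagoquant import pipelines, synthetic
from phagoquant.core_io import ImageStack, LabelMask
from phagoquant.fusion import (
    antigen_remaining,
    fit_ph_calibration,
    plf_index,
    ratio_to_ph,
)
from phagoquant.synthetic import PH_BUFFERS, true_ph_ratio


def _plf_scene(fret_val=10.0, green_val=5.0, red_val=1.0):
    """One 10x10 cell, one 20-px phagosome, uniform channels."""
    cell = np.zeros((12, 12), np.int32)
    cell[1:11, 1:11] = 1  # 100 px
    phag = np.zeros((12, 12), np.int32)
    phag[3:7, 3:8] = 1  # 20 px
    mk = lambda v: ImageStack.from_array(np.full((12, 12), float(v)), pixel_size_nm=100)
    return (mk(fret_val), mk(green_val), mk(red_val),
            LabelMask(phag, role="phagosome"), LabelMask(cell, role="cell"))


class TestPlfIndex:
    def test_hand_computed_value(self):
        # mean(FRET/green) = 2 over one phagosome; total red = 100 px x 1
        out = plf_index(*_plf_scene())
        m = out[1]
        assert m.plf_index == pytest.approx(2.0 / 100.0)
        assert m.fret_ratio == pytest.approx(10.0 * 20 / 100.0)
        assert m.phagosome_count == 1

    def test_zero_fret_gives_zero(self):
        out = plf_index(*_plf_scene(fret_val=0.0))
        assert out[1].plf_index == 0.0

    def test_joint_fret_red_scaling_invariance(self):
        a = plf_index(*_plf_scene())[1].plf_index
        b = plf_index(*_plf_scene(fret_val=10.0 * 7, red_val=1.0 * 7))[1].plf_index
        assert a == pytest.approx(b)

    def test_green_gain_scales_inversely(self):
        a = plf_index(*_plf_scene(green_val=5.0))[1].plf_index
        b = plf_index(*_plf_scene(green_val=10.0))[1].plf_index
        assert b == pytest.approx(a / 2.0)

    def test_no_phagosome_flagged_not_zero(self):
        fret, green, red, _, cell = _plf_scene()
        empty = LabelMask(np.zeros((12, 12), np.int32), role="phagosome")
        m = plf_index(fret, green, red, empty, cell)[1]
        assert np.isnan(m.plf_index)
        assert m.flagged

    def test_zero_green_pixels_excluded_and_reported(self):
        fret, green, red, phag, cell = _plf_scene()
        g = green.data.copy()
        g[..., 3:5, 3:8] = 0.0  # half the phagosome pixels
        m = plf_index(fret, green.with_data(g), red, phag, cell)[1]
        assert m.excluded_pixel_fraction == pytest.approx(0.5)
        assert m.plf_index == pytest.approx(2.0 / 100.0)

    def test_knockdown_contrast_recovered(self):
        a = pipelines.run_plf(synthetic.preset("shCTR", 41), 15)
        b = pipelines.run_plf(synthetic.preset("shSec22b", 42), 15)
        assert b.mean() / a.mean() == pytest.approx(1.5, rel=0.10)


class TestPhCalibration:
    def _images(self, ratios_by_ph, size=8):
        out = {}
        for ph, r in ratios_by_ph.items():
            den = np.full((size, size), 100.0)
            num = r * den
            mk = lambda a: ImageStack.from_array(a, pixel_size_nm=160)
            out[ph] = [(mk(num), mk(den))]
        return out

    def test_parameters_recovered_from_known_curve(self):
        images = self._images({ph: float(true_ph_ratio(ph)) for ph in PH_BUFFERS})
        cal = fit_ph_calibration(images)
        assert cal.pKa == pytest.approx(6.3, abs=1e-3)
        assert cal.slope == pytest.approx(0.8, abs=1e-3)
        assert cal.A1 == pytest.approx(0.3, abs=2e-3)
        assert cal.A2 == pytest.approx(2.0, abs=2e-3)
        assert cal.ascending

    def test_round_trip_at_buffer_points(self):
        images = self._images({ph: float(true_ph_ratio(ph)) for ph in PH_BUFFERS})
        cal = fit_ph_calibration(images)
        for ph in PH_BUFFERS:
            assert ratio_to_ph(cal.ratio_at(ph), cal) == pytest.approx(ph, abs=0.1)

    def test_monotone_inverse(self):
        images = self._images({ph: float(true_ph_ratio(ph)) for ph in PH_BUFFERS})
        cal = fit_ph_calibration(images)
        assert ratio_to_ph(1.5, cal) > ratio_to_ph(0.8, cal)

    def test_out_of_range_ratio_clamped_with_warning(self):
        images = self._images({ph: float(true_ph_ratio(ph)) for ph in PH_BUFFERS})
        cal = fit_ph_calibration(images)
        with pytest.warns(UserWarning):
            ph = ratio_to_ph(99.0, cal)
        assert ph == pytest.approx(cal.valid_range[1])

    def test_too_few_buffers_rejected(self):
        images = self._images({4.0: 0.4, 9.0: 1.9})
        with pytest.raises(ValueError):
            fit_ph_calibration(images)

    def test_constant_ratios_rejected(self):
        images = self._images({ph: 1.0 for ph in PH_BUFFERS})
        with pytest.raises(ValueError):
            fit_ph_calibration(images)

    def test_generated_phagosome_ph_recovered(self):
        assert pipelines.run_ph(synthetic.preset("shCTR", 51)) == pytest.approx(6.0, abs=0.15)


class TestAntigenRemaining:
    def _scene(self, ing_val, free_val):
        img = np.zeros((16, 32))
        img[4:12, 4:12] = ing_val
        img[4:12, 20:28] = free_val
        ing = np.zeros((16, 32), np.int32)
        ing[4:12, 4:12] = 1
        free = np.zeros((16, 32), np.int32)
        free[4:12, 20:28] = 1
        return (ImageStack.from_array(img, pixel_size_nm=100),
                LabelMask(ing, role="bead_ingested"), LabelMask(free, role="bead_free"))

    def test_equal_intensities_are_hundred_percent(self):
        out = antigen_remaining(*self._scene(100.0, 100.0))
        assert out[1] == pytest.approx(100.0)

    def test_half_intensity_is_fifty_percent(self):
        out = antigen_remaining(*self._scene(50.0, 100.0))
        assert out[1] == pytest.approx(50.0)

    def test_illumination_scaling_invariance(self):
        img, ing, free = self._scene(50.0, 100.0)
        a = antigen_remaining(img, ing, free)[1]
        b = antigen_remaining(img.with_data(img.data * 4.2), ing, free)[1]
        assert a == pytest.approx(b)

    def test_zero_free_mean_raises(self):
        with pytest.raises(ValueError):
            antigen_remaining(*self._scene(50.0, 0.0))

    def test_knockdown_lowers_percent_remaining(self):
        a = pipelines.run_antigen(synthetic.preset("shCTR", 61))
        b = pipelines.run_antigen(synthetic.preset("shSec22b", 62))
        assert a.mean() == pytest.approx(65.0, rel=0.05)
        assert b.mean() == pytest.approx(45.0, rel=0.05)
        assert b.mean() < a.mean()
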