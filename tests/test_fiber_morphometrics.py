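"""Fiber detection and the MBP / fiber score algebra against planted geometry."""

import numpy as np
import pytest

from myeliscreen import (
    FiberParams,
    FormatError,
    UndefinedScoreError,
    compute_fiber_score,
    compute_mbp_score,
    detect_fibers,
    score_differentiation_field,
    score_field,
    threshold_mbp,
)
from myeliscreen.fiber_morphometrics import Fiber, MBPMask
from myeliscreen.synthdata import FieldSpec, render_field, render_single_fiber


class TestThresholdMBP:
    @pytest.mark.parametrize("method", ["otsu", "fixed:10", "quantile:0.9"])
    def test_zero_raster_any_method(self, method):
        m = threshold_mbp(np.zeros((64, 64)), method)
        assert m.area_px == 0 and m.mean_intensity_in_mask == 0.0

    def test_fixed_threshold_block(self):
        img = np.zeros((64, 64))
        img[10:20, 10:20] = 1000.0
        m = threshold_mbp(img, "fixed:500")
        assert m.area_px == 100 and m.mean_intensity_in_mask == 1000.0
        assert m.threshold_value == 500.0

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.3, 2.0])
    def test_quantile_out_of_range_rejected(self, q):
        with pytest.raises(FormatError):
            threshold_mbp(np.ones((8, 8)), f"quantile:{q}")

    def test_noiseless_mask_area_near_planted_footprint(self):
        spec = FieldSpec(background_level=0.0, noise_sd=0.0)
        img, truth = render_field(spec, seed=5)
        m = threshold_mbp(img.channels["MBP"].astype(float), "fixed:0")
        assert abs(m.area_px - truth.mbp_footprint_area) / truth.mbp_footprint_area <= 0.10


class TestMBPScore:
    def test_formula(self):
        mask = MBPMask(np.ones((10, 10), bool), 0.0, 100, 1000.0)
        assert compute_mbp_score(mask, 4) == 25000.0
        assert compute_mbp_score(mask, 8) == 12500.0  # doubling N halves the score

    def test_empty_mask_scores_zero(self):
        mask = MBPMask(np.zeros((10, 10), bool), 0.0, 0, 0.0)
        assert compute_mbp_score(mask, 5) == 0.0

    def test_zero_cells_is_undefined(self):
        mask = MBPMask(np.ones((4, 4), bool), 0.0, 16, 10.0)
        with pytest.raises(UndefinedScoreError):
            compute_mbp_score(mask, 0)


class TestDetectFibers:
    def test_blank_field_yields_none(self):
        img = np.zeros((64, 64))
        assert detect_fibers(img, threshold_mbp(img, "otsu")) == []

    def test_single_straight_fiber_recovered(self):
        img, _ = render_single_fiber(length=100.0, intensity=1000.0)
        fibers = detect_fibers(img, threshold_mbp(img, "fixed:100"))
        assert len(fibers) == 1
        f = fibers[0]
        assert 90.0 <= f.path_length_px <= 110.0
        assert f.straightness >= 0.98
        assert f.mean_intensity == pytest.approx(1000.0, rel=0.02)

    @pytest.mark.parametrize("angle", [0, 30, 45, 60, 90])
    def test_length_recovery_across_orientations(self, angle):
        img, _ = render_single_fiber(angle_deg=angle, length=100.0)
        fibers = detect_fibers(img, threshold_mbp(img, "fixed:100"))
        assert len(fibers) == 1
        assert abs(fibers[0].path_length_px - 100.0) / 100.0 <= 0.10

    def test_diffuse_blob_rejected(self):
        """A disc (diffuse OL morphology) must not register as a fiber."""
        spec = FieldSpec(
            image_shape=(256, 256), n_nuclei_total=5, frac_olig2=1.0, n_ol_diffuse=1,
            n_ol_fibrous=0, diffuse_blob_radius_px=20.0, background_level=0.0, noise_sd=0.0,
        )
        img, _ = render_field(spec, seed=2)
        mbp = img.channels["MBP"].astype(float)
        assert detect_fibers(mbp, threshold_mbp(mbp, "otsu")) == []

    def test_separated_fibers_counted_exactly(self):
        """Parallel fibers >= 10 px apart are each recovered once (noiseless)."""
        img = np.zeros((200, 200))
        for k in range(3):
            fiber_img, _ = render_single_fiber(
                shape=(200, 200), start=(60.0 + 15 * k, 40.0), angle_deg=0.0, length=120.0
            )
            img = np.maximum(img, fiber_img)
        fibers = detect_fibers(img, threshold_mbp(img, "fixed:100"))
        assert len(fibers) == 3


class TestFiberScore:
    def _fiber(self, length=100.0, intensity=1000.0):
        return Fiber([(0, 0)], length, length, 1.0, intensity)

    def test_formula_and_additivity(self):
        one = [self._fiber()]
        two = [self._fiber(), self._fiber()]
        assert compute_fiber_score(one, 10) == 10000.0
        assert compute_fiber_score(two, 10) == 2 * compute_fiber_score(one, 10)
        assert compute_fiber_score([], 5) == 0.0

    def test_length_only_mode(self):
        fibers = [self._fiber(length=80.0, intensity=500.0)]
        assert compute_fiber_score(fibers, 4, "length_only") == 20.0

    def test_zero_olig2_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            compute_fiber_score([self._fiber()], 0)


class TestIntensityCovariance:
    def test_scores_scale_with_intensity_but_quotient_invariant(self):
        """x c on the raster scales both scores by c; fiber/MBP is unchanged."""
        spec = FieldSpec(
            image_shape=(256, 256), n_nuclei_total=40, n_ol_diffuse=2, n_ol_fibrous=3,
            fiber_intensity=800.0, diffuse_intensity=400.0,
            background_level=0.0, noise_sd=0.0,
        )
        img, _ = render_field(spec, seed=11)
        mbp = img.channels["MBP"].astype(float)
        c = 4.0

        def scores(raster, thr):
            mask = threshold_mbp(raster, f"fixed:{thr}")
            ms = compute_mbp_score(mask, 5)
            fibers = detect_fibers(raster, mask)
            fs = compute_fiber_score(fibers, 5)
            return ms, fs

        ms1, fs1 = scores(mbp, 50.0)
        ms2, fs2 = scores(mbp * c, 50.0 * c)
        assert ms2 == pytest.approx(c * ms1, rel=0.01)
        assert fs2 == pytest.approx(c * fs1, rel=0.01)
        assert fs2 / ms2 == pytest.approx(fs1 / ms1, rel=0.01)


class TestScoreField:
    def test_field_without_ols_is_unusable(self):
        spec = FieldSpec(n_nuclei_total=30, frac_olig2=0.0, n_ol_diffuse=0, n_ol_fibrous=0)
        img, _ = render_field(spec, seed=3)
        fs = score_field(img)
        assert fs.usable is False and fs.fiber_score is None

    def test_fibrous_field_outranks_diffuse_on_quotient(self):
        """Same OL count, fibrous vs diffuse MBP: the quotient separates them."""
        common = dict(image_shape=(512, 512), n_nuclei_total=150)
        img_f, _ = render_field(FieldSpec(n_ol_diffuse=0, n_ol_fibrous=14, **common), seed=5)
        img_d, _ = render_field(FieldSpec(n_ol_diffuse=14, n_ol_fibrous=0, **common), seed=5)
        sf, sd = score_field(img_f), score_field(img_d)
        assert sf.fiber_mbp > sd.fiber_mbp

    def test_diffuse_only_fiber_score_near_zero(self):
        common = dict(image_shape=(512, 512), n_nuclei_total=150)
        img_f, _ = render_field(FieldSpec(n_ol_diffuse=0, n_ol_fibrous=14, **common), seed=5)
        img_d, _ = render_field(FieldSpec(n_ol_diffuse=14, n_ol_fibrous=0, **common), seed=5)
        sf, sd = score_field(img_f), score_field(img_d)
        assert sd.fiber_score <= 0.05 * sf.fiber_score

    def test_recovers_ground_truth_scores_within_15pct(self, default_field):
        img, truth = default_field
        fs = score_field(img)
        assert fs.usable
        assert fs.mbp_score == pytest.approx(truth.expected_mbp_score, rel=0.15)
        assert fs.fiber_score == pytest.approx(truth.expected_fiber_score, rel=0.15)


class TestDifferentiationScore:
    def test_rendered_differentiation_field_recovered(self):
        """Purified-OPC mode: MBP score over DAPI nuclei, no Olig2 channel needed."""
        spec = FieldSpec(
            n_nuclei_total=60, frac_olig2=1.0, n_ol_diffuse=20, n_ol_fibrous=0,
        )
        img, truth = render_field(spec, seed=13)
        score = score_differentiation_field(img)
        expected = truth.expected_mbp_score * truth.n_olig2 / spec.n_nuclei_total
        assert score == pytest.approx(expected, rel=0.15)

    def test_blank_mbp_scores_zero(self):
        spec = FieldSpec(n_nuclei_total=30, n_ol_diffuse=0, n_ol_fibrous=0,
                         noise_sd=0.0, background_level=0.0)
        img, _ = render_field(spec, seed=3)
        assert score_differentiation_field(img) == 0.0
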