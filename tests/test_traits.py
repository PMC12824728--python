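import math

import numpy as np
import pytest

from rootfringe import (
    CalibrationConfig,
    DegenerateRootError,
    InputError,
    LabeledMask,
    RawImage,
    geometry,
    synthetic,
    traits,
)
from rootfringe.synthetic import ConstantProfile, SyntheticRootSpec


class TestBinProfile:
    def test_constant_fringe_measures_constant_rhl(self, straight_constant_scene, cal):
        prof = traits.bin_profile(straight_constant_scene, cal)
        expected = 30 / cal.conv
        assert np.allclose(prof.rhl_left, expected, atol=1.5 / cal.conv)
        assert np.allclose(prof.rhl_right, expected, atol=1.5 / cal.conv)

    def test_hairless_root_measures_zero(self, cal):
        spec = SyntheticRootSpec(
            image_height=300, image_width=120, tip_row=280,
            hair_profile_left=ConstantProfile(0),
            hair_profile_right=ConstantProfile(0),
        )
        _, mask, _ = synthetic.generate(spec, conv=cal.conv)
        scene = geometry.normalize(mask, cal)
        prof = traits.bin_profile(scene, cal)
        assert (prof.rhl_left == 0).all() and (prof.rha_right == 0).all()

    def test_binned_area_partitions_hair_mask_exactly(self, straight_constant_scene, cal):
        prof = traits.bin_profile(straight_constant_scene, cal)
        retained = int(
            straight_constant_scene.left_hair.sum()
            + straight_constant_scene.right_hair.sum()
        )
        assert int(prof.hair_px_left.sum() + prof.hair_px_right.sum()) == retained
        total_rha = prof.rha_left.sum() + prof.rha_right.sum()
        assert total_rha * cal.conv**2 == pytest.approx(retained, abs=1e-6)

    def test_bin_spacing_is_resolution_over_conv(self, straight_constant_scene, cal):
        prof = traits.bin_profile(straight_constant_scene, cal)
        assert np.allclose(np.diff(prof.distance_mm), cal.bin_mm)


class TestElongationZone:
    def test_ramp_recovers_closed_form(self, ramp_profile_measured, cal):
        _, prof = ramp_profile_measured
        ez = traits.elongation_zone(prof.mean_rhl_series(), prof.distance_mm, cal)
        assert ez.start == pytest.approx(0.0, abs=cal.bin_mm)
        assert ez.end == pytest.approx(500 / cal.conv, abs=1.5 * cal.bin_mm)
        assert ez.gradient == pytest.approx(0.2, rel=0.10)
        assert ez.distance == pytest.approx(ez.end - ez.start)

    def test_flat_profile_has_empty_zone(self, cal):
        y = np.full(30, 0.5)
        x = (np.arange(30) + 0.5) * cal.bin_mm
        ez = traits.elongation_zone(y, x, cal)
        assert ez.distance == 0.0 and math.isnan(ez.gradient)

    def test_monotone_profile_spans_whole_root(self, cal):
        x = (np.arange(40) + 0.5) * cal.bin_mm
        y = 0.05 * x  # rises ~2 px per bin, above the quantisation floor
        ez = traits.elongation_zone(y, x, cal)
        assert ez.start == pytest.approx(x[0])
        assert ez.end == pytest.approx(x[-1])

    def test_too_few_bins_rejected(self, cal):
        with pytest.raises(DegenerateRootError):
            traits.elongation_zone(np.ones(4), np.arange(4) + 0.5, cal)


class TestHeterogeneity:
    def test_symmetric_profile_has_zero_delta(self, straight_constant_scene, cal):
        prof = traits.bin_profile(straight_constant_scene, cal)
        d_rhl, _, d_rha, _ = traits.heterogeneity(prof)
        assert d_rhl == 0.0 and d_rha == 0.0

    def test_matches_exhaustive_scan(self, cal):
        rng = np.random.default_rng(7)
        n = 25
        prof = traits.BinProfile(
            name="r",
            distance_mm=(np.arange(n) + 0.5) * cal.bin_mm,
            rhl_left=rng.uniform(0, 1, n),
            rhl_right=rng.uniform(0, 1, n),
            rha_left=rng.uniform(0, 0.1, n),
            rha_right=rng.uniform(0, 0.1, n),
            root_width_mm=np.full(n, 0.2),
            hair_px_left=np.zeros(n, int),
            hair_px_right=np.zeros(n, int),
        )
        d_rhl, p_rhl, d_rha, p_rha = traits.heterogeneity(prof)
        # brute-force oracle
        best_l = max(range(n), key=lambda i: abs(prof.rhl_left[i] - prof.rhl_right[i]))
        best_a = max(range(n), key=lambda i: abs(prof.rha_left[i] - prof.rha_right[i]))
        assert d_rhl == abs(prof.rhl_left[best_l] - prof.rhl_right[best_l])
        assert p_rhl == prof.distance_mm[best_l]
        assert d_rha == abs(prof.rha_left[best_a] - prof.rha_right[best_a])
        assert p_rha == prof.distance_mm[best_a]


class TestRootMetrics:
    def test_rectangular_root_arithmetic(self):
        cal = CalibrationConfig(conv=102.0, resolution=20)
        spec = SyntheticRootSpec(
            image_height=540, image_width=140, root_width=21,
            top_row=10, tip_row=519,
            hair_profile_left=ConstantProfile(10),
            hair_profile_right=ConstantProfile(10),
        )
        _, mask, _ = synthetic.generate(spec, conv=cal.conv)
        scene = geometry.normalize(mask, cal)
        thickness, length = traits.root_metrics(scene, cal)
        assert thickness == pytest.approx(21 / 102.0, abs=0.5 / cal.conv)
        assert length == pytest.approx(510 / 102.0, abs=2 / cal.conv)

    def test_tapered_root_thickness_matches_analytic_mean(self):
        # hand-built linear taper 31 -> 11 px over 400 rows: mean width 21 px
        cal = CalibrationConfig(conv=102.0, resolution=20)
        lab = np.zeros((420, 120), dtype=np.uint8)
        centre = 60
        for i, r in enumerate(range(10, 410)):
            half = int(round((31 - 20 * i / 399) // 2))
            lab[r, centre - half : centre + half + 1] = 2
        scene = geometry.normalize(LabeledMask(lab), cal)
        thickness, _ = traits.root_metrics(scene, cal)
        assert thickness == pytest.approx(21 / 102.0, abs=1.0 / cal.conv)


class TestDensityProxy:
    def _pair(self, hair_val, bg_val):
        lab = np.zeros((10, 10), dtype=np.uint8)
        lab[:5] = 1
        lab[5:8] = 2
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        px[:5] = hair_val
        px[5:8] = 50
        px[8:] = bg_val
        return RawImage(px), LabeledMask(lab)

    def test_exact_ratio(self):
        image, mask = self._pair(100, 200)
        h, b, r = traits.density_proxy(image, mask)
        assert (h, b, r) == (100.0, 200.0, 0.5)

    def test_uniform_intensity_gives_unit_ratio(self):
        image, mask = self._pair(130, 130)
        assert traits.density_proxy(image, mask)[2] == 1.0

    def test_missing_image_yields_missing_values(self):
        _, mask = self._pair(1, 2)
        assert all(math.isnan(v) for v in traits.density_proxy(None, mask))

    def test_denser_filaments_lower_the_ratio(self):
        sparse = synthetic.preset("filament-sparse")
        dense = synthetic.preset("filament-dense")
        i1, m1, _ = synthetic.generate(sparse)
        i2, m2, _ = synthetic.generate(dense)
        assert traits.density_proxy(i2, m2)[2] < traits.density_proxy(i1, m1)[2]


class TestSummarize:
    def test_constant_profile_collapses_order_statistics(self, straight_constant_scene, cal):
        prof = traits.bin_profile(straight_constant_scene, cal)
        s = traits.summarize(prof, cal, name="t")
        assert s.min_rhl <= s.mean_rhl <= s.max_rhl
        assert s.max_rhl - s.min_rhl <= 2 / cal.conv

    def test_cutoff_equals_bruteforce_recomputation(self, ramp_profile_measured):
        _, prof = ramp_profile_measured
        cal = CalibrationConfig(conv=102.0, resolution=20, length_cutoff=10.0)
        s = traits.summarize(prof, cal, name="t")
        keep = prof.distance_mm <= 10.0
        both = np.concatenate([prof.rhl_left[keep], prof.rhl_right[keep]])
        assert s.mean_rhl == pytest.approx(both.mean())
        assert s.max_rhl == pytest.approx(both.max())
        assert s.min_rhl == pytest.approx(both.min())
        assert s.total_rha == pytest.approx(
            prof.rha_left[keep].sum() + prof.rha_right[keep].sum()
        )

    def test_total_rha_monotone_in_cutoff(self, ramp_profile_measured):
        _, prof = ramp_profile_measured
        totals = []
        for cutoff in (4.0, 7.0, 10.0, None):
            cal = CalibrationConfig(conv=102.0, resolution=20, length_cutoff=cutoff)
            totals.append(traits.summarize(prof, cal).total_rha)
        assert totals == sorted(totals)

    def test_cutoff_smaller_than_bin_rejected(self, ramp_profile_measured):
        _, prof = ramp_profile_measured
        cal = CalibrationConfig(conv=102.0, resolution=20, length_cutoff=0.05)
        with pytest.raises(DegenerateRootError):
            traits.summarize(prof, cal)

    def test_scale_equivariance_in_conv(self, straight_constant_scene):
        cal1 = CalibrationConfig(conv=100.0, resolution=20)
        cal2 = CalibrationConfig(conv=200.0, resolution=20)
        p1 = traits.bin_profile(straight_constant_scene, cal1)
        p2 = traits.bin_profile(straight_constant_scene, cal2)
        assert np.allclose(p2.rhl_left * 2, p1.rhl_left)
        assert np.allclose(p2.rha_left * 4, p1.rha_left)
        s1 = traits.summarize(p1, cal1)
        s2 = traits.summarize(p2, cal2)
        assert s2.mean_rhl * 2 == pytest.approx(s1.mean_rhl)
        assert s2.total_rha * 4 == pytest.approx(s1.total_rha)
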