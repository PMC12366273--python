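"""Vessel-network and lipid morphometry against synthetic ground truth."""

import numpy as np
import pytest

import gradientchip as gc
from gradientchip.synthetic import NetworkSpec, _render_tubes


PX = 4.0  # um/px for hand-built masks


def _frame(arr, px=PX):
    return gc.ImageFrame(np.asarray(arr, dtype=np.uint8), px)


def _tube_image(shape=(100, 200), row=50, half_width=4, lo=30, hi=220):
    img = np.full(shape, lo, dtype=np.uint8)
    img[row - half_width:row + half_width, 10:-10] = hi
    return img


class TestBinarizeVessels:
    def test_uniform_background_empty(self):
        mask = gc.binarize_vessels(_frame(np.full((64, 64), 50)))
        assert not mask.any()

    def test_small_particle_removed(self):
        img = np.full((64, 64), 30, dtype=np.uint8)
        img[30:33, 30:33] = 220  # 9 px = 144 um^2 < 500 um^2 default
        mask = gc.binarize_vessels(_frame(img), intensity_threshold=100)
        assert not mask.any()

    def test_interior_speck_filled(self):
        img = _tube_image()
        img[50, 100] = 30  # 1 px dark speck, 16 um^2 < 100 um^2
        mask = gc.binarize_vessels(_frame(img), intensity_threshold=100)
        assert mask[50, 100]

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gc.binarize_vessels(_frame(_tube_image()), intensity_threshold=300)


class TestVesselMetrics:
    def test_straight_tube_topology(self):
        mask = gc.binarize_vessels(_frame(_tube_image()), intensity_threshold=100)
        m = gc.vessel_metrics(mask, PX)
        assert m.n_junctions == 0
        assert m.n_endpoints == 2
        assert m.total_area == pytest.approx(mask.sum() * (PX / 1000) ** 2)

    def test_plus_sign_topology(self):
        img = np.full((101, 101), 30, dtype=np.uint8)
        img[47:54, 10:91] = 220
        img[10:91, 47:54] = 220
        mask = gc.binarize_vessels(_frame(img), intensity_threshold=100)
        m = gc.vessel_metrics(mask, PX)
        assert m.n_junctions == 1
        assert m.n_endpoints == 4

    def test_empty_mask_zeroes(self):
        m = gc.vessel_metrics(np.zeros((10, 10), bool), PX)
        assert (m.n_junctions, m.n_endpoints, m.total_length, m.total_area) == \
            (0, 0, 0.0, 0.0)

    @pytest.mark.parametrize("seed", [0, 7, 21])
    def test_synthetic_network_ground_truth(self, seed):
        """Counts recover the generating graph exactly; length within 5%."""
        frame, truth = gc.generate_network_image(NetworkSpec(seed=seed))
        mask = gc.binarize_vessels(frame)
        m = gc.vessel_metrics(mask, frame.pixel_size)
        assert m.n_junctions == truth.n_junctions
        assert m.n_endpoints == truth.n_endpoints
        assert m.total_length == pytest.approx(truth.geometric_length_mm, rel=0.05)

    def test_translation_and_rotation_invariance(self):
        frame, _ = gc.generate_network_image(NetworkSpec(seed=3))
        mask = gc.binarize_vessels(frame)
        base = gc.vessel_metrics(mask, frame.pixel_size)
        shifted = np.roll(np.pad(mask, 16), 9, axis=1)
        rotated = mask[::-1, ::-1]
        for variant in (shifted, rotated):
            m = gc.vessel_metrics(variant, frame.pixel_size)
            assert m.n_junctions == base.n_junctions
            assert m.n_endpoints == base.n_endpoints
            assert m.total_length == pytest.approx(base.total_length, rel=0.01)

    def test_resolution_doubling_stable(self):
        """Twice the sampling leaves counts unchanged, length within 3%."""
        results = {}
        for px in (4.0, 2.0):
            spec = NetworkSpec(seed=5, pixel_size=px, noise_sigma=2.0,
                               salt_pepper_fraction=0.0)
            frame, truth = gc.generate_network_image(spec)
            mask = gc.binarize_vessels(frame)
            results[px] = (gc.vessel_metrics(mask, px), truth)
        m4, t4 = results[4.0]
        m2, t2 = results[2.0]
        assert t4.edges == t2.edges  # same generating graph
        assert m4.n_junctions == m2.n_junctions
        assert m4.n_endpoints == m2.n_endpoints
        assert m4.total_length == pytest.approx(m2.total_length, rel=0.03)

    def test_area_bounds_length_times_width(self):
        spec = NetworkSpec(seed=11)
        frame, truth = gc.generate_network_image(spec)
        mask = gc.binarize_vessels(frame)
        m = gc.vessel_metrics(mask, frame.pixel_size)
        min_width_mm = min(truth.tube_widths_um) / 1000.0
        assert m.total_area >= m.total_length * min_width_mm * 0.9


class TestVesselDiameter:
    def _tube_mask(self, width_px, shape=(60, 200), row=30):
        mask = np.zeros(shape, dtype=bool)
        half = width_px / 2
        lo = int(np.ceil(row - half))
        mask[lo:lo + width_px, 10:-10] = True
        return mask

    @pytest.mark.parametrize("width_px", [5, 9, 13])
    def test_known_width_within_one_pixel(self, width_px):
        mask = self._tube_mask(width_px)
        mean, _ = gc.vessel_diameter(mask, PX)
        assert abs(mean - width_px * PX) <= PX

    def test_two_tubes_average(self):
        mask = np.zeros((120, 200), dtype=bool)
        mask[20:26, 10:-10] = True    # 6 px wide
        mask[80:92, 10:-10] = True    # 12 px wide
        mean, _ = gc.vessel_diameter(mask, PX)
        assert mean == pytest.approx(0.5 * (6 + 12) * PX, abs=1.5 * PX)

    def test_single_pixel_line(self):
        mask = np.zeros((20, 60), dtype=bool)
        mask[10, 5:-5] = True
        mean, _ = gc.vessel_diameter(mask, PX)
        assert abs(mean - PX) <= PX

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            gc.vessel_diameter(np.zeros((5, 5), bool), PX)


class TestTimeseries:
    def _stack(self, n, shape=(40, 40)):
        img = _tube_image(shape=shape, row=20, half_width=3)
        return [gc.ImageFrame(img, PX, timestamp=600.0 * i) for i in range(n)]

    def test_truncate_matches_reported_count(self):
        """478 frames at every tenth give 47 analyzed frames by default."""
        out = gc.timeseries_metrics(self._stack(478), 10,
                                    intensity_threshold=100)
        assert len(out) == 47

    def test_inclusive_mode_gives_48(self):
        out = gc.timeseries_metrics(self._stack(478), 10,
                                    endpoint_mode="inclusive",
                                    intensity_threshold=100)
        assert len(out) == 48

    def test_subsample_one_analyzes_all(self):
        out = gc.timeseries_metrics(self._stack(7), 1, intensity_threshold=100)
        assert len(out) == 7

    def test_constant_stack_constant_metrics(self):
        out = gc.timeseries_metrics(self._stack(6), 2, intensity_threshold=100)
        metrics = [m for _, m in out]
        assert all(m == metrics[0] for m in metrics)
        assert [f.timestamp for f, _ in out] == [0.0, 1200.0, 2400.0]

    def test_empty_stack_raises(self):
        with pytest.raises(ValueError):
            gc.timeseries_metrics([], 10)


class TestLipidCoverage:
    def test_bright_roi_is_zero(self):
        prof = gc.lipid_coverage(_frame(np.full((64, 64), 230), px=2.0))
        assert prof.whole == 0.0

    def test_dark_roi_is_full(self):
        prof = gc.lipid_coverage(_frame(np.full((64, 64), 40), px=2.0))
        assert prof.whole == 100.0

    def test_synthetic_droplets_recover_truth(self):
        frame, truth = gc.generate_lipid_image(30.0, seed=1)
        prof = gc.lipid_coverage(frame)
        assert prof.whole == pytest.approx(truth.droplet_fraction_pct, abs=2.0)

    def test_thirds_weighted_mean_equals_whole(self):
        frame, _ = gc.generate_lipid_image(25.0, seed=2)
        prof = gc.lipid_coverage(frame)
        ncols = frame.pixels.shape[1]
        edges = [round(i * ncols / 3) for i in range(4)]
        weights = np.diff(edges) / ncols
        assert np.dot(prof.thirds, weights) == pytest.approx(prof.whole, abs=1e-6)

    def test_bins_span_roi(self):
        frame, _ = gc.generate_lipid_image(10.0, seed=3)
        prof = gc.lipid_coverage(frame)
        bin_px = round(prof.bin_width / frame.pixel_size)
        assert len(prof.bins) == int(np.ceil(frame.pixels.shape[1] / bin_px))

    def test_roi_outside_image_raises(self):
        with pytest.raises(ValueError):
            gc.lipid_coverage(_frame(np.full((64, 64), 230), px=2.0),
                              roi=(0, 0, 65, 64))


def test_rendered_mask_matches_generator_mask():
    """Segmentation of a clean render reproduces the generator's tube mask."""
    spec = NetworkSpec(seed=9, noise_sigma=0.0, salt_pepper_fraction=0.0,
                       blur_sigma_px=0.8)
    frame, truth = gc.generate_network_image(spec)
    mask = gc.binarize_vessels(frame)
    assert mask.mean() == pytest.approx(
        truth.rendered_area_mm2 / (spec.domain_um / 1000.0) ** 2, rel=0.1)
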