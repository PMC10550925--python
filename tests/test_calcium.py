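"""Fura-2 SOCE metrics and Fluo-8 hotspot detection."""

import numpy as np
import pytest

from phagoquant.calcium import (
    RatioTrace,
    detect_hotspots,
    fura_ratio,
    phagocytic_index,
    soce_metrics,
)
from phagoquant.core_io import ImageStack, LabelMask
from phagoquant import synthetic
from oracle_utils import brute_force_components_with_area, min_dist_to_mask_px


def disk_mask(shape, cy, cx, r, label=1):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    m = np.zeros(shape, dtype=np.int32)
    m[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = label
    return m


class TestFuraRatio:
    def _stacks(self, f380_data):
        f380 = ImageStack.from_array(f380_data, pixel_size_nm=160, frame_interval_s=3)
        f340 = f380.with_data(2.0 * f380.data)
        return f340, f380

    def test_ratio_two(self, rng):
        f340, f380 = self._stacks(rng.uniform(50, 150, (4, 16, 16)))
        cell = LabelMask(disk_mask((16, 16), 8, 8, 6), role="cell")
        traces = fura_ratio(f340, f380, cell)
        np.testing.assert_allclose(traces[1].ratio, 2.0)

    def test_mask_isolation(self, rng):
        data = rng.uniform(50, 150, (3, 16, 16))
        f340, f380 = self._stacks(data)
        cell = LabelMask(disk_mask((16, 16), 8, 8, 5), role="cell")
        r1 = fura_ratio(f340, f380, cell)[1].ratio
        # corrupt everything outside the cell
        outside = ~cell.foreground
        d2 = data.copy()
        d2[:, outside] = 9999.0
        f340b, f380b = self._stacks(d2)
        f340b = f340b.with_data(f340.data.copy())
        f340b.data[0, :, 0][:, outside] = 1.0
        r2 = fura_ratio(f340b, f380b, cell)[1].ratio
        np.testing.assert_allclose(r1, r2)

    def test_zero_denominator_flagged(self):
        f380 = ImageStack.from_array(np.zeros((2, 8, 8)), pixel_size_nm=160)
        f340 = f380.with_data(np.ones_like(f380.data))
        cell = LabelMask(np.ones((8, 8), np.int32), role="cell")
        tr = fura_ratio(f340, f380, cell)[1]
        assert not tr.valid.any()
        assert np.isnan(tr.ratio).all()


class TestSoceMetrics:
    def test_constant_trace(self):
        t = np.arange(0, 300, 3.0)
        tr = RatioTrace(t, np.full_like(t, 0.8), readd_time_s=150.0)
        slope, amp = soce_metrics(tr, baseline_window_s=60)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert amp == pytest.approx(0.0, abs=1e-12)

    def test_ramp_to_plateau(self):
        t = np.arange(0, 600, 3.0)
        r = np.full_like(t, 0.6)
        post = t >= 300
        r[post] = 0.6 + np.minimum(0.01 * (t[post] - 300), 0.8)
        tr = RatioTrace(t, r, readd_time_s=300.0)
        slope, amp = soce_metrics(tr, baseline_window_s=60)
        assert slope == pytest.approx(0.01, rel=1e-6)
        assert amp == pytest.approx(0.8, rel=1e-6)

    def test_amplitude_invariant_to_offset(self):
        t = np.arange(0, 600, 3.0)
        r = 0.6 + 0.5 / (1 + np.exp((400 - t) / 20))
        a = soce_metrics(RatioTrace(t, r, 300.0), 60)[1]
        b = soce_metrics(RatioTrace(t, r + 3.3, 300.0), 60)[1]
        assert a == pytest.approx(b)

    def test_too_few_post_points_raises(self):
        t = np.arange(0, 30, 3.0)
        with pytest.raises(ValueError):
            soce_metrics(RatioTrace(t, np.ones_like(t), readd_time_s=27.0), 9)

    def test_generated_traces_recover_configured_step(self):
        cfg = synthetic.preset("shCTR", 13)
        traces, gt = synthetic.gen_fura_traces(cfg, 10)
        peaks = gt.values("soce_peak")
        for tr, true_peak in zip(traces, peaks):
            slope, amp = soce_metrics(tr, baseline_window_s=60)
            assert amp == pytest.approx(true_peak, rel=0.05)
            # the 5-point window attenuates the instantaneous initial slope
            assert 0.5 * true_peak / 20.0 < slope <= 1.05 * true_peak / 20.0


class TestDetectHotspots:
    def _scene(self, blocks=(), mu=100.0, sd=5.0, seed=0):
        rng = np.random.default_rng(seed)
        img = mu + rng.normal(0, sd, (48, 48))
        for y, x, amp in blocks:
            img[y : y + 2, x : x + 2] += amp
        phag = LabelMask(disk_mask((48, 48), 24, 24, 6), role="phagosome")
        cyto_labels = (disk_mask((48, 48), 24, 24, 20) > 0) & ~(
            disk_mask((48, 48), 24, 24, 12) > 0
        )
        cyto = LabelMask(cyto_labels.astype(np.int32), role="cytosol")
        stack = ImageStack.from_array(img[None], pixel_size_nm=250.0)
        return stack, cyto, phag

    def test_uniform_image_no_hotspots(self):
        stack, cyto, phag = self._scene(sd=0.0)
        assert detect_hotspots(stack, cyto, phag).count == 0

    def test_constructed_block_near_border(self):
        # 2x2 block at mu + 3 sigma, 2 px outside the border
        stack, cyto, phag = self._scene(blocks=[(23, 32, 40.0)], sd=5.0)
        hs = detect_hotspots(stack, cyto, phag, k_sd=2)
        assert hs.count == 1
        assert hs.hotspots[0].phagosome_id == 1
        assert hs.hotspots[0].peak_f_over_fave > 1.2

    def test_far_block_rejected(self):
        stack, cyto, phag = self._scene(blocks=[(4, 4, 60.0)], sd=5.0)
        assert detect_hotspots(stack, cyto, phag).count == 0

    def test_k_sd_and_distance_monotonicity(self):
        stack, cyto, phag = self._scene(
            blocks=[(23, 32, 25.0), (14, 22, 40.0)], sd=5.0
        )
        counts_k = [detect_hotspots(stack, cyto, phag, k_sd=k).count
                    for k in (1.0, 2.0, 4.0, 8.0)]
        assert all(a >= b for a, b in zip(counts_k, counts_k[1:]))
        counts_d = [detect_hotspots(stack, cyto, phag, max_dist_nm=d).count
                    for d in (250.0, 750.0, 2000.0)]
        assert all(a <= b for a, b in zip(counts_d, counts_d[1:]))

    def test_empty_cytosol_raises(self):
        stack, _, phag = self._scene()
        empty = LabelMask(np.zeros((48, 48), np.int32), role="cytosol")
        with pytest.raises(ValueError):
            detect_hotspots(stack, empty, phag)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        phag_arr = disk_mask((48, 48), 24, 24, 6)
        phag = LabelMask(phag_arr, role="phagosome")
        cyto = LabelMask(
            ((disk_mask((48, 48), 24, 24, 20) > 0)
             & ~(disk_mask((48, 48), 24, 24, 12) > 0)).astype(np.int32),
            role="cytosol")
        # border pixels by explicit 4-neighbor scan
        fg = phag_arr > 0
        border = np.zeros_like(fg)
        for y, x in zip(*np.nonzero(fg)):
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                if not fg[y + dy, x + dx]:
                    border[y, x] = True
                    break
        for _ in range(60):
            img = np.clip(rng.normal(100, 12, (48, 48)), 0, None)
            stack = ImageStack.from_array(img[None], pixel_size_nm=250.0)
            hs = detect_hotspots(stack, cyto, phag, avg_frames=1)
            frame = stack.data[0, 0, 0]
            mu = frame[cyto.foreground].mean()
            sd = frame[cyto.foreground].std()
            expected = 0
            labels, n = __import__("oracle_utils").flood_fill_label(
                frame > mu + 2 * sd, 8)
            for lab in range(1, n + 1):
                ys, xs = np.nonzero(labels == lab)
                if len(ys) < 4 or fg[ys, xs].mean() > 0.5:
                    continue
                d = min_dist_to_mask_px(ys.mean(), xs.mean(), border) * 250.0
                if d <= 750.0:
                    expected += 1
            assert hs.count == expected

    def test_equal_rates_statistically_indistinguishable(self):
        from phagoquant import pipelines

        a = pipelines.run_hotspots(synthetic.preset("shCTR", 31), 150)
        b = pipelines.run_hotspots(synthetic.preset("shSec22b", 32), 150)
        # bootstrap difference of means covers zero
        rng = np.random.default_rng(0)
        diffs = [
            a[rng.integers(0, len(a), len(a))].mean()
            - b[rng.integers(0, len(b), len(b))].mean()
            for _ in range(2000)
        ]
        lo, hi = np.percentile(diffs, [2.5, 97.5])
        assert lo <= 0.0 <= hi


class TestPhagocyticIndex:
    def test_arithmetic(self):
        phag = LabelMask(np.arange(12, dtype=np.int32).reshape(3, 4) % 11)  # 10 labels
        cells = LabelMask((np.arange(6, dtype=np.int32) % 6).reshape(2, 3))  # 5 labels
        assert phagocytic_index(phag, cells) == pytest.approx(200.0)

    def test_no_phagosomes(self):
        cells = LabelMask(np.ones((4, 4), np.int32))
        assert phagocytic_index(LabelMask(np.zeros((4, 4), np.int32)), cells) == 0.0

    def test_zero_cells_raises(self):
        with pytest.raises(ValueError):
            phagocytic_index(
                LabelMask(np.ones((4, 4), np.int32)),
                LabelMask(np.zeros((4, 4), np.int32)),
            )
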