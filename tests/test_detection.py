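"""Spot detection and Gaussian-fitting accuracy against the rendering model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from smtrack.detection import (DetectionParams, bandpass_log, detect_spots,
                               find_candidates, fit_gaussian,
                               robust_threshold)
from smtrack.render import RenderConfig, render_frame, render_movie
from smtrack.synthetic import _place_anchors

NOISELESS = RenderConfig(field_px=64, photons_per_unit=1000.0,
                         background_mean=0.0, read_noise_sd=0.0)


def _render_single(x, y, intensity=1.0, cfg=NOISELESS, rng=None,
                   noiseless=True):
    return render_frame(np.array([[x, y]]), np.array([intensity]), cfg,
                        rng=rng, noiseless=noiseless)


class TestBandpass:
    def test_constant_image_maps_to_zero(self):
        # zero up to kernel-truncation error (<0.1% of the constant)
        out = bandpass_log(np.full((40, 40), 7.3), 1.3)
        assert np.max(np.abs(out)) < 1e-3 * 7.3

    def test_linearity(self, rng):
        a = rng.normal(size=(32, 32))
        b = rng.normal(size=(32, 32))
        lhs = bandpass_log(a + b, 1.5)
        rhs = bandpass_log(a, 1.5) + bandpass_log(b, 1.5)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_maximum_at_spot_pixel(self):
        img = _render_single(23.3, 30.7)
        filt = bandpass_log(img, 1.3)
        iy, ix = np.unravel_index(np.argmax(filt), filt.shape)
        assert (iy, ix) == (31, 23)   # nearest pixel to the true center

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            bandpass_log(np.zeros((5, 5)), 0.0)


class TestCandidates:
    def test_blank_noise_no_candidates(self, rng):
        noise = rng.normal(0.0, 1.0, size=(128, 128))
        filt = bandpass_log(noise, 1.3)
        thr = 10.0 * float(np.std(filt))
        assert len(find_candidates(filt, thr)) == 0

    def test_well_separated_pair(self):
        img = (_render_single(20.0, 20.0) + _render_single(30.0, 20.0))
        filt = bandpass_log(img, 1.3)
        assert len(find_candidates(filt, 10.0)) == 2

    def test_close_pair_merges(self):
        img = (_render_single(20.0, 20.0) + _render_single(21.0, 20.0))
        filt = bandpass_log(img, 1.3)
        assert len(find_candidates(filt, 10.0)) == 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(hst.integers(0, 2**31 - 1), hst.floats(1.0, 50.0),
           hst.floats(0.1, 10.0))
    def test_threshold_monotonicity(self, seed, thr, extra):
        """Raising the threshold never increases the candidate count."""
        r = np.random.default_rng(seed)
        filt = bandpass_log(r.normal(0, 5, size=(48, 48)), 1.3)
        n_low = len(find_candidates(filt, thr))
        n_high = len(find_candidates(filt, thr + extra))
        assert n_high <= n_low


class TestFit:
    def test_noiseless_recovery(self):
        """Sub-pixel center within 0.02 px, intensity within 1%."""
        img = _render_single(17.30, 22.70)
        spot, reason = fit_gaussian(img, (23, 17), DetectionParams())
        assert reason is None
        assert spot.x == pytest.approx(17.30, abs=0.02)
        assert spot.y == pytest.approx(22.70, abs=0.02)
        assert spot.integrated_intensity == pytest.approx(1000.0, rel=0.01)

    def test_flat_window_rejected(self):
        img = np.zeros((31, 31))
        spot, reason = fit_gaussian(img, (15, 15), DetectionParams())
        assert spot is None
        assert reason == "no_signal"

    def test_localization_near_crlb_at_snr5(self):
        """Monte-Carlo localization precision is Cramer-Rao-order.

        At peak SNR ~5 (531 photons over sigma=1.3 on background 100) the
        information-limit prediction for the per-axis SD is
        ``(sigma^2 + 1/12)/N * (16/9 + 4*tau)`` with
        ``tau = 2*pi*b*(sigma^2 + 1/12)/N``; the fit's median radial
        error must reach that order (and not beat it).
        """
        N, b, sigma = 531.0, 100.0, 1.3
        sa2 = sigma**2 + 1.0 / 12.0
        tau = 2 * np.pi * b * sa2 / N
        per_axis_sd = np.sqrt(sa2 / N * (16.0 / 9.0 + 4.0 * tau))
        pred_median = np.sqrt(2 * np.log(2)) * per_axis_sd
        cfg = RenderConfig(field_px=32, photons_per_unit=N,
                           background_mean=b, read_noise_sd=2.0)
        errs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            x, y = 15.0 + (seed % 10) / 10.0, 16.0
            img = _render_single(x, y, cfg=cfg, rng=r, noiseless=False)
            spot, reason = fit_gaussian(img, (int(round(y)), int(round(x))),
                                        DetectionParams())
            if spot is not None:
                errs.append(np.hypot(spot.x - x, spot.y - y))
        assert len(errs) > 85
        assert 0.5 * pred_median < np.median(errs) < 1.4 * pred_median

    def test_edge_spot_flagged(self):
        img = _render_single(2.0, 30.0)
        spot, reason = fit_gaussian(img, (30, 2), DetectionParams())
        assert reason is None
        assert spot.edge

    def test_integrated_identity_and_window_sum(self):
        """Integrated intensity equals the analytic Gaussian volume and the
        background-subtracted window sum within 2%."""
        img = _render_single(31.6, 32.4) + 10.0
        spot, _ = fit_gaussian(img, (32, 32), DetectionParams(fit_half_px=8))
        vol = 2 * np.pi * spot.amplitude * spot.sigma_x * spot.sigma_y
        assert spot.integrated_intensity == pytest.approx(vol, rel=1e-12)
        window = img[32 - 8:32 + 9, 32 - 8:32 + 9]
        winsum = float(window.sum() - spot.background * window.size)
        assert spot.integrated_intensity == pytest.approx(winsum, rel=0.02)


class TestDetectSpots:
    def test_empty_stack(self):
        out = detect_spots(np.zeros((3, 32, 32)), DetectionParams())
        assert [len(f) for f in out] == [0, 0, 0]

    def test_recall_precision_at_high_snr(self):
        """>=95% recall and precision against generator truth at 10:1 SNR."""
        r = np.random.default_rng(3)
        n_sp, n_frames = 12, 10
        anchors = _place_anchors(n_sp, 64, 8.0, r)
        pos = anchors[:, None, :] + r.normal(0, 0.3, size=(n_sp, n_frames, 2))
        cfg = RenderConfig(field_px=64, photons_per_unit=1000.0,
                           background_mean=100.0, read_noise_sd=2.0)
        stack = render_movie(pos, np.ones((n_sp, n_frames)), cfg, seed=9)
        per_frame = detect_spots(stack.data,
                                 DetectionParams(amp_threshold_k=3.0))
        tp = fp = fn = 0
        for t, spots in enumerate(per_frame):
            got = np.array([[s.x, s.y] for s in spots]).reshape(-1, 2)
            used = set()
            for tx, ty in pos[:, t, :]:
                d = (np.hypot(got[:, 0] - tx, got[:, 1] - ty)
                     if len(got) else np.array([]))
                cand = [i for i in np.argsort(d)
                        if i not in used and d[i] <= 1.0]
                if cand:
                    used.add(cand[0])
                    tp += 1
                else:
                    fn += 1
            fp += len(got) - len(used)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95

    def test_intensity_linearity(self):
        """Doubling the photon yield doubles the mean fitted intensity
        (+-2%, averaged over frames to beat shot noise)."""
        n_frames = 50
        pos = np.repeat(np.array([[[20.0, 20.0]], [[40.0, 44.0]]]),
                        n_frames, axis=1)
        inten = np.ones((2, n_frames))
        means = []
        for ppu in (1000.0, 2000.0):
            cfg = RenderConfig(field_px=64, photons_per_unit=ppu,
                               background_mean=100.0, read_noise_sd=1.0)
            stack = render_movie(pos, inten, cfg, seed=4)
            per_frame = detect_spots(stack.data,
                                     DetectionParams(amp_threshold_k=3.0))
            vals = [s.integrated_intensity for fr in per_frame for s in fr]
            assert len(vals) == 2 * n_frames
            means.append(np.mean(vals))
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.02)

    def test_translation_equivariance(self):
        img = _render_single(20.25, 24.75, cfg=RenderConfig(
            field_px=64, photons_per_unit=1000.0, background_mean=50.0,
            read_noise_sd=0.0))
        shifted = np.roll(img, (5, 7), axis=(0, 1))
        p = DetectionParams(min_amplitude=20.0)
        s0 = detect_spots(img, p)[0]
        s1 = detect_spots(shifted, p)[0]
        assert len(s0) == len(s1) == 1
        assert s1[0].x - s0[0].x == pytest.approx(7.0, abs=1e-6)
        assert s1[0].y - s0[0].y == pytest.approx(5.0, abs=1e-6)
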