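import numpy as np
import pandas as pd
import pytest

from flatpaint.illumination import FieldOfView, IlluminationProfile, calibrate_edge_ratio, intensity_at
from flatpaint.localize import (
    SpotCandidate,
    detect_spots,
    fit_spot,
    localize_stack,
    net_gradient_map,
)
from flatpaint.simulate import EmissionModel, render_frames


def brute_force_net_gradient(img: np.ndarray, box: int) -> np.ndarray:
    """Independent double-loop evaluation of the net-gradient definition."""
    gy, gx = np.gradient(img.astype(float))
    h = box // 2
    out = np.zeros_like(img, dtype=float)
    for pr in range(h + 1, img.shape[0] - h - 1):
        for pc in range(h + 1, img.shape[1] - h - 1):
            acc = 0.0
            for qr in range(pr - h, pr + h + 1):
                for qc in range(pc - h, pc + h + 1):
                    if qr == pr and qc == pc:
                        continue
                    dy, dx = pr - qr, pc - qc
                    norm = np.hypot(dx, dy)
                    acc += gx[qr, qc] * dx / norm + gy[qr, qc] * dy / norm
            out[pr, pc] = acc
    return out


def gaussian_spot(shape, x, y, photons, sigma=1.0, bg=0.0):
    from scipy.special import erf

    rows, cols = shape
    ex = np.arange(cols + 1, dtype=float)
    ey = np.arange(rows + 1, dtype=float)
    s2 = sigma * np.sqrt(2)
    fx = 0.5 * (erf((ex[1:] - x) / s2) - erf((ex[:-1] - x) / s2))
    fy = 0.5 * (erf((ey[1:] - y) / s2) - erf((ey[:-1] - y) / s2))
    return photons * np.outer(fy, fx) + bg


class TestNetGradient:
    def test_constant_image_is_zero(self):
        assert np.all(net_gradient_map(np.full((15, 15), 7.0), box=5) == 0.0)

    def test_maximum_at_spot_center(self):
        img = gaussian_spot((21, 21), 10.5, 10.5, 1000.0)
        ng = net_gradient_map(img, box=7)
        assert np.unravel_index(np.argmax(ng), ng.shape) == (10, 10)

    @pytest.mark.parametrize("box", [3, 5, 7])
    def test_matches_brute_force_oracle(self, box, rng):
        img = rng.uniform(0, 100, (13, 13))
        ng = net_gradient_map(img, box=box)
        oracle = brute_force_net_gradient(img, box=box)
        h = box // 2 + 1
        inner = (slice(h, -h), slice(h, -h))
        assert np.allclose(ng[inner], oracle[inner], atol=1e-10)

    def test_even_or_tiny_box_rejected(self):
        with pytest.raises(ValueError):
            net_gradient_map(np.zeros((9, 9)), box=4)
        with pytest.raises(ValueError):
            net_gradient_map(np.zeros((9, 9)), box=1)


class TestDetect:
    def test_below_threshold_not_detected(self):
        img = gaussian_spot((21, 21), 10.5, 10.5, 500.0)
        ng = net_gradient_map(img, box=7)
        assert detect_spots(ng, threshold=2 * ng.max()) == []
        assert len(detect_spots(ng, threshold=0.5 * ng.max())) == 1

    def test_nearby_candidates_suppressed_to_strongest(self):
        ng = np.zeros((21, 21))
        ng[10, 10] = 100.0
        ng[10, 11] = 90.0
        ng[10, 16] = 80.0
        spots = detect_spots(ng, threshold=10.0, min_separation=3)
        assert [(s.row, s.col) for s in spots] == [(10, 10), (10, 16)]

    def test_efficiency_nondecreasing_in_photons(self):
        fov = FieldOfView(32)
        prof = IlluminationProfile(kind="flattop", plateau_radius=1e9)
        rng_seed = 0
        effs = []
        for ph_yield in (10000.0, 30000.0, 100000.0):
            em = EmissionModel(photon_yield=ph_yield, background_rate=20.0,
                               exposure=0.1, readout_noise=1.5, baseline=100.0)
            ev = pd.DataFrame({
                "event_id": [0], "site_id": [0], "structure_id": [0],
                "x": [fov.width / 2], "y": [fov.height / 2],
                "t_on": [0.0], "t_off": [3.0], "bleached": [False], "censored": [False],
            })
            stack = render_frames(ev, em, prof, fov, 30, seed=rng_seed)
            hits = 0
            for f in range(30):
                ng = net_gradient_map(stack[f].astype(float) - 100.0, box=7)
                hits += len(detect_spots(ng, threshold=2000.0)) > 0
            effs.append(hits / 30)
        assert effs == sorted(effs)


class TestFit:
    def test_noiseless_centered_spot_recovered_exactly(self):
        img = gaussian_spot((15, 15), 7.5, 7.5, 20000.0, sigma=1.0, bg=5.0)
        cand = SpotCandidate(frame=0, row=7, col=7, net_gradient=1.0)
        row = fit_spot(img, cand, box=7)
        assert row is not None
        assert row["photons"] == pytest.approx(20000.0, rel=1e-3)
        assert row["x"] == pytest.approx(7.5, abs=1e-3)
        assert row["y"] == pytest.approx(7.5, abs=1e-3)
        assert row["bg"] == pytest.approx(5.0, rel=0.05)

    def test_subpixel_offset_recovered(self, rng):
        # Monte Carlo at N = 1e4: bias well under 0.02 px
        errs = []
        for i in range(40):
            img = rng.poisson(gaussian_spot((15, 15), 7.8, 7.3, 10000.0, bg=10.0)).astype(float)
            row = fit_spot(img, SpotCandidate(0, 7, 7, 1.0), box=9)
            if row is not None:
                errs.append((row["x"] - 7.8, row["y"] - 7.3))
        errs = np.array(errs)
        assert len(errs) > 35
        assert np.all(np.abs(errs.mean(axis=0)) < 0.02)

    def test_two_emitters_at_20nm_fit_as_double_photons(self):
        # 20 nm apart = 0.154 px at 130 nm pixels: unresolvable, one spot
        # carrying the summed photons
        n_single = 10000.0
        img = (gaussian_spot((15, 15), 7.42, 7.5, n_single)
               + gaussian_spot((15, 15), 7.58, 7.5, n_single))
        row = fit_spot(img, SpotCandidate(0, 7, 7, 1.0), box=9)
        assert row["photons"] == pytest.approx(2 * n_single, rel=0.01)

    def test_unbiased_photon_estimate(self, rng):
        # invariant: < 1% bias for N >= 5000 at bg <= 50/px
        ests = []
        for i in range(200):
            img = rng.poisson(gaussian_spot((15, 15), 7.5, 7.5, 5000.0, bg=50.0)).astype(float)
            row = fit_spot(img, SpotCandidate(0, 7, 7, 1.0), box=9)
            if row is not None:
                ests.append(row["photons"])
        assert len(ests) > 190
        assert abs(np.mean(ests) / 5000.0 - 1.0) < 0.01


class TestLocalizeStack:
    def test_empty_stack_gives_empty_table(self):
        stack = np.zeros((3, 32, 32), dtype=np.uint16)
        table = localize_stack(stack, threshold=100.0)
        assert len(table) == 0

    def test_recovers_simulated_events(self):
        fov = FieldOfView(48)
        prof = IlluminationProfile(kind="flattop", plateau_radius=1e9)
        em = EmissionModel(photon_yield=100000.0, background_rate=10.0,
                           exposure=0.1, readout_noise=1.5, baseline=100.0)
        positions = [(1500.0, 1700.0), (4200.0, 3100.0), (5100.0, 4900.0)]
        ev = pd.DataFrame({
            "event_id": range(3), "site_id": range(3), "structure_id": range(3),
            "x": [p[0] for p in positions], "y": [p[1] for p in positions],
            "t_on": 0.0, "t_off": 2.0, "bleached": False, "censored": False,
        })
        stack = render_frames(ev, em, prof, fov, 20, seed=5)
        table = localize_stack(stack, box=7, threshold=3000.0, baseline=100.0)
        # >= 95% of event-frames recovered
        assert len(table) >= 0.95 * 3 * 20
        # fitted positions match the planted emitters
        for x_nm, y_nm in positions:
            d = np.hypot(table["x"] * 130.0 - x_nm, table["y"] * 130.0 - y_nm)
            assert (d < 30.0).sum() >= 19

    def test_gaussian_threshold_penalizes_periphery_flattop_does_not(self):
        fov = FieldOfView(64)
        em = EmissionModel(photon_yield=100000.0, background_rate=10.0,
                           exposure=0.1, readout_noise=1.5, baseline=100.0)
        cx, cy = fov.center
        inner = (cx, cy)
        outer = (cx + fov.width / 2 - 500.0, cy)
        ev = pd.DataFrame({
            "event_id": range(2), "site_id": range(2), "structure_id": range(2),
            "x": [inner[0], outer[0]], "y": [inner[1], outer[1]],
            "t_on": 0.0, "t_off": 3.0, "bleached": False, "censored": False,
        })
        gauss = calibrate_edge_ratio(
            IlluminationProfile(kind="gaussian", gauss_sigma=1.0), fov, 1.0 / 3.0)
        flat = IlluminationProfile(kind="flattop", center=fov.center,
                                   plateau_radius=0.9 * fov.width, edge_order=20)
        rates = {}
        for name, prof in [("gauss", gauss), ("flat", flat)]:
            stack = render_frames(ev, em, prof, fov, 30, seed=6)
            n_in = n_out = 0
            for f in range(30):
                ng = net_gradient_map(stack[f].astype(float) - 100.0, box=7)
                spots = detect_spots(ng, threshold=6000.0)
                for s in spots:
                    d_in = np.hypot(s.col * 130.0 - inner[0], s.row * 130.0 - inner[1])
                    d_out = np.hypot(s.col * 130.0 - outer[0], s.row * 130.0 - outer[1])
                    if d_in < 400:
                        n_in += 1
                    elif d_out < 400:
                        n_out += 1
            rates[name] = (n_in / 30, n_out / 30)
        assert rates["gauss"][1] < rates["gauss"][0]  # periphery under-detected
        assert abs(rates["flat"][0] - rates["flat"][1]) <= 0.05  # uniform
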