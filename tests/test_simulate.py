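import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flatpaint.illumination import FieldOfView, IlluminationProfile, intensity_at
from flatpaint.simulate import (
    EmissionModel,
    KineticsModel,
    StructureModel,
    events_to_localizations,
    jittered_site_localizations,
    make_layout,
    make_rod_phantom,
    render_frames,
    simulate_traces,
)


class TestLayout:
    def test_grid_site_geometry(self):
        # 3 x 4 sites at 20 nm pitch: neighbors along rows/cols exactly 20 nm apart
        coords = StructureModel(rows=3, cols=4, pitch=20.0).site_coords()
        assert coords.shape == (12, 2)
        xs = np.unique(coords[:, 0])
        ys = np.unique(coords[:, 1])
        assert np.allclose(np.diff(xs), 20.0) and len(xs) == 4
        assert np.allclose(np.diff(ys), 20.0) and len(ys) == 3
        assert np.allclose(coords.mean(axis=0), 0.0)

    def test_layout_deterministic_and_inside(self):
        fov = FieldOfView(512)
        s = StructureModel()
        a = make_layout(s, 500, fov, seed=7)
        b = make_layout(s, 500, fov, seed=7)
        pd.testing.assert_frame_equal(a.structures, b.structures)
        pd.testing.assert_frame_equal(a.sites, b.sites)
        assert a.structures["x"].between(0, fov.width).all()
        assert a.sites["y"].between(0, fov.height).all()

    def test_centers_uniform(self):
        fov = FieldOfView(512)
        layout = make_layout(StructureModel(), 4000, fov, seed=3)
        # chi-square on a 4x4 occupancy grid
        hx = np.digitize(layout.structures["x"], np.linspace(0, fov.width, 5)[1:-1])
        hy = np.digitize(layout.structures["y"], np.linspace(0, fov.height, 5)[1:-1])
        counts = np.bincount(hx * 4 + hy, minlength=16)
        _, p = stats.chisquare(counts)
        assert p > 0.001

    def test_overcrowded_fov_rejected(self):
        with pytest.raises(ValueError):
            make_layout(StructureModel(), 5000, FieldOfView(16), seed=0)


class TestTraces:
    @staticmethod
    def _flat_unit():
        return IlluminationProfile(kind="flattop", plateau_radius=1e9, edge_order=20)

    def test_mean_bright_time_no_bleach(self):
        fov = FieldOfView(128)
        layout = make_layout(StructureModel(), 60, fov, seed=5)
        kin = KineticsModel(k_on=2e6, imager_concentration=5e-8, k_off=2.0)
        ev = simulate_traces(layout, kin, self._flat_unit(), 500.0, seed=5)
        durations = (ev["t_off"] - ev["t_on"])[~ev["censored"]]
        n = len(durations)
        assert n > 1e4
        sem = durations.std() / np.sqrt(n)
        assert abs(durations.mean() - 0.5) < 3 * sem

    def test_mean_bright_time_with_bleach_matches_competing_exponentials(self):
        # oracle: min(Exp(k_off), Exp(k_b I)) is Exp(k_off + k_b I)
        fov = FieldOfView(128)
        layout = make_layout(StructureModel(), 60, fov, seed=6)
        kin = KineticsModel(k_on=2e6, imager_concentration=5e-8, k_off=2.0, bleach_coeff=3.0)
        ev = simulate_traces(layout, kin, self._flat_unit(), 500.0, seed=6)
        durations = (ev["t_off"] - ev["t_on"])[~ev["censored"]]
        expect = 1.0 / (2.0 + 3.0 * 1.0)
        sem = durations.std() / np.sqrt(len(durations))
        assert abs(durations.mean() - expect) < 3 * sem
        # direct Monte Carlo oracle at the same rates
        rng = np.random.default_rng(0)
        oracle = np.minimum(rng.exponential(1 / 2.0, 20000), rng.exponential(1 / 3.0, 20000))
        assert abs(durations.mean() - oracle.mean()) < 4 * sem

    def test_bleach_wins_flag_consistent(self):
        fov = FieldOfView(128)
        layout = make_layout(StructureModel(), 30, fov, seed=8)
        kin = KineticsModel(k_on=2e6, imager_concentration=5e-8, k_off=1.0, bleach_coeff=1.0)
        ev = simulate_traces(layout, kin, self._flat_unit(), 300.0, seed=8)
        frac = ev["bleached"].mean()
        # equal rates: bleaching wins half the time
        assert abs(frac - 0.5) < 0.05

    def test_flat_top_bright_times_uniform_across_radius(self, flattop, fov256):
        layout = make_layout(StructureModel(), 200, fov256, seed=9)
        kin = KineticsModel(k_on=2e6, imager_concentration=5e-8, k_off=2.0, bleach_coeff=2.0)
        ev = simulate_traces(layout, kin, flattop, 400.0, seed=9)
        cx, cy = fov256.center
        r = np.hypot(ev["x"] - cx, ev["y"] - cy)
        dur = (ev["t_off"] - ev["t_on"]).to_numpy()
        keep = ~ev["censored"].to_numpy()
        inner = dur[keep & (r < np.median(r))]
        outer = dur[keep & (r >= np.median(r))]
        sem = np.hypot(inner.std() / np.sqrt(len(inner)), outer.std() / np.sqrt(len(outer)))
        assert abs(inner.mean() - outer.mean()) < 3 * sem


class TestFastPath:
    def _setup(self, seed=0, n=40, conc=5e-9):
        fov = FieldOfView(256)
        prof = IlluminationProfile(kind="flattop", plateau_radius=0.9 * fov.width,
                                   edge_order=20, center=fov.center)
        layout = make_layout(StructureModel(), n, fov, seed=seed)
        kin = KineticsModel(k_on=2e6, imager_concentration=conc, k_off=2.0)
        ev = simulate_traces(layout, kin, prof, 300.0, seed=seed)
        return fov, prof, layout, ev

    def test_event_spanning_three_frames_gives_three_localizations(self):
        fov = FieldOfView(64)
        prof = IlluminationProfile(kind="flattop", plateau_radius=1e9)
        ev = pd.DataFrame({
            "event_id": [0], "site_id": [0], "structure_id": [0],
            "x": [4000.0], "y": [4000.0], "t_on": [0.5], "t_off": [0.8],
            "bleached": [False], "censored": [False],
        })
        em = EmissionModel(exposure=0.1)
        locs = events_to_localizations(ev, em, prof, 20, fov, seed=1)
        assert len(locs) == 3
        assert (locs["event_id"] == 0).all()
        assert sorted(locs["frame"]) == [5, 6, 7]

    def test_full_frame_photon_mean(self):
        fov, prof, layout, ev = self._setup(seed=11)
        em = EmissionModel(photon_yield=150000.0, exposure=0.1)
        locs = events_to_localizations(ev, em, prof, 3000, fov, seed=11)
        # select single-emitter localizations from frames fully covered by
        # their event (overlap exactly 1): expected photons = psi*I*exposure
        merged = locs.merge(ev[["event_id", "t_on", "t_off"]], on="event_id")
        full = (
            (merged["frame"] * 0.1 >= merged["t_on"])
            & ((merged["frame"] + 1) * 0.1 <= merged["t_off"])
            & (merged["n_emitters"] == 1)
        )
        ph = merged.loc[full, "photons"]
        sem = ph.std() / np.sqrt(len(ph))
        assert len(ph) > 500
        assert abs(ph.mean() - 15000) < 3 * sem

    def test_simultaneous_nearby_events_merge_with_pooled_photons(self):
        fov = FieldOfView(64)
        prof = IlluminationProfile(kind="flattop", plateau_radius=1e9)
        ev = pd.DataFrame({
            "event_id": [0, 1], "site_id": [0, 1], "structure_id": [0, 0],
            "x": [4000.0, 4020.0], "y": [4000.0, 4000.0],
            "t_on": [0.0, 0.0], "t_off": [1.0, 1.0],
            "bleached": [False, False], "censored": [False, False],
        })
        em = EmissionModel(photon_yield=150000.0, exposure=0.1, psf_sigma=130.0)
        locs = events_to_localizations(ev, em, prof, 10, fov, seed=2)
        assert (locs["n_emitters"] == 2).all()
        # pooled photons ~ 2 x single-frame expectation
        assert abs(locs["photons"].mean() - 30000) < 500
        # far-apart events do not merge
        ev2 = ev.copy()
        ev2.loc[1, "x"] = 6000.0
        locs2 = events_to_localizations(ev2, em, prof, 10, fov, seed=2)
        assert (locs2["n_emitters"] == 1).all()

    def test_photon_linearity_with_intensity(self, gauss_third, fov256):
        # positions at intensity ratio 3 give photon ratio 3 within 3 SEM
        cx, cy = gauss_third.center
        edge_x = cx + fov256.width / 2
        n_ev = 3000
        ev = pd.DataFrame({
            "event_id": np.arange(2 * n_ev),
            "site_id": np.repeat([0, 1], n_ev),
            "structure_id": np.repeat([0, 1], n_ev),
            "x": np.repeat([cx, edge_x], n_ev),
            "y": np.full(2 * n_ev, cy),
            "t_on": np.tile(np.arange(n_ev) * 0.5, 2),
            "t_off": np.tile(np.arange(n_ev) * 0.5 + 0.1, 2),
            "bleached": False, "censored": False,
        })
        em = EmissionModel(photon_yield=150000.0, exposure=0.1)
        locs = events_to_localizations(ev, em, gauss_third, 20000, fov256, seed=3)
        center_ph = locs.photons[locs["site_id"] == 0]
        edge_ph = locs.photons[locs["site_id"] == 1]
        ratio = center_ph.mean() / edge_ph.mean()
        sem = ratio * np.hypot(center_ph.sem() / center_ph.mean(),
                               edge_ph.sem() / edge_ph.mean())
        assert abs(ratio - 3.0) < 3 * sem

    def test_determinism_byte_identical(self):
        fov, prof, layout, ev = self._setup(seed=12)
        em = EmissionModel()
        a = events_to_localizations(ev, em, prof, 3000, fov, seed=99)
        b = events_to_localizations(ev, em, prof, 3000, fov, seed=99)
        pd.testing.assert_frame_equal(a, b)
        assert hash(a.to_csv()) == hash(b.to_csv())


class TestRodPhantom:
    def test_transverse_positions_bounded_without_linkage_noise(self):
        layout = make_rod_phantom(length=2000.0, label_radius=18.5, linkage_sd=0.0,
                                  density=2.0, seed=4)
        cy = layout.fov.center[1]
        trans = layout.sites["y"].to_numpy() - cy
        assert np.all(np.abs(trans) <= 18.5 + 1e-9)

    def test_transverse_histogram_peaks_near_rails(self):
        # projection density 1/sqrt(R^2 - x^2) piles up near +-R
        layout = make_rod_phantom(length=50000.0, label_radius=18.5, density=2.0, seed=5)
        trans = layout.sites["y"].to_numpy() - layout.fov.center[1]
        hist, edges = np.histogram(trans, bins=37, range=(-18.5, 18.5))
        centers = 0.5 * (edges[:-1] + edges[1:])
        # outer 20% of bins hold more than their uniform share
        outer = np.abs(centers) > 0.8 * 18.5
        assert hist[outer].mean() > 2.0 * hist[~outer].mean()

    def test_requires_positive_radius(self):
        with pytest.raises(ValueError):
            make_rod_phantom(label_radius=0.0)


class TestRenderFrames:
    def test_no_events_no_background_is_baseline_plus_readout(self):
        fov = FieldOfView(32)
        prof = IlluminationProfile(kind="flattop", plateau_radius=1e9)
        em = EmissionModel(background_rate=0.0, readout_noise=1.5, baseline=100.0)
        stack = render_frames(pd.DataFrame(), em, prof, fov, 20, seed=6)
        vals = stack.astype(float).ravel()
        sem = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - 100.0) < 3 * sem

    def test_noiseless_psf_preserves_photon_sum(self):
        fov = FieldOfView(32)
        prof = IlluminationProfile(kind="flattop", plateau_radius=1e9)
        em = EmissionModel(photon_yield=10000.0, background_rate=0.0,
                           readout_noise=0.0, baseline=0.0, exposure=0.1)
        ev = pd.DataFrame({
            "event_id": [0], "site_id": [0], "structure_id": [0],
            "x": [fov.width / 2], "y": [fov.height / 2],
            "t_on": [0.0], "t_off": [0.1], "bleached": [False], "censored": [False],
        })
        stack = render_frames(ev, em, prof, fov, 1, seed=7)
        # Poisson noise applies, but the expected sum is psi*I*t = 1000
        total = stack[0].astype(float).sum()
        assert abs(total - 1000.0) < 3 * np.sqrt(1000.0)

    def test_doubling_yield_doubles_spot_counts(self):
        fov = FieldOfView(32)
        prof = IlluminationProfile(kind="flattop", plateau_radius=1e9)
        ev = pd.DataFrame({
            "event_id": [0], "site_id": [0], "structure_id": [0],
            "x": [fov.width / 2], "y": [fov.height / 2],
            "t_on": [0.0], "t_off": [2.0], "bleached": [False], "censored": [False],
        })
        sums = []
        for y in (5000.0, 10000.0):
            em = EmissionModel(photon_yield=y, background_rate=0.0,
                               readout_noise=0.0, baseline=0.0, exposure=0.1)
            stack = render_frames(ev, em, prof, fov, 20, seed=8)
            sums.append(stack.astype(float).sum())
        assert sums[1] / sums[0] == pytest.approx(2.0, rel=0.05)


def test_jittered_localizations_have_planted_error():
    layout = make_rod_phantom(length=1000.0, label_radius=10.0, density=0.05, seed=9)
    locs = jittered_site_localizations(layout.sites, sigma=2.0, frames_per_site=500,
                                       pixel_size=130.0, seed=9)
    err_x = locs["x"].to_numpy() * 130.0 - np.repeat(layout.sites["x"].to_numpy(), 500)
    assert np.std(err_x) == pytest.approx(2.0, rel=0.05)
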