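"""Reference parameter-recovery scenarios.

Each function simulates a complete experiment at the standard study
conditions and pushes it through the analysis pipeline, returning the
recovered quantity next to its planted ground truth.  These scenarios back
the package's regression suite and the reproduction script; sizes are kept
at the smallest scale at which the estimators are stable.
"""

from __future__ import annotations

import numpy as np

from . import average as avg
from . import kinetics as kin
from . import postfilter, precision
from .scenario import RunConfig, simulate_fast
from .simulate import StructureModel, jittered_site_localizations, make_layout

__all__ = [
    "grid_spacing_benchmark",
    "resolution_by_segment_benchmark",
    "nena_benchmark",
    "rod_profile_benchmark",
    "photon_mixture_benchmark",
    "photon_linearity_benchmark",
]

# photon yield giving ~2 nm localization error on full frames:
# sigma = excess * psf / sqrt(N) with excess 1.4, psf 130 nm -> N = 8281
PHOTONS_FOR_2NM = 8281.0


def _grid_cfg(seed: int, pitch: float, n_structures: int, n_frames: int) -> RunConfig:
    return RunConfig(
        seed=seed,
        n_pixels=512,
        profile_kind="flattop",
        pitch=pitch,
        n_structures=n_structures,
        n_frames=n_frames,
        photon_yield=PHOTONS_FOR_2NM / 0.1,
        imager_concentration=5.0e-9,
        do_filter=False, do_nena=False, do_average=False,
    )


def _aligned_grid_locs(cfg: RunConfig):
    """Simulate, pick, QC and align grid structures; return the average result."""
    layout, events, locs, profile = simulate_fast(cfg)
    picks = kin.pick_by_ground_truth(locs, layout.structures, cfg.pixel_size,
                                     radius=cfg.pick_radius)
    model_coords = StructureModel(rows=cfg.rows, cols=cfg.cols, pitch=cfg.pitch).site_coords()
    coords, structure_ids = [], []
    for p in picks:
        pk = kin.pick_kinetics(locs, p, cfg.exposure, cfg.n_frames)
        if not pk.qc_pass:
            continue
        sel = locs["structure_id"].to_numpy() == p.structure_id
        xy = locs.loc[sel, ["x", "y"]].to_numpy() * cfg.pixel_size - np.asarray(p.center)
        if len(xy) >= 30:
            coords.append(xy)
            structure_ids.append(p.structure_id)
    res = avg.average_picks(
        coords, model_coords, oversampling=cfg.oversampling,
        pixel_size=cfg.pixel_size, symmetry_deg=cfg.symmetry_deg,
        rot_step_deg=cfg.rot_step_deg,
    )
    return layout, res, np.asarray(structure_ids)


def grid_spacing_benchmark(seed: int = 0, n_structures: int = 220,
                           n_frames: int = 3000) -> dict:
    """Recover the designed 20 nm site pitch from averaged origami grids.

    Simulates 3 x 4 grids at 20 nm pitch under flat-top illumination with
    ~2 nm localization error, aligns all QC-passed picks (oversampling 40,
    180-degree symmetry) and fits a double Gaussian across the central
    site columns of the pooled aligned localizations.
    """
    cfg = _grid_cfg(seed, 20.0, n_structures, n_frames)
    _, res, _ = _aligned_grid_locs(cfg)
    fit = avg.spacing_fit(res.aligned_xy, cfg.pitch, axis="x")
    return {
        "spacing_nm": fit.distance,
        "designed_nm": cfg.pitch,
        "peak_sigma_nm": fit.mean_sigma,
        "dip": fit.dip,
        "n_picks": int(res.transforms.shape[0]),
    }


def resolution_by_segment_benchmark(seed: int = 0, n_structures: int = 260,
                                    n_frames: int = 3000) -> dict:
    """Resolve 10-nm-pitch grids in every concentric segment.

    Structures are split into 5 equal-count rings; picks are aligned and a
    two-peak fit with the >= 20% midpoint-dip criterion is evaluated per
    ring.  Returns per-segment spacing/dip and the outermost segment's
    resolved separation.
    """
    from .segments import equal_count_rings

    cfg = _grid_cfg(seed, 10.0, n_structures, n_frames)
    layout, res, used_ids = _aligned_grid_locs(cfg)
    centers = layout.structures[["x", "y"]].to_numpy()
    segmap = equal_count_rings(centers, 5, cfg.fov.center)
    seg_of = dict(zip(layout.structures["structure_id"].to_numpy(), segmap.labels))
    loc_seg = np.array([seg_of[used_ids[i]] for i in res.pick_index])
    out: dict = {"segments": {}}
    for seg in range(1, 6):
        xy = res.aligned_xy[loc_seg == seg]
        fit = avg.spacing_fit(xy, cfg.pitch, axis="x")
        out["segments"][seg] = {
            "spacing_nm": fit.distance, "dip": fit.dip, "resolved": fit.resolved,
            "n_locs": int(len(xy)),
        }
    outer = out["segments"][5]
    out["outer_resolved_separation_nm"] = outer["spacing_nm"] if outer["resolved"] else float("inf")
    out["all_segments_resolved"] = all(s["resolved"] for s in out["segments"].values())
    return out


def nena_benchmark(seed: int = 0, sigma: float = 2.0, n_sites: int = 60,
                   frames_per_site: int = 250) -> dict:
    """Recover a planted isotropic localization error with the NeNA fit."""
    from .illumination import FieldOfView
    from .kinetics import Pick

    fov = FieldOfView(512)
    layout = make_layout(StructureModel(pitch=40.0), max(n_sites // 12, 1) + 1,
                         fov, seed=seed)
    sites = layout.sites.iloc[:n_sites]
    locs = jittered_site_localizations(sites, sigma, frames_per_site, 130.0, seed=seed + 1)
    pick = [Pick(0, 0, np.arange(len(locs)), (0.0, 0.0))]
    fit = precision.nena(locs, pick, 130.0, min_pairs=10000)
    return {"nena_nm": fit.sigma, "planted_nm": sigma, "n_pairs": fit.n_pairs}


def rod_profile_benchmark(seed: int = 0, label_radius: float = 18.5,
                          length: float = 2000.0, n_frames: int = 3000) -> dict:
    """Recover the rail separation of a microtubule-like rod phantom.

    The rod is labeled on a cylinder surface of the given radius and imaged
    at photon counts giving ~5 nm localization error; multi-emitter
    localizations are removed with the 1/e^2 photon threshold when a second
    photon peak is detected, and the transverse histogram is fitted with the
    blurred circle-projection model.
    """
    # ~5 nm localization error: N = (1.4 * 130 / 5)^2 = 1325 photons/frame
    cfg = RunConfig(
        seed=seed, n_pixels=64, profile_kind="flattop",
        structure_kind="rod", rod_length=length, rod_label_radius=label_radius,
        rod_density=0.5, n_frames=n_frames,
        photon_yield=1325.0 / 0.1, imager_concentration=1.25e-9,
        do_filter=False, do_nena=False, do_average=False,
    )
    layout, events, locs, profile = simulate_fast(cfg)
    try:
        mix = postfilter.fit_photon_mixture(locs["photons"].to_numpy())
        if not mix.single_peak:
            locs, _ = postfilter.filter_multiemitter(locs, mix.threshold)
    except (ValueError, RuntimeError):
        pass
    theta = float(layout.structures["theta"].iloc[0])
    cx, cy = cfg.fov.center
    x = locs["x"].to_numpy() * cfg.pixel_size - cx
    y = locs["y"].to_numpy() * cfg.pixel_size - cy
    trans = -x * np.sin(theta) + y * np.cos(theta)
    fit = avg.rod_transverse_fit(trans)
    fit["designed_p2p"] = 2 * label_radius
    return fit


def photon_mixture_benchmark(seed: int = 0, n_structures: int = 120,
                             n_frames: int = 4000) -> dict:
    """Second-to-first photon-peak ratio when doubles are simultaneous pairs.

    The imager concentration is raised so that two sites of one origami are
    regularly bound in the same frame; merged localizations carry the pooled
    photons, and the fitted peak ratio measures how faithfully the second
    histogram peak sits at twice the single-emitter peak.
    """
    cfg = RunConfig(
        seed=seed, n_pixels=512, profile_kind="flattop",
        n_structures=n_structures, n_frames=n_frames,
        imager_concentration=2.0e-8,
        do_filter=False, do_nena=False, do_average=False,
    )
    _, _, locs, _ = simulate_fast(cfg)
    mix = postfilter.fit_photon_mixture(locs["photons"].to_numpy())
    return {
        "mu1": mix.mu1, "mu2": mix.mu2, "ratio": mix.peak_ratio,
        "single_peak": mix.single_peak, "n_locs": int(len(locs)),
    }


def photon_linearity_benchmark(seed: int = 0, n_frames: int = 20000) -> dict:
    """Mean photons at beam center vs a position receiving 1/3 the excitation.

    Under the edge-calibrated Gaussian profile the FOV edge midpoint sees
    exactly one third of the center intensity; two isolated sites are imaged
    at both positions and the per-localization photon means are compared.
    The center full-frame mean is planted at 15,000 photons.
    """
    import pandas as pd

    from .illumination import intensity_at
    from .simulate import EmissionModel, KineticsModel, simulate_traces
    from .simulate import FieldLayout
    from .scenario import make_profile

    cfg = RunConfig(seed=seed, n_pixels=256, profile_kind="gaussian",
                    n_frames=n_frames)
    fov = cfg.fov
    profile = make_profile(cfg)
    cx, cy = fov.center
    edge = (cx + fov.width / 2.0, cy)
    structures = pd.DataFrame({
        "structure_id": [0, 1], "x": [cx, edge[0]], "y": [cy, edge[1]],
        "theta": [0.0, 0.0], "species": [0, 0],
    })
    sites = pd.DataFrame({
        "site_id": [0, 1], "structure_id": [0, 1],
        "x": [cx, edge[0]], "y": [cy, edge[1]],
    })
    layout = FieldLayout(structures=structures, sites=sites, fov=fov)
    kinetics = KineticsModel(k_on=2e6, imager_concentration=1e-7, k_off=2.0)
    events = simulate_traces(layout, kinetics, profile, cfg.duration_s, seed=seed)
    from .simulate import events_to_localizations

    em = cfg.emission_model()
    locs = events_to_localizations(events, em, profile, cfg.n_frames, fov, seed=seed + 1)
    singles = locs[locs["n_emitters"] == 1]
    center_ph = singles.loc[singles["site_id"] == 0, "photons"]
    edge_ph = singles.loc[singles["site_id"] == 1, "photons"]
    return {
        "center_mean": float(center_ph.mean()),
        "edge_mean": float(edge_ph.mean()),
        "ratio": float(center_ph.mean() / edge_ph.mean()),
        "planted_intensity_ratio": float(
            intensity_at(profile, cx, cy) / intensity_at(profile, *edge)
        ),
        "n_center": int(len(center_ph)), "n_edge": int(len(edge_ph)),
    }
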