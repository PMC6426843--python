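"""End-to-end scenario runner.

A :class:`RunConfig` fully determines a simulated experiment plus its
analysis; ``run_scenario`` executes simulate -> pick -> QC -> segment ->
kinetics -> photon filter -> NeNA -> average -> spacing fit and returns a
machine-readable report.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import average as avg
from . import kinetics as kin
from . import postfilter, precision, segments
from .illumination import FieldOfView, IlluminationProfile, calibrate_edge_ratio
from .simulate import (
    EmissionModel,
    KineticsModel,
    StructureModel,
    events_to_localizations,
    make_layout,
    make_rod_phantom,
    simulate_traces,
)

__all__ = ["RunConfig", "make_profile", "run_scenario"]


@dataclass
class RunConfig:
    """Complete, serializable description of one simulated experiment."""

    seed: int = 0
    # field of view
    n_pixels: int = 512
    pixel_size: float = 130.0
    # illumination
    profile_kind: str = "flattop"
    edge_ratio: float = 1.0 / 3.0  # gaussian: intensity at FOV edge / center
    plateau_fraction: float = 0.9  # flattop: plateau radius / FOV width
    edge_order: float = 20.0
    peak_intensity: float = 1.0
    # structures
    structure_kind: str = "grid"
    rows: int = 3
    cols: int = 4
    pitch: float = 20.0
    n_structures: int = 400
    rod_length: float = 2000.0
    rod_label_radius: float = 18.5
    rod_linkage_sd: float = 0.0
    rod_density: float = 1.0
    layout_margin: float | None = None  # nm; default from structure footprint
    # kinetics
    k_on: float = 2.0e6
    imager_concentration: float = 5.0e-9
    k_off: float = 2.0
    bleach_coeff: float = 0.0
    # emission / camera
    photon_yield: float = 150000.0
    background_rate: float = 20.0
    exposure: float = 0.1
    psf_sigma: float = 130.0
    loc_error_excess: float = 1.4
    # acquisition
    n_frames: int = 6000
    # analysis
    n_rings: int = 5
    pick_radius: float = 143.0
    max_dark_frames: int = 0
    qc_center_tol: float = 0.2
    qc_min_std_frac: float = 0.15
    oversampling: float = 40.0
    symmetry_deg: float = 180.0
    rot_step_deg: float = 1.0
    # stage toggles
    do_filter: bool = True
    do_nena: bool = True
    do_average: bool = True

    @property
    def fov(self) -> FieldOfView:
        return FieldOfView(n_pixels=self.n_pixels, pixel_size=self.pixel_size)

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.exposure

    def kinetics_model(self) -> KineticsModel:
        return KineticsModel(
            k_on=self.k_on,
            imager_concentration=self.imager_concentration,
            k_off=self.k_off,
            bleach_coeff=self.bleach_coeff,
        )

    def emission_model(self) -> EmissionModel:
        return EmissionModel(
            photon_yield=self.photon_yield,
            background_rate=self.background_rate,
            exposure=self.exposure,
            psf_sigma=self.psf_sigma,
            loc_error_excess=self.loc_error_excess,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls(**yaml.safe_load(f))


def make_profile(cfg: RunConfig, kind: str | None = None) -> IlluminationProfile:
    """Build the configured illumination profile centered on the FOV."""
    kind = kind or cfg.profile_kind
    fov = cfg.fov
    if kind == "gaussian":
        prof = IlluminationProfile(
            kind="gaussian", peak_intensity=cfg.peak_intensity,
            center=fov.center, gauss_sigma=1.0,
        )
        return calibrate_edge_ratio(prof, fov, cfg.edge_ratio)
    if kind == "flattop":
        return IlluminationProfile(
            kind="flattop", peak_intensity=cfg.peak_intensity, center=fov.center,
            plateau_radius=cfg.plateau_fraction * fov.width, edge_order=cfg.edge_order,
        )
    raise ValueError(f"unknown profile kind {kind!r}")


def simulate_fast(cfg: RunConfig):
    """Simulate a scenario via the fast (non-rendered) path.

    Returns ``(layout, events, locs, profile)``.
    """
    rng = np.random.default_rng(cfg.seed)
    fov = cfg.fov
    profile = make_profile(cfg)
    if cfg.structure_kind == "grid":
        structure = StructureModel(kind="grid", rows=cfg.rows, cols=cfg.cols, pitch=cfg.pitch)
        layout = make_layout(structure, cfg.n_structures, fov, seed=rng,
                             margin=cfg.layout_margin)
    elif cfg.structure_kind == "rod":
        layout = make_rod_phantom(
            length=cfg.rod_length, label_radius=cfg.rod_label_radius,
            linkage_sd=cfg.rod_linkage_sd, density=cfg.rod_density,
            fov=fov, seed=rng,
        )
    else:
        raise ValueError(f"unknown structure kind {cfg.structure_kind!r}")
    events = simulate_traces(layout, cfg.kinetics_model(), profile, cfg.duration_s, seed=rng)
    locs = events_to_localizations(
        events, cfg.emission_model(), profile, cfg.n_frames, fov, seed=rng
    )
    return layout, events, locs, profile


def run_scenario(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis pipeline on a simulated dataset.

    Returns a JSON-serializable report; if ``out_dir`` is given, writes
    ``report.json`` and the persisted config there.
    """
    layout, events, locs, profile = simulate_fast(cfg)
    report: dict = {"config": dataclasses.asdict(cfg), "n_events": int(len(events)),
                    "n_localizations": int(len(locs))}

    picks = kin.pick_by_ground_truth(
        locs, layout.structures, cfg.pixel_size, radius=cfg.pick_radius
    )
    pk_list = [
        kin.pick_kinetics(
            locs, p, cfg.exposure, cfg.n_frames,
            max_dark_frames=cfg.max_dark_frames,
            center_tol=cfg.qc_center_tol, min_std_frac=cfg.qc_min_std_frac,
        )
        for p in picks
    ]
    pk_table = pd.DataFrame(
        {
            "pick_id": [pk.pick_id for pk in pk_list],
            "structure_id": [pk.structure_id for pk in pk_list],
            "n_events": [pk.n_events for pk in pk_list],
            "mean_bright_time": [pk.mean_bright_time for pk in pk_list],
            "mean_frame": [pk.mean_frame for pk in pk_list],
            "std_frame": [pk.std_frame for pk in pk_list],
            "qc_pass": [pk.qc_pass for pk in pk_list],
        }
    )
    report["qc_pass_fraction"] = float(pk_table["qc_pass"].mean()) if len(pk_table) else np.nan

    centers = layout.structures[["x", "y"]].to_numpy()
    k_rings = min(cfg.n_rings, len(centers))
    segmap = segments.equal_count_rings(centers, k_rings, cfg.fov.center)
    summary = segments.per_segment_summary(
        locs, segmap, layout.structures["structure_id"].to_numpy(), pick_kinetics=pk_table
    )
    report["segments"] = summary.to_dict(orient="records")

    if len(pk_list):
        pooled = kin.bright_time_distribution([pk for pk in pk_list if len(pk.bright_times)])
        report["bright_time_mean"] = pooled["mean"]
        report["bright_time_std"] = pooled["std"]

    if cfg.do_filter and len(locs) >= 500:
        mix = postfilter.fit_photon_mixture(locs["photons"].to_numpy())
        report["photon_mixture"] = {
            "mu1": mix.mu1, "sigma1": mix.sigma1, "mu2": mix.mu2,
            "sigma2": mix.sigma2, "single_peak": mix.single_peak,
            "peak_ratio": mix.peak_ratio,
        }
        if not mix.single_peak:
            filtered, rep = postfilter.filter_multiemitter(locs, mix.threshold)
            report["filter"] = rep
            locs_for_imaging = filtered
        else:
            locs_for_imaging = locs
    else:
        locs_for_imaging = locs

    if cfg.do_nena:
        # NeNA runs on the unfiltered table (pick indices refer to it);
        # consecutive-frame pairs are unaffected by the photon cut
        try:
            fit = precision.nena(locs, picks, cfg.pixel_size)
            report["nena_nm"] = fit.sigma
        except ValueError:
            report["nena_nm"] = None

    if cfg.do_average and cfg.structure_kind == "grid":
        model_coords = StructureModel(
            kind="grid", rows=cfg.rows, cols=cfg.cols, pitch=cfg.pitch
        ).site_coords()
        good = {pk.pick_id for pk in pk_list if pk.qc_pass}
        coords = []
        px = cfg.pixel_size
        for p in picks:
            if p.pick_id not in good or len(p.indices) == 0:
                continue
            xy = _pick_xy(locs_for_imaging, p, px, cfg.pick_radius)
            if len(xy):
                coords.append(xy)
        if len(coords) >= 2:
            res = avg.average_picks(
                coords, model_coords, oversampling=cfg.oversampling,
                pixel_size=px, symmetry_deg=cfg.symmetry_deg,
                rot_step_deg=cfg.rot_step_deg,
            )
            fit = avg.spacing_fit(res.aligned_xy, cfg.pitch, axis="x")
            report["averaging"] = {
                "n_picks": len(coords),
                "n_iterations": res.n_iterations,
                "converged": res.converged,
                "spacing_nm": fit.distance,
                "peak_sigma_nm": fit.mean_sigma,
                "dip": fit.dip,
                "resolved": fit.resolved,
            }

    if cfg.structure_kind == "rod":
        theta = float(layout.structures["theta"].iloc[0])
        cx, cy = cfg.fov.center
        x = locs_for_imaging["x"].to_numpy() * cfg.pixel_size - cx
        y = locs_for_imaging["y"].to_numpy() * cfg.pixel_size - cy
        trans = -x * np.sin(theta) + y * np.cos(theta)
        rod = avg.rod_transverse_fit(trans)
        report["rod_transverse"] = rod

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out_dir / "config.yaml")
        with open(out_dir / "report.json", "w") as f:
            json.dump(report, f, indent=2, default=_jsonable)
    return report


def _pick_xy(locs: pd.DataFrame, pick, pixel_size: float, radius: float) -> np.ndarray:
    """Pick localizations as nm offsets from the pick center.

    Indices stored on the pick refer to the unfiltered table; after photon
    filtering rows may be gone, so membership is recomputed — from the
    ground-truth ``structure_id`` column when available, otherwise from the
    distance to the pick center.
    """
    xy = locs[["x", "y"]].to_numpy() * pixel_size
    d = xy - np.asarray(pick.center)
    if "structure_id" in locs.columns:
        sel = locs["structure_id"].to_numpy() == pick.structure_id
    else:
        sel = np.hypot(d[:, 0], d[:, 1]) <= radius
    return d[sel]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
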