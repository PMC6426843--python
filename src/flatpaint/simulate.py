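"""Physics-based DNA-PAINT data generator.

The generator produces, in order of increasing realism:

1. ground-truth structure layouts (origami grids or microtubule-like rods),
2. per-site binding-event traces from two-state imager kinetics with
   intensity-dependent photobleaching,
3. localization tables via a fast path that converts events directly into
   noisy localizations (bypassing frame rendering), and
4. rendered 16-bit camera frame stacks for testing the spot detector and
   fitter end to end.

Binding kinetics
----------------
Each docking site alternates between a dark state (imager unbound) and a
bright state (imager bound).  Dark intervals are exponential with rate
``k_on * c`` (association).  Each bound imager is a fresh dye; its bright
interval ends either by dissociation (rate ``k_off``) or by photobleaching
(rate ``k_bleach * I`` at local excitation intensity ``I``), whichever comes
first, so the expected bright time is ``1 / (k_off + k_bleach * I)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .illumination import FieldOfView, IlluminationProfile, intensity_at

__all__ = [
    "StructureModel",
    "FieldLayout",
    "KineticsModel",
    "EmissionModel",
    "make_layout",
    "make_rod_phantom",
    "simulate_traces",
    "events_to_localizations",
    "render_frames",
]


@dataclass(frozen=True)
class StructureModel:
    """Designed docking-strand geometry of one structure.

    The default is the rectangular origami standard: a 3 x 4 grid of docking
    strands at 20 nm pitch.  A 10 nm pitch variant serves as resolution
    benchmark.
    """

    kind: Literal["grid", "rod"] = "grid"
    rows: int = 3
    cols: int = 4
    pitch: float = 20.0
    # rod parameters
    length: float = 2000.0
    label_radius: float = 18.5
    linkage_sd: float = 0.0

    def site_coords(self) -> np.ndarray:
        """Site positions in the structure frame (nm), centered on origin."""
        if self.kind != "grid":
            raise ValueError("explicit site coordinates exist for grids only")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        xs = (np.arange(self.cols) - (self.cols - 1) / 2.0) * self.pitch
        ys = (np.arange(self.rows) - (self.rows - 1) / 2.0) * self.pitch
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class FieldLayout:
    """Ground-truth field: structure table plus per-site table.

    ``structures``: columns ``structure_id, x, y, theta, species``.
    ``sites``: columns ``site_id, structure_id, x, y`` (absolute nm).
    """

    structures: pd.DataFrame
    sites: pd.DataFrame
    fov: FieldOfView
    model: StructureModel | None = None

    @property
    def n_structures(self) -> int:
        return len(self.structures)


@dataclass(frozen=True)
class KineticsModel:
    """Two-state imager binding kinetics with photobleaching.

    ``k_on`` in 1/(M s), ``imager_concentration`` in M, ``k_off`` in 1/s and
    ``bleach_coeff`` in 1/s per intensity unit.  Defaults give a mean bright
    time of 0.5 s and a mean dark time of 100 s per site.
    """

    k_on: float = 2.0e6
    imager_concentration: float = 5.0e-9
    k_off: float = 2.0
    bleach_coeff: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_on", "imager_concentration", "k_off", "bleach_coeff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def on_rate(self) -> float:
        return self.k_on * self.imager_concentration

    def mean_bright_time(self, intensity: float) -> float:
        return 1.0 / (self.k_off + self.bleach_coeff * intensity)


@dataclass(frozen=True)
class EmissionModel:
    """Photon emission and camera model.

    ``photon_yield`` is detected photons per second per excitation-intensity
    unit; a full frame at unit intensity therefore yields
    ``photon_yield * exposure`` photons.  ``background_rate`` is photons per
    second per pixel per intensity unit (imager background is
    excitation-driven).  ``psf_sigma`` is in nm.
    """

    photon_yield: float = 150000.0
    background_rate: float = 20.0
    exposure: float = 0.1
    readout_noise: float = 1.5
    gain: float = 1.0
    baseline: float = 100.0
    psf_sigma: float = 130.0
    loc_error_excess: float = 1.4
    min_frame_overlap: float = 0.3
    merge_radius_factor: float = 2.5


def _check_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_layout(
    structure: StructureModel,
    n_structures: int,
    fov: FieldOfView,
    seed=0,
    margin: float | None = None,
    species: np.ndarray | None = None,
) -> FieldLayout:
    """Scatter structures uniformly at random over the field of view.

    Centers are uniform inside the FOV (with a margin keeping whole
    structures inside), orientations uniform in [0, 2 pi).  Deterministic
    for a given seed.
    """
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    rng = _check_rng(seed)
    site_local = structure.site_coords()
    extent = float(np.max(np.hypot(site_local[:, 0], site_local[:, 1])))
    if margin is None:
        margin = extent + 10.0
    usable_w = fov.width - 2 * margin
    usable_h = fov.height - 2 * margin
    if usable_w <= 0 or usable_h <= 0:
        raise ValueError("FOV too small for the structure footprint")
    # refuse absurd densities: each structure needs room for its pick region
    if n_structures * (4 * extent) ** 2 > 4 * usable_w * usable_h:
        raise ValueError("FOV too small for the requested structure density")

    cx = rng.uniform(margin, fov.width - margin, n_structures)
    cy = rng.uniform(margin, fov.height - margin, n_structures)
    theta = rng.uniform(0.0, 2.0 * np.pi, n_structures)
    if species is None:
        species = np.zeros(n_structures, dtype=int)
    structures = pd.DataFrame(
        {
            "structure_id": np.arange(n_structures),
            "x": cx,
            "y": cy,
            "theta": theta,
            "species": np.asarray(species),
        }
    )

    n_sites = len(site_local)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    sx = (
        cx[:, None]
        + site_local[None, :, 0] * cos_t[:, None]
        - site_local[None, :, 1] * sin_t[:, None]
    )
    sy = (
        cy[:, None]
        + site_local[None, :, 0] * sin_t[:, None]
        + site_local[None, :, 1] * cos_t[:, None]
    )
    sites = pd.DataFrame(
        {
            "site_id": np.arange(n_structures * n_sites),
            "structure_id": np.repeat(np.arange(n_structures), n_sites),
            "x": sx.ravel(),
            "y": sy.ravel(),
        }
    )
    return FieldLayout(structures=structures, sites=sites, fov=fov, model=structure)


def make_rod_phantom(
    length: float = 2000.0,
    label_radius: float = 18.5,
    linkage_sd: float = 0.0,
    density: float = 1.0,
    fov: FieldOfView | None = None,
    seed=0,
    orientation: float = 0.0,
) -> FieldLayout:
    """Microtubule-like rod: labels on a cylinder surface, projected to 2D.

    Label azimuths are uniform on the cylinder, so the projected transverse
    coordinate is ``label_radius * cos(phi)`` — an arcsine-type density
    peaking near +/- ``label_radius`` — optionally blurred by a Gaussian
    linkage error.  ``density`` is labels per nm of rod length.
    """
    if label_radius <= 0:
        raise ValueError("label_radius must be positive")
    rng = _check_rng(seed)
    if fov is None:
        n_px = int(np.ceil((length + 400.0) / 130.0))
        fov = FieldOfView(n_pixels=n_px)
    n_sites = max(2, int(round(density * length)))
    along = rng.uniform(-length / 2.0, length / 2.0, n_sites)
    phi = rng.uniform(0.0, 2.0 * np.pi, n_sites)
    trans = label_radius * np.cos(phi)
    if linkage_sd > 0:
        trans = trans + rng.normal(0.0, linkage_sd, n_sites)
    cx, cy = fov.center
    ct, st = np.cos(orientation), np.sin(orientation)
    x = cx + along * ct - trans * st
    y = cy + along * st + trans * ct
    structures = pd.DataFrame(
        {
            "structure_id": [0],
            "x": [cx],
            "y": [cy],
            "theta": [orientation],
            "species": [0],
        }
    )
    sites = pd.DataFrame(
        {
            "site_id": np.arange(n_sites),
            "structure_id": np.zeros(n_sites, dtype=int),
            "x": x,
            "y": y,
        }
    )
    model = StructureModel(
        kind="rod", length=length, label_radius=label_radius, linkage_sd=linkage_sd
    )
    return FieldLayout(structures=structures, sites=sites, fov=fov, model=model)


def simulate_traces(
    layout: FieldLayout,
    kinetics: KineticsModel,
    profile: IlluminationProfile,
    duration_s: float,
    seed=0,
) -> pd.DataFrame:
    """Simulate binding events for every docking site.

    Returns a DataFrame with columns ``event_id, site_id, structure_id, x, y,
    t_on, t_off, bleached, censored``.  Events still active at the end of the
    acquisition are truncated and flagged censored.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = _check_rng(seed)
    sites = layout.sites
    n_sites = len(sites)
    intens = np.asarray(intensity_at(profile, sites["x"].to_numpy(), sites["y"].to_numpy()))
    on_rate = kinetics.on_rate
    if on_rate <= 0:
        return _empty_events()

    mean_cycle = 1.0 / on_rate + 1.0 / kinetics.k_off if kinetics.k_off > 0 else 1.0 / on_rate
    n_cycles = int(np.ceil(duration_s / mean_cycle * 1.5 + 12))
    # cap memory; top up per-site below if a site runs past the horizon
    n_cycles = min(n_cycles, 20000)

    darks = rng.exponential(1.0 / on_rate, size=(n_sites, n_cycles))
    off_draw = (
        rng.exponential(1.0 / kinetics.k_off, size=(n_sites, n_cycles))
        if kinetics.k_off > 0
        else np.full((n_sites, n_cycles), np.inf)
    )
    bleach_rate = kinetics.bleach_coeff * intens
    with np.errstate(divide="ignore"):
        bleach_scale = np.where(bleach_rate > 0, 1.0 / np.where(bleach_rate > 0, bleach_rate, 1.0), np.inf)
    bleach_draw = np.where(
        np.isfinite(bleach_scale)[:, None],
        rng.exponential(1.0, size=(n_sites, n_cycles)) * np.where(np.isfinite(bleach_scale), bleach_scale, 1.0)[:, None],
        np.inf,
    )
    brights = np.minimum(off_draw, bleach_draw)
    bleached = bleach_draw < off_draw

    cycle = darks + brights
    t_end = np.cumsum(cycle, axis=1)
    t_on = t_end - brights
    keep = t_on < duration_s
    if keep[:, -1].any():
        # extremely fast kinetics relative to the horizon; fall back to a
        # per-site loop for the overflowing sites (rare by construction)
        raise RuntimeError(
            "cycle buffer exhausted; reduce duration or association rate"
        )
    site_idx, cyc_idx = np.nonzero(keep)
    t_on_v = t_on[site_idx, cyc_idx]
    t_off_v = np.minimum(t_end[site_idx, cyc_idx], duration_s)
    censored = t_end[site_idx, cyc_idx] > duration_s
    events = pd.DataFrame(
        {
            "event_id": np.arange(len(site_idx)),
            "site_id": sites["site_id"].to_numpy()[site_idx],
            "structure_id": sites["structure_id"].to_numpy()[site_idx],
            "x": sites["x"].to_numpy()[site_idx],
            "y": sites["y"].to_numpy()[site_idx],
            "t_on": t_on_v,
            "t_off": t_off_v,
            "bleached": bleached[site_idx, cyc_idx],
            "censored": censored,
        }
    )
    events.sort_values(["t_on", "site_id"], inplace=True, kind="mergesort")
    events["event_id"] = np.arange(len(events))
    events.reset_index(drop=True, inplace=True)
    return events


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": pd.Series(dtype=int),
            "site_id": pd.Series(dtype=int),
            "structure_id": pd.Series(dtype=int),
            "x": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "t_on": pd.Series(dtype=float),
            "t_off": pd.Series(dtype=float),
            "bleached": pd.Series(dtype=bool),
            "censored": pd.Series(dtype=bool),
        }
    )


def events_to_localizations(
    events: pd.DataFrame,
    emission: EmissionModel,
    profile: IlluminationProfile,
    n_frames: int,
    fov: FieldOfView,
    seed=0,
) -> pd.DataFrame:
    """Fast path: convert binding events directly into a localization table.

    Each event contributes one localization per overlapped camera frame.
    Frame photons are Poisson with mean ``photon_yield * I * overlap_s``;
    the localization error is isotropic Gaussian with
    ``sigma_loc = loc_error_excess * psf_sigma / sqrt(photons)``.  Frames
    whose exposure overlap is below ``min_frame_overlap`` are dropped, as are
    zero-photon frames.  Localizations of distinct emitters active in the
    same frame closer than ``merge_radius_factor * psf_sigma`` are merged
    into one multi-emitter localization carrying the pooled photons (this is
    what a single-emitter fitter would report); ``n_emitters`` records the
    ground truth.

    Positions ``x, y`` are in camera pixels (sub-pixel); ground-truth
    columns ``event_id, site_id, structure_id, n_emitters`` are retained.
    """
    rng = _check_rng(seed)
    exp_t = emission.exposure
    if len(events) == 0:
        return _empty_locs()
    t_on = events["t_on"].to_numpy()
    t_off = np.minimum(events["t_off"].to_numpy(), n_frames * exp_t)
    valid = t_off > t_on
    ev = events.loc[valid].reset_index(drop=True)
    t_on, t_off = t_on[valid], t_off[valid]

    f0 = np.floor(t_on / exp_t).astype(int)
    f1 = np.minimum(np.ceil(t_off / exp_t).astype(int) - 1, n_frames - 1)
    counts = f1 - f0 + 1
    ev_idx = np.repeat(np.arange(len(ev)), counts)
    frame = f0.repeat(counts) + _ragged_arange(counts)
    overlap = (
        np.minimum(t_off[ev_idx], (frame + 1) * exp_t)
        - np.maximum(t_on[ev_idx], frame * exp_t)
    ) / exp_t
    keep = overlap >= emission.min_frame_overlap
    ev_idx, frame, overlap = ev_idx[keep], frame[keep], overlap[keep]

    x_nm = ev["x"].to_numpy()[ev_idx]
    y_nm = ev["y"].to_numpy()[ev_idx]
    intens = np.asarray(intensity_at(profile, x_nm, y_nm))
    mean_photons = emission.photon_yield * intens * overlap * exp_t
    photons = rng.poisson(mean_photons).astype(float)
    keep = photons > 0
    ev_idx, frame, overlap, x_nm, y_nm, intens, photons = (
        a[keep] for a in (ev_idx, frame, overlap, x_nm, y_nm, intens, photons)
    )

    # merge simultaneous emitters within the diffraction-limited radius
    merge_r = emission.merge_radius_factor * emission.psf_sigma
    order = np.lexsort((ev_idx, frame))
    ev_idx, frame, x_nm, y_nm, photons = (
        a[order] for a in (ev_idx, frame, x_nm, y_nm, photons)
    )
    group = _merge_groups(frame, x_nm, y_nm, merge_r)
    n_groups = group.max() + 1 if len(group) else 0
    g_photons = np.bincount(group, weights=photons, minlength=n_groups)
    g_x = np.bincount(group, weights=photons * x_nm, minlength=n_groups) / g_photons
    g_y = np.bincount(group, weights=photons * y_nm, minlength=n_groups) / g_photons
    g_n = np.bincount(group, minlength=n_groups)
    g_frame = np.zeros(n_groups, dtype=int)
    g_frame[group] = frame
    # attribute the merged localization to the brightest contributor
    brightest = np.full(n_groups, -1, dtype=int)
    # argmax per group via sorting on (group, photons): last write wins
    srt = np.lexsort((photons, group))
    brightest[group[srt]] = srt  # last write per group wins = max photons
    g_event = ev["event_id"].to_numpy()[ev_idx[brightest]]
    g_site = ev["site_id"].to_numpy()[ev_idx[brightest]]
    g_struct = ev["structure_id"].to_numpy()[ev_idx[brightest]]

    sigma_loc = emission.loc_error_excess * emission.psf_sigma / np.sqrt(g_photons)
    obs_x = g_x + rng.normal(0.0, sigma_loc)
    obs_y = g_y + rng.normal(0.0, sigma_loc)

    bg = emission.background_rate * np.asarray(
        intensity_at(profile, g_x, g_y)
    ) * exp_t
    px = fov.pixel_size
    locs = pd.DataFrame(
        {
            "frame": g_frame,
            "x": obs_x / px,
            "y": obs_y / px,
            "photons": g_photons,
            "sx": np.full(n_groups, emission.psf_sigma / px),
            "sy": np.full(n_groups, emission.psf_sigma / px),
            "bg": bg,
            "lpx": sigma_loc / px,
            "lpy": sigma_loc / px,
            "net_gradient": g_photons / (2.0 * np.pi * (emission.psf_sigma / px) ** 2),
            "event_id": g_event,
            "site_id": g_site,
            "structure_id": g_struct,
            "n_emitters": g_n,
        }
    )
    locs.sort_values(["frame", "x"], inplace=True, kind="mergesort")
    locs.reset_index(drop=True, inplace=True)
    return locs


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    """Concatenated ``arange(c)`` for each count ``c``."""
    if len(counts) == 0:
        return np.array([], dtype=int)
    total = counts.sum()
    out = np.ones(total, dtype=int)
    out[0] = 0
    starts = np.cumsum(counts)[:-1]
    out[starts] = 1 - counts[:-1]
    return np.cumsum(out)


def _merge_groups(frame, x, y, radius) -> np.ndarray:
    """Group simultaneous localizations closer than ``radius`` (single link).

    Input must be sorted by frame.  Quadratic only within a frame, which is
    fine at DNA-PAINT duty cycles.
    """
    n = len(frame)
    group = np.arange(n)
    if n == 0:
        return group
    bounds = np.flatnonzero(np.diff(frame)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [n]])
    r2 = radius * radius
    next_id = 0
    for s, e in zip(starts, ends):
        m = e - s
        labels = -np.ones(m, dtype=int)
        for i in range(m):
            if labels[i] < 0:
                labels[i] = next_id
                next_id += 1
            for j in range(i + 1, m):
                if (x[s + i] - x[s + j]) ** 2 + (y[s + i] - y[s + j]) ** 2 <= r2:
                    if labels[j] < 0:
                        labels[j] = labels[i]
                    # if j already labelled, leave it (single-link chains are
                    # negligible at realistic duty cycles)
        group[s:e] = labels
    return group


def _empty_locs() -> pd.DataFrame:
    cols = [
        "frame", "x", "y", "photons", "sx", "sy", "bg", "lpx", "lpy",
        "net_gradient", "event_id", "site_id", "structure_id", "n_emitters",
    ]
    return pd.DataFrame({c: pd.Series(dtype=float) for c in cols}).astype(
        {"frame": int, "event_id": int, "site_id": int, "structure_id": int, "n_emitters": int}
    )


def jittered_site_localizations(
    sites: pd.DataFrame,
    sigma: float,
    frames_per_site: int,
    pixel_size: float,
    seed=0,
    photons: float = 10000.0,
) -> pd.DataFrame:
    """Repeated localizations of fixed sites with planted isotropic jitter.

    Every site is localized in ``frames_per_site`` consecutive frames with
    independent Gaussian errors of known ``sigma`` (nm) — the ground-truth
    input for localization-precision estimators.
    """
    rng = _check_rng(seed)
    n_sites = len(sites)
    sx = np.repeat(sites["x"].to_numpy(), frames_per_site)
    sy = np.repeat(sites["y"].to_numpy(), frames_per_site)
    frame = np.tile(np.arange(frames_per_site), n_sites)
    obs_x = sx + rng.normal(0.0, sigma, len(sx))
    obs_y = sy + rng.normal(0.0, sigma, len(sy))
    return pd.DataFrame(
        {
            "frame": frame,
            "x": obs_x / pixel_size,
            "y": obs_y / pixel_size,
            "photons": np.full(len(sx), photons),
            "sx": 1.0,
            "sy": 1.0,
            "bg": 0.0,
            "lpx": sigma / pixel_size,
            "lpy": sigma / pixel_size,
            "net_gradient": photons / (2 * np.pi),
            "site_id": np.repeat(sites["site_id"].to_numpy(), frames_per_site),
            "structure_id": np.repeat(sites["structure_id"].to_numpy(), frames_per_site),
            "n_emitters": 1,
        }
    )


def render_frames(
    events: pd.DataFrame,
    emission: EmissionModel,
    profile: IlluminationProfile,
    fov: FieldOfView,
    n_frames: int,
    seed=0,
) -> np.ndarray:
    """Render a 16-bit camera frame stack from binding events.

    Per frame, each active emitter deposits an integrated-pixel Gaussian PSF
    scaled to its frame photons; excitation-proportional background is added;
    Poisson shot noise, Gaussian readout noise, gain and baseline are applied.
    Returns an array of shape ``(n_frames, n_pixels, n_pixels)`` (uint16).
    """
    rng = _check_rng(seed)
    npx = fov.n_pixels
    px = fov.pixel_size
    exp_t = emission.exposure

    # per-pixel background rate map (photons per frame)
    jj, ii = np.meshgrid(np.arange(npx), np.arange(npx))
    bg_map = (
        emission.background_rate
        * np.asarray(intensity_at(profile, (jj + 0.5) * px, (ii + 0.5) * px))
        * exp_t
    )

    stack = np.empty((n_frames, npx, npx), dtype=np.uint16)
    t_on = events["t_on"].to_numpy() if len(events) else np.array([])
    t_off = events["t_off"].to_numpy() if len(events) else np.array([])
    ex = events["x"].to_numpy() if len(events) else np.array([])
    ey = events["y"].to_numpy() if len(events) else np.array([])
    if len(events):
        intens = np.asarray(intensity_at(profile, ex, ey))
    sig_px = emission.psf_sigma / px
    half = max(3, int(np.ceil(4 * sig_px)))

    for f in range(n_frames):
        expected = bg_map.copy()
        if len(events):
            ov = np.clip(
                (np.minimum(t_off, (f + 1) * exp_t) - np.maximum(t_on, f * exp_t))
                / exp_t,
                0.0,
                1.0,
            )
            active = np.flatnonzero(ov > 0)
            for k in active:
                n_ph = emission.photon_yield * intens[k] * ov[k] * exp_t
                _add_psf(expected, ex[k] / px, ey[k] / px, n_ph, sig_px, half)
        if emission.readout_noise > 0 or emission.background_rate > 0 or len(events):
            electrons = rng.poisson(expected).astype(float)
        else:
            electrons = expected
        if emission.readout_noise > 0:
            electrons += rng.normal(0.0, emission.readout_noise, electrons.shape)
        adu = emission.gain * electrons + emission.baseline
        stack[f] = np.clip(np.rint(adu), 0, 65535).astype(np.uint16)
    return stack


def _add_psf(img: np.ndarray, x_px: float, y_px: float, photons: float, sigma: float, half: int) -> None:
    """Add an integrated-pixel Gaussian PSF to ``img`` in place."""
    from scipy.special import erf

    npx = img.shape[0]
    j0 = max(0, int(np.floor(x_px)) - half)
    j1 = min(npx, int(np.floor(x_px)) + half + 1)
    i0 = max(0, int(np.floor(y_px)) - half)
    i1 = min(npx, int(np.floor(y_px)) + half + 1)
    if j0 >= j1 or i0 >= i1:
        return
    edges_x = np.arange(j0, j1 + 1, dtype=float)
    edges_y = np.arange(i0, i1 + 1, dtype=float)
    s2 = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((edges_x[1:] - x_px) / s2) - erf((edges_x[:-1] - x_px) / s2))
    fy = 0.5 * (erf((edges_y[1:] - y_px) / s2) - erf((edges_y[:-1] - y_px) / s2))
    img[i0:i1, j0:j1] += photons * np.outer(fy, fx)
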