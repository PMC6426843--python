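"""Binding-kinetics analysis of localization traces.

Localizations grouped per pick (one structure's region of interest) are
linked over frames into binding events; consecutive-frame runs form one
event whose *bright time* is the run length times the exposure, and the
gaps between events are *dark times*.  Pick-level temporal statistics (the
mean localization frame and its standard deviation) separate repetitive,
specific binding from one-off sticking events, and per-pick mean bright
times separate docking-strand species with different unbinding rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.mixture import GaussianMixture

__all__ = [
    "Pick",
    "PickKinetics",
    "link_events",
    "pick_qc",
    "pick_kinetics",
    "pick_by_ground_truth",
    "bright_time_distribution",
    "separate_populations",
]


@dataclass
class Pick:
    """Region of interest holding one structure's localizations."""

    pick_id: int
    structure_id: int
    indices: np.ndarray  # row indices into the localization table
    center: tuple[float, float]  # nm


@dataclass
class PickKinetics:
    """Temporal trace summary for one pick."""

    pick_id: int
    structure_id: int
    n_events: int
    bright_times: np.ndarray  # seconds, censored events excluded
    dark_times: np.ndarray  # seconds
    mean_frame: float
    std_frame: float
    n_locs: int
    qc_pass: bool = False

    @property
    def mean_bright_time(self) -> float:
        return float(np.mean(self.bright_times)) if len(self.bright_times) else np.nan


def link_events(
    frames: np.ndarray, exposure: float, max_dark_frames: int = 0, n_frames: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Link sorted localization frames into binding events.

    Consecutive frames (gaps of at most ``max_dark_frames`` bridged) form one
    event.  Returns ``(bright_times_s, dark_times_s, censored)`` where
    ``censored`` flags events touching the acquisition boundaries (their
    duration is a lower bound).  Bright time = number of linked frames times
    the exposure; dark times are the gaps between events in seconds.
    """
    frames = np.unique(np.asarray(frames, dtype=int))
    if len(frames) == 0:
        return np.array([]), np.array([]), np.array([], dtype=bool)
    gaps = np.diff(frames)
    breaks = np.flatnonzero(gaps > max_dark_frames + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(frames) - 1]])
    first = frames[starts]
    last = frames[ends]
    bright = (last - first + 1) * exposure
    dark = (first[1:] - last[:-1] - 1) * exposure
    censored = np.zeros(len(first), dtype=bool)
    censored[0] = first[0] == 0
    if n_frames is not None:
        censored[-1] |= last[-1] >= n_frames - 1
    return bright, dark, censored


def pick_kinetics(
    locs: pd.DataFrame,
    pick: Pick,
    exposure: float,
    n_frames: int,
    max_dark_frames: int = 0,
    center_tol: float = 0.2,
    min_std_frac: float = 0.15,
) -> PickKinetics:
    """Event statistics and temporal QC for one pick."""
    frames = locs["frame"].to_numpy()[pick.indices]
    bright, dark, censored = link_events(
        frames, exposure, max_dark_frames=max_dark_frames, n_frames=n_frames
    )
    mean_frame = float(np.mean(frames)) if len(frames) else np.nan
    std_frame = float(np.std(frames)) if len(frames) else np.nan
    pk = PickKinetics(
        pick_id=pick.pick_id,
        structure_id=pick.structure_id,
        n_events=len(bright),
        bright_times=bright[~censored],
        dark_times=dark,
        mean_frame=mean_frame,
        std_frame=std_frame,
        n_locs=len(frames),
    )
    pk.qc_pass = pick_qc(pk, n_frames, center_tol=center_tol, min_std_frac=min_std_frac)
    return pk


def pick_qc(
    pk: PickKinetics, n_frames: int, center_tol: float = 0.2, min_std_frac: float = 0.15
) -> bool:
    """Temporal QC: repetitive binding spans the whole acquisition.

    Specific, repetitive binding puts the mean localization frame near half
    the acquisition with a large spread (a uniform arrival pattern has
    ``std = n_frames / sqrt(12) = 0.29 n_frames``); a one-off burst sits at
    its time of occurrence with a tiny spread.  Pass requires the mean frame
    within ``center_tol * n_frames`` of the midpoint and the frame std at
    least ``min_std_frac * n_frames``.
    """
    if pk.n_locs < 2 or not np.isfinite(pk.mean_frame):
        return False
    centered = abs(pk.mean_frame - n_frames / 2.0) <= center_tol * n_frames
    spread = pk.std_frame >= min_std_frac * n_frames
    return bool(centered and spread)


def pick_by_ground_truth(
    locs: pd.DataFrame,
    structures: pd.DataFrame,
    pixel_size: float,
    radius: float = 143.0,
) -> list[Pick]:
    """Assign localizations to structures by proximity to known centers.

    Each localization within ``radius`` nm of a structure center joins that
    structure's pick; a localization within the radius of several centers
    goes to the nearest.  Structures without localizations yield empty
    picks (retained).
    """
    centers = structures[["x", "y"]].to_numpy()
    ids = structures["structure_id"].to_numpy()
    if len(locs):
        xy = locs[["x", "y"]].to_numpy() * pixel_size
        tree = cKDTree(centers)
        dist, nearest = tree.query(xy, k=1)
        ok = dist <= radius
    else:
        nearest = np.array([], dtype=int)
        ok = np.array([], dtype=bool)
    picks = []
    for j, sid in enumerate(ids):
        idx = np.flatnonzero(ok & (nearest == j))
        picks.append(
            Pick(pick_id=j, structure_id=int(sid), indices=idx, center=tuple(centers[j]))
        )
    return picks


def bright_time_distribution(
    kinetics_list: list[PickKinetics], bins: int | str = "auto"
) -> dict:
    """Pooled bright-time distribution over picks.

    Censored events are already excluded at the pick level.  Returns the
    pooled sample with its mean, standard deviation and a histogram — the
    standard deviation is the quantity whose Gaussian-to-flat-top ratio
    measures illumination-induced broadening.
    """
    pooled = np.concatenate([pk.bright_times for pk in kinetics_list]) if kinetics_list else np.array([])
    if len(pooled) == 0:
        raise ValueError("no bright times to pool")
    hist, edges = np.histogram(pooled, bins=bins)
    return {
        "bright_times": pooled,
        "mean": float(np.mean(pooled)),
        "std": float(np.std(pooled, ddof=1)) if len(pooled) > 1 else 0.0,
        "hist": hist,
        "bin_edges": edges,
    }


def separate_populations(
    mean_bright_times: np.ndarray,
    overlap_flag_threshold: float = 0.5,
    seed: int = 0,
) -> dict:
    """Two-component separation of per-pick mean bright times.

    Fits a two-component Gaussian mixture in the log domain, assigns each
    pick to a component, and reports the component means (back-transformed,
    seconds), the assignment, and the overlap coefficient of the two fitted
    densities (integral of the pointwise minimum).  A fit whose components
    overlap more than ``overlap_flag_threshold`` — or that collapses to one
    cluster — is flagged non-separable.
    """
    x = np.asarray(mean_bright_times, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) < 2:
        raise ValueError("need at least 2 picks")
    logx = np.log(x).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=5).fit(logx)
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(logx)
    bic_prefers_two = gm.bic(logx) < gm1.bic(logx) - 6.0
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    labels_raw = gm.predict(logx)
    labels = np.where(labels_raw == order[0], 0, 1)

    # overlap coefficient of the two unit-normalized component densities:
    # 1 for identical components, ~0 for well-separated ones
    grid = np.linspace(logx.min() - 3 * sds.max(), logx.max() + 3 * sds.max(), 2001)
    pdfs = [
        np.exp(-((grid - m) ** 2) / (2 * s**2)) / (s * np.sqrt(2 * np.pi))
        for m, s in zip(means, sds)
    ]
    overlap = float(np.trapezoid(np.minimum(pdfs[0], pdfs[1]), grid))
    # Ashman's D: separation of the two component means in pooled-sd units;
    # D >= 2 is the usual criterion for a genuinely bimodal mixture
    ashman_d = float(np.sqrt(2.0) * abs(means[1] - means[0]) / np.sqrt(sds[0] ** 2 + sds[1] ** 2))
    degenerate = (
        not bic_prefers_two
        or ashman_d < 2.0
        or min(weights) < 0.02
    )
    return {
        "component_means_s": np.exp(means),
        "component_sds_log": sds,
        "weights": weights,
        "assignment": labels,
        "overlap": overlap,
        "ashman_d": ashman_d,
        "separable": bool(not degenerate and overlap <= overlap_flag_threshold),
    }
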