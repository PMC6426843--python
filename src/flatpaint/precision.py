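"""Nearest-neighbor analysis (NeNA) of localization precision.

A molecule localized in two consecutive frames yields two independent draws
from the same error distribution; the planar distance between them follows

    p(d) = (d / (2 sigma^2)) * exp(-d^2 / (4 sigma^2)),

a Rayleigh density with scale ``sqrt(2) sigma`` whose single parameter is
the per-localization precision ``sigma``.  Distances between *different*
emitters contaminate the sample, so the histogram is fitted with the
same-molecule term plus a broad peaked correction (nearest distinct site)
and a linear background term, with all weights free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

__all__ = ["NenaFit", "consecutive_frame_distances", "nena"]


@dataclass
class NenaFit:
    sigma: float  # nm
    weights: tuple[float, float, float]  # same-molecule, correction, linear
    correction_center: float
    correction_sd: float
    residual: float
    n_pairs: int


def consecutive_frame_distances(
    locs: pd.DataFrame, picks, pixel_size: float, max_distance: float = 200.0
) -> np.ndarray:
    """Distances (nm) from each localization to its nearest neighbor in the
    next frame within the same pick.

    ``picks`` is an iterable of objects with an ``indices`` attribute
    (row indices into ``locs``); pass a single pseudo-pick covering the
    whole table to pool globally.
    """
    out: list[np.ndarray] = []
    frames_all = locs["frame"].to_numpy()
    x_all = locs["x"].to_numpy() * pixel_size
    y_all = locs["y"].to_numpy() * pixel_size
    for pick in picks:
        idx = np.asarray(pick.indices)
        if len(idx) < 2:
            continue
        frames = frames_all[idx]
        order = np.argsort(frames, kind="stable")
        idx = idx[order]
        frames = frames[order]
        xy = np.column_stack([x_all[idx], y_all[idx]])
        uniq = np.unique(frames)
        next_of = {f: f + 1 for f in uniq}
        by_frame = {f: xy[frames == f] for f in uniq}
        for f in uniq:
            nxt = by_frame.get(next_of[f])
            if nxt is None or len(nxt) == 0:
                continue
            tree = cKDTree(nxt)
            d, _ = tree.query(by_frame[f], k=1)
            out.append(np.asarray(d))
    if not out:
        return np.array([])
    d = np.concatenate(out)
    return d[d <= max_distance]


def _nena_model(d, w1, sigma, w2, dc, sc, w3):
    same = w1 * (d / (2.0 * sigma**2)) * np.exp(-(d**2) / (4.0 * sigma**2))
    corr = w2 * np.exp(-((d - dc) ** 2) / (2.0 * sc**2)) / (sc * np.sqrt(2 * np.pi))
    lin = w3 * d
    return same + corr + lin


def nena(
    locs: pd.DataFrame,
    picks,
    pixel_size: float,
    min_pairs: int = 1000,
    max_distance: float | None = None,
) -> NenaFit:
    """Estimate the localization precision from consecutive-frame distances.

    Requires at least ``min_pairs`` nearest-neighbor pairs.  The histogram
    of distances is fitted with the same-molecule density plus correction
    terms; the same-molecule ``sigma`` (nm) is the NeNA precision.
    """
    d = consecutive_frame_distances(
        locs, picks, pixel_size, max_distance=max_distance or 200.0
    )
    if len(d) < min_pairs:
        raise ValueError(f"need >= {min_pairs} consecutive-frame pairs, got {len(d)}")
    hist, edges = np.histogram(d, bins=100, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # the same-molecule mode sits at sigma*sqrt(2)
    mode = centers[np.argmax(hist)]
    s0 = max(mode / np.sqrt(2.0), 0.3)
    dmax = float(d.max())
    p0 = [0.8, s0, 0.1, min(6 * s0, dmax), max(2 * s0, 1.0), 1e-4]
    lo = [0.0, 0.05, 0.0, 0.0, 0.1, 0.0]
    hi = [10.0, dmax, 10.0, dmax, dmax, 1.0]
    popt, _ = curve_fit(_nena_model, centers, hist, p0=p0, bounds=(lo, hi), maxfev=60000)
    resid = float(np.sum((_nena_model(centers, *popt) - hist) ** 2))
    return NenaFit(
        sigma=float(popt[1]),
        weights=(float(popt[0]), float(popt[2]), float(popt[5])),
        correction_center=float(popt[3]),
        correction_sd=float(popt[4]),
        residual=resid,
        n_pairs=int(len(d)),
    )
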