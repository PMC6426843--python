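"""Equal-count concentric-ring segmentation of a field of view.

Radial trends (detection efficiency, bright times, photon counts, precision)
are quantified by splitting the imaged structures into K concentric rings
around the beam center such that every ring holds the same number of
structures (to within one).  Structures — not localizations — are the
segmentation unit; each structure's localizations inherit its ring label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SegmentMap", "equal_count_rings", "per_segment_summary"]


@dataclass
class SegmentMap:
    """Ring labels (1..K) per structure plus ring boundary radii in nm."""

    origin: tuple[float, float]
    boundaries: np.ndarray  # K-1 inner boundaries, ascending
    labels: np.ndarray  # per-structure ring label, 1-based
    radii: np.ndarray  # per-structure radial distance

    @property
    def n_segments(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0


def equal_count_rings(centers: np.ndarray, k: int, origin: tuple[float, float]) -> SegmentMap:
    """Partition structure centers into K equal-count concentric rings.

    Structures are ranked by distance from ``origin`` (ties broken by input
    order); ring ``j`` (0-based) receives ranks ``[floor(j N / K),
    floor((j+1) N / K))``.  Boundary radii are midpoints between the last
    structure of one ring and the first of the next.
    """
    centers = np.asarray(centers, dtype=float)
    n = len(centers)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot split {n} structures into {k} rings")
    r = np.hypot(centers[:, 0] - origin[0], centers[:, 1] - origin[1])
    order = np.argsort(r, kind="stable")
    labels = np.empty(n, dtype=int)
    cuts = [(j * n) // k for j in range(k + 1)]
    for j in range(k):
        labels[order[cuts[j] : cuts[j + 1]]] = j + 1
    r_sorted = r[order]
    boundaries = np.array(
        [0.5 * (r_sorted[cuts[j] - 1] + r_sorted[cuts[j]]) for j in range(1, k)]
    )
    return SegmentMap(origin=tuple(origin), boundaries=boundaries, labels=labels, radii=r)


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return (np.nan, np.nan)
    m = float(np.mean(x))
    sem = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return m, sem


def per_segment_summary(
    locs: pd.DataFrame,
    segmap: SegmentMap,
    structure_ids: np.ndarray,
    pick_kinetics: pd.DataFrame | None = None,
    nena_by_segment: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Per-ring summary statistics with SEM error bars.

    ``structure_ids`` maps the rows of ``segmap.labels`` to structure ids.
    ``locs`` must carry a ``structure_id`` column (ground truth or from the
    picker).  ``pick_kinetics`` (optional) is the per-pick kinetics table
    with columns ``structure_id, n_events, mean_bright_time`` and per-event
    bright times; events/structure and bright-time statistics come from it.
    """
    seg_of_structure = pd.Series(segmap.labels, index=np.asarray(structure_ids))
    k = segmap.n_segments
    rows = []
    for seg in range(1, k + 1):
        members = seg_of_structure.index[seg_of_structure.values == seg]
        seg_locs = locs[locs["structure_id"].isin(members)] if len(locs) else locs
        row: dict = {"segment": seg, "n_structures": len(members)}
        row["n_localizations"] = int(len(seg_locs))
        ph_mean, ph_sem = _mean_sem(seg_locs["photons"].to_numpy()) if len(seg_locs) else (np.nan, np.nan)
        row["photons_mean"], row["photons_sem"] = ph_mean, ph_sem
        if pick_kinetics is not None and len(pick_kinetics):
            pk = pick_kinetics[pick_kinetics["structure_id"].isin(members)]
            ev_mean, ev_sem = _mean_sem(pk["n_events"].to_numpy())
            row["events_per_structure_mean"], row["events_per_structure_sem"] = ev_mean, ev_sem
            bt = pk["mean_bright_time"].to_numpy()
            bt = bt[np.isfinite(bt)]
            bt_mean, bt_sem = _mean_sem(bt)
            row["bright_time_mean"], row["bright_time_sem"] = bt_mean, bt_sem
        if nena_by_segment is not None:
            row["nena_nm"] = nena_by_segment.get(seg, np.nan)
        row["flagged_empty"] = len(members) == 0
        rows.append(row)
    return pd.DataFrame(rows)
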