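"""Figure helpers for QC and profile diagnostics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["qc_scatter", "line_profile_figure"]


def qc_scatter(pick_kinetics_table, n_frames: int, path=None):
    """Mean localization frame vs its std, one dot per pick.

    Repetitive (specific) picks cluster at mean ~ n_frames/2 with a large
    std; one-off sticking events scatter along the mean-frame axis with a
    small std and fail QC (open markers).
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    t = pick_kinetics_table
    good = t["qc_pass"].to_numpy().astype(bool)
    ax.scatter(t["mean_frame"][good], t["std_frame"][good], s=12, label="pass")
    ax.scatter(t["mean_frame"][~good], t["std_frame"][~good], s=12,
               facecolors="none", edgecolors="tab:red", label="fail")
    ax.axvline(n_frames / 2, color="gray", lw=0.5)
    ax.set_xlabel("mean localization frame")
    ax.set_ylabel("std of localization frames")
    ax.set_xlim(0, n_frames)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def line_profile_figure(profile, fov, path=None):
    """Intensity along the x and y axes through the profile center."""
    from .illumination import line_profile

    fig, ax = plt.subplots(figsize=(5, 3))
    for axis, color in (("x", "tab:red"), ("y", "tab:blue")):
        pos, vals = line_profile(profile, fov, axis=axis)
        ax.plot(pos / 1000.0, vals, color=color, label=axis)
    ax.set_xlabel("position (um)")
    ax.set_ylabel("intensity (a.u.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
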