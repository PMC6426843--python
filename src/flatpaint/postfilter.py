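"""Photon-count based rejection of multi-emitter mislocalizations.

When two imagers are bound simultaneously within a diffraction-limited
region, a single-emitter fitter places one spurious localization between
them carrying roughly the summed photons.  Under uniform excitation the
per-frame photon histogram therefore shows a single-emitter peak and a
second peak at about twice its position.  Fitting a two-Gaussian model and
cutting everything above the upper 1/e^2 abscissa of the first peak
(``mu1 + 2 sigma1``) removes the doubles at negligible cost to singles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PhotonMixtureFit",
    "fit_photon_mixture",
    "one_over_e2_threshold",
    "filter_multiemitter",
]


@dataclass
class PhotonMixtureFit:
    mu1: float
    sigma1: float
    amp1: float
    mu2: float | None
    sigma2: float | None
    amp2: float | None
    residual: float
    single_peak: bool

    @property
    def threshold(self) -> float:
        return one_over_e2_threshold(self.mu1, self.sigma1)

    @property
    def peak_ratio(self) -> float | None:
        return None if self.single_peak else self.mu2 / self.mu1


def _double_gauss(x, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-((x - m1) ** 2) / (2 * s1**2)) + a2 * np.exp(
        -((x - m2) ** 2) / (2 * s2**2)
    )


def _single_gauss(x, a, m, s):
    return a * np.exp(-((x - m) ** 2) / (2 * s**2))


def fit_photon_mixture(photons: np.ndarray, min_n: int = 500) -> PhotonMixtureFit:
    """Two-Gaussian least-squares fit of the per-frame photon histogram.

    Binned with the Freedman-Diaconis rule; the first component starts at
    the histogram mode, the second at twice that, widths from the
    inter-quartile spread.  If the fitted second component carries less
    than 1% of the first component's area, a single-peak result is
    reported instead.
    """
    ph = np.asarray(photons, dtype=float)
    ph = ph[np.isfinite(ph) & (ph > 0)]
    if len(ph) < min_n:
        raise ValueError(f"need at least {min_n} localizations, got {len(ph)}")
    hist, edges = np.histogram(ph, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = centers[np.argmax(hist)]
    iqr = float(np.subtract(*np.percentile(ph, [75, 25])))
    s0 = max(iqr / 4.0, np.sqrt(mode), 1.0)
    a0 = float(hist.max())
    p0 = [a0, mode, s0, a0 / 8.0, 2.0 * mode, 1.5 * s0]
    lo = [0.0, 0.0, 1e-6, 0.0, 0.0, 1e-6]
    hi = [np.inf, ph.max() * 2, ph.max(), np.inf, ph.max() * 2, ph.max()]
    try:
        popt, _ = curve_fit(_double_gauss, centers, hist, p0=p0, bounds=(lo, hi), maxfev=40000)
    except RuntimeError as err:
        raise RuntimeError(
            f"photon mixture fit did not converge (n={len(ph)}, mode={mode:.0f})"
        ) from err
    a1, m1, s1, a2, m2, s2 = popt
    if m2 < m1:
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
    resid = float(np.sum((_double_gauss(centers, *popt) - hist) ** 2))
    # component areas restricted to the histogram support: a component
    # pushed outside the data range is unconstrained, not a real peak
    from scipy.stats import norm

    lo_e, hi_e = edges[0], edges[-1]
    area1 = a1 * s1 * (norm.cdf((hi_e - m1) / s1) - norm.cdf((lo_e - m1) / s1))
    area2 = a2 * s2 * (norm.cdf((hi_e - m2) / s2) - norm.cdf((lo_e - m2) / s2))
    if area2 < 0.01 * area1 or a2 < 1.0:
        popt1, _ = curve_fit(_single_gauss, centers, hist, p0=[a0, mode, s0], maxfev=20000)
        resid1 = float(np.sum((_single_gauss(centers, *popt1) - hist) ** 2))
        return PhotonMixtureFit(
            mu1=float(popt1[1]), sigma1=float(abs(popt1[2])), amp1=float(popt1[0]),
            mu2=None, sigma2=None, amp2=None, residual=resid1, single_peak=True,
        )
    return PhotonMixtureFit(
        mu1=float(m1), sigma1=float(abs(s1)), amp1=float(a1),
        mu2=float(m2), sigma2=float(abs(s2)), amp2=float(a2),
        residual=resid, single_peak=False,
    )


def one_over_e2_threshold(mu1: float, sigma1: float) -> float:
    """Upper abscissa where a Gaussian falls to 1/e^2 of its peak: mu + 2 sigma."""
    if sigma1 <= 0:
        raise ValueError("sigma1 must be positive")
    return mu1 + 2.0 * sigma1


def filter_multiemitter(
    locs: pd.DataFrame, threshold: float
) -> tuple[pd.DataFrame, dict]:
    """Remove localizations with photons above the threshold.

    Returns the filtered table and a removal report.  If the table carries
    the simulator's ``n_emitters`` ground-truth column, the report
    cross-tabulates removals against it (fraction of multi-emitter rows
    removed, fraction of single-emitter rows lost).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = locs["photons"].to_numpy() > threshold
    kept = locs.loc[~above].reset_index(drop=True)
    report: dict = {
        "threshold": float(threshold),
        "n_before": int(len(locs)),
        "n_removed": int(above.sum()),
        "n_after": int(len(kept)),
        "fraction_removed": float(above.mean()) if len(locs) else 0.0,
    }
    if "n_emitters" in locs.columns and len(locs):
        multi = locs["n_emitters"].to_numpy() > 1
        report["n_multi"] = int(multi.sum())
        report["multi_removed_fraction"] = (
            float(above[multi].mean()) if multi.any() else np.nan
        )
        report["single_removed_fraction"] = (
            float(above[~multi].mean()) if (~multi).any() else np.nan
        )
    return kept, report
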