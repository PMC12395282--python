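"""Characterization of detrending residuals.

After removing a modeled baseline from task-free fPET-FDG data, a perfect
fit leaves only noise; any *consistent* deviation from zero is baseline
mischaracterization.  To isolate the consistent part, residual time-series
are smoothed with a 2-minute-FWHM Gaussian temporal filter and summarized
by their root-mean-square (RMSE), per parcel and averaged over subjects.
Cross-subject mean residual patterns are compared with noise-free
simulation residuals via Pearson correlation, and the similarity of two
spatial RMSE maps to a common reference is compared with Steiger's Z test
for dependent correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ResidualSummary",
    "fwhm_to_sigma",
    "gaussian_smooth_time",
    "residual_rmse",
    "summarize_residuals",
    "compare_residual_patterns",
    "steiger_z",
]

DEFAULT_FWHM = 2.0  # minutes


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ResidualSummary:
    """Smoothed residuals and their cross-subject summaries.

    ``rmse_map`` is the per-parcel mean (over subjects) of each subject's
    RMS of the smoothed residual; ``mean_residual`` the cross-subject mean
    residual time-series per parcel, and ``mean_residual_cortex`` its
    unweighted average over parcels (the whole-cortex pattern).
    """

    smoothed: np.ndarray          # (S, n, P)
    rmse_map: np.ndarray          # (P,)
    mean_residual: np.ndarray     # (n, P)
    mean_residual_cortex: np.ndarray  # (n,)
    fwhm: float


def gaussian_smooth_time(series: np.ndarray, fwhm: float,
                         frame_duration: float) -> np.ndarray:
    """Gaussian temporal smoothing on a uniform frame grid.

    The discrete kernel has sigma = fwhm / (2 sqrt(2 ln 2)), is truncated
    at +-4 sigma, and is renormalized at the series boundaries (equivalent
    to dividing by the smoothed all-ones series), so constants pass through
    unchanged and no data are fabricated beyond the scan edges.  ``series``
    may be 1-D or (n, P); smoothing acts along axis 0.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if frame_duration <= 0:
        raise ValueError("frame_duration must be positive")
    x = np.asarray(series, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    sigma = fwhm_to_sigma(fwhm) / frame_duration  # in samples
    radius = max(int(np.ceil(4.0 * sigma)), 1)
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    k /= k.sum()
    n = x.shape[0]
    weight = np.convolve(np.ones(n), k, mode="same")
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = np.convolve(x[:, j], k, mode="same") / weight
    return out[:, 0] if one_d else out


def _as_subject_stack(residuals) -> np.ndarray:
    """Coerce residual input to a (S, n, P) stack."""
    if isinstance(residuals, np.ndarray) and residuals.ndim == 3:
        return residuals.astype(float)
    arrs = [np.atleast_2d(np.asarray(r, dtype=float)) for r in residuals]
    return np.stack(arrs)


def residual_rmse(residuals, fwhm: float, frame_duration: float) -> np.ndarray:
    """Per-parcel RMSE map of smoothed residuals, averaged over subjects.

    ``residuals`` is a list of per-subject (n_frames, P) arrays or a
    (S, n, P) stack.
    """
    stack = _as_subject_stack(residuals)
    if stack.size == 0:
        raise ValueError("empty residuals")
    sm = np.stack([gaussian_smooth_time(s, fwhm, frame_duration) for s in stack])
    rms = np.sqrt((sm ** 2).mean(axis=1))   # (S, P)
    return rms.mean(axis=0)


def summarize_residuals(residuals, fwhm: float = DEFAULT_FWHM,
                        frame_duration: float = 16.0 / 60.0) -> ResidualSummary:
    """Full residual summary: smoothing, RMSE map, cross-subject means."""
    stack = _as_subject_stack(residuals)
    sm = np.stack([gaussian_smooth_time(s, fwhm, frame_duration) for s in stack])
    rms = np.sqrt((sm ** 2).mean(axis=1))
    mean_res = stack.mean(axis=0)
    return ResidualSummary(smoothed=sm, rmse_map=rms.mean(axis=0),
                           mean_residual=mean_res,
                           mean_residual_cortex=mean_res.mean(axis=1),
                           fwhm=fwhm)


def compare_residual_patterns(mean_residual, sim_residual):
    """Pearson correlation between an observed cross-subject mean residual
    and a simulated residual on the same frame grid.

    Returns (r, two-sided p) with p from the t transform at dof = n - 2.
    """
    a = np.asarray(mean_residual, dtype=float)
    b = np.asarray(sim_residual, dtype=float)
    if a.shape != b.shape:
        raise ValueError("residual series must share the frame grid")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("residual series must be non-constant")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def steiger_z(r12: float, r13: float, r23: float, n: int):
    """Steiger's Z test (Z1* variant) for two dependent correlations
    sharing variable 1.

    Tests whether corr(1,2) exceeds corr(1,3) given that variables 2 and 3
    are themselves correlated (r23), using the Fisher-z difference divided
    by its standard error with the pooled dependent-correlation covariance
    term.  Returns (z, one-sided upper-tail p).
    """
    for r in (r12, r13, r23):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3")
    z12 = np.arctanh(r12)
    z13 = np.arctanh(r13)
    rbar = 0.5 * (r12 + r13)
    rb2 = rbar * rbar
    # covariance of the two dependent correlations (pooled-r form)
    cov = (r23 * (1.0 - 2.0 * rb2) - 0.5 * rb2 * (1.0 - 2.0 * rb2 - r23 ** 2)) \
        / (1.0 - rb2) ** 2
    z = (z12 - z13) * np.sqrt((n - 3) / (2.0 * (1.0 - cov)))
    p = float(stats.norm.sf(z))
    return float(z), p
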