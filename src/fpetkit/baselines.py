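"""Baseline (detrending) models for fPET-FDG time-activity curves.

Five baseline families are implemented:

``P3``
    Third-order polynomial fitted independently to each parcel TAC.
``P3MT``
    Third-order polynomial fitted once to the cortical-mean TAC; the fitted
    curve is then scaled per parcel (amplitude + intercept).
``MT``
    The cortical-mean TAC itself regressed from each parcel.
``SA``
    Spectral analysis: the baseline is expanded in basis functions
    ``psi_j(t) = AIF (x) exp(-beta_j t)`` over a grid of tissue clearance
    rates ``beta_j`` (plus the undecayed ``beta = 0`` integral term), with
    non-negative spectral coefficients.  Requires prior knowledge of the AIF.
``EXP2``
    An analytic linear-plus-biexponential baseline
    ``B(t) = c0 + c1 t + c2 e^{-mu1 t} + c3 e^{-mu2 t}``, the closed-form
    shape of the two-tissue compartment solution driven by a
    constant-infusion AIF with a single-exponential approach to plateau.

Every method can exclude the initial pre-equilibration minutes of the scan;
a frame is excluded when it *starts* before the boundary, so no kept frame
overlaps the excluded window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .kinetics import ArterialInput, FramedTac, frame_average, _conv_trapz

__all__ = [
    "BaselineSpec",
    "BaselineFit",
    "BaselineFitError",
    "METHODS",
    "default_sa_beta_grid",
    "fit_p3",
    "fit_p3mt",
    "fit_mt",
    "fit_sa",
    "fit_exp2",
    "detrend",
]

METHODS = ("P3", "P3MT", "MT", "SA", "EXP2")

_EXCL_ATOL = 1e-9


def default_sa_beta_grid(n: int = 48, lo: float = 1e-3, hi: float = 1.0) -> np.ndarray:
    """Log-spaced spectral-rate grid (1/min) spanning effective FDG
    clearance rates; the beta = 0 integral term is added separately."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


@dataclass
class BaselineSpec:
    """Configuration of a baseline fit.

    ``exclude_initial`` is the number of initial minutes of the scan to
    drop before fitting (0 or 10 in this work).  ``task_nuisance`` is an
    optional task regressor sampled on the *full* frame grid of the input
    TAC; it participates in the fit (unconstrained) but never in the
    returned baseline.  It is honored by SA (appended to the basis) and by
    P3MT (included when fitting the mean TAC).
    """

    method: str = "P3"
    exclude_initial: float = 0.0
    sa_beta_grid: np.ndarray | None = None
    task_nuisance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.method = self.method.upper()
        if self.method not in METHODS:
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.exclude_initial < 0:
            raise ValueError("exclude_initial must be non-negative")
        if self.sa_beta_grid is not None:
            g = np.asarray(self.sa_beta_grid, dtype=float)
            if len(g) == 0 or np.any(g <= 0) or np.any(np.diff(g) <= 0):
                raise ValueError("sa_beta_grid must be strictly positive and sorted")
            self.sa_beta_grid = g


@dataclass
class BaselineFit:
    """Result of a baseline fit on the kept frames.

    ``fitted + residuals`` equals the input TAC on the kept frames whenever
    no task nuisance was supplied; with a nuisance, the task contribution is
    kept out of ``fitted`` (it is not baseline) and stored in
    ``nuisance_fitted`` so that
    ``fitted + nuisance_fitted + residuals = input``.
    """

    spec: BaselineSpec
    frames_kept: np.ndarray          # boolean mask over input frames
    frame_mid: np.ndarray            # kept-frame midpoints, minutes
    regressors: np.ndarray | None    # shared design (kept x k), None for EXP2
    coefficients: np.ndarray | None  # (k x P)
    fitted: np.ndarray               # baseline (kept x P)
    residuals: np.ndarray            # (kept x P)
    nuisance_fitted: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_parcels(self) -> int:
        return self.fitted.shape[1]

    def mean_residual(self) -> np.ndarray:
        """Whole-cortex (unweighted across parcels) mean residual series."""
        return self.residuals.mean(axis=1)


class BaselineFitError(RuntimeError):
    """Nonlinear baseline fit failed; carries best-so-far parameters."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# shared machinery


def exclusion_mask(tac: FramedTac, exclude_initial: float) -> np.ndarray:
    """Frames kept after dropping those that start before the boundary."""
    starts = tac.frame_mid - tac.frame_dur / 2.0
    return starts >= exclude_initial - _EXCL_ATOL


def _scaled_time(t: np.ndarray) -> np.ndarray:
    lo, hi = t[0], t[-1]
    return 2.0 * (t - lo) / (hi - lo) - 1.0


def _poly_design(t: np.ndarray, order: int = 3) -> np.ndarray:
    # centered/scaled to [-1, 1] for conditioning over ~350 frames
    s = _scaled_time(t)
    return np.vander(s, order + 1, increasing=True)


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of every column of Y on X.  Returns (coef, fitted)."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return coef, X @ coef


def _nnls_mixed(A: np.ndarray, b: np.ndarray, free: np.ndarray) -> np.ndarray:
    """NNLS in which columns flagged ``free`` are sign-unconstrained.

    Free columns are mirrored (+col, -col) so the whole problem stays a
    plain NNLS; the mirrored pair is recombined afterwards.
    """
    maxiter = max(2000, 30 * A.shape[1])
    if not free.any():
        x, _ = nnls(A, b, maxiter=maxiter)
        return x
    aug = np.hstack([A, -A[:, free]])
    x_aug, _ = nnls(aug, b, maxiter=maxiter)
    x = x_aug[: A.shape[1]].copy()
    x[free] -= x_aug[A.shape[1]:]
    return x


def _prepare(tac: FramedTac, spec: BaselineSpec):
    keep = exclusion_mask(tac, spec.exclude_initial)
    t = tac.frame_mid[keep]
    Y = tac.values[keep]
    task = None
    if spec.task_nuisance is not None:
        task = np.asarray(spec.task_nuisance, dtype=float)
        if len(task) != tac.n_frames:
            raise ValueError("task_nuisance must be sampled on the full frame grid")
        task = task[keep]
        task = task - task.mean()
    return keep, t, Y, task


# ---------------------------------------------------------------------------
# the five baseline models


def fit_p3(tac: FramedTac, spec: BaselineSpec) -> BaselineFit:
    """Third-order polynomial fitted to each parcel independently."""
    keep, t, Y, task = _prepare(tac, spec)
    if keep.sum() < 8:
        raise ValueError("need at least 8 frames after exclusion")
    X = _poly_design(t)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient polynomial design (degenerate timing)")
    coef, fitted = _ols(X, Y)
    return BaselineFit(spec=spec, frames_kept=keep, frame_mid=t, regressors=X,
                       coefficients=coef, fitted=fitted, residuals=Y - fitted)


def fit_p3mt(tac: FramedTac, mean_tac: np.ndarray, spec: BaselineSpec) -> BaselineFit:
    """Third-order polynomial pre-fitted to the cortical-mean TAC, then
    amplitude-scaled per parcel.

    Stage 1 fits a cubic (optionally with the task regressor as an
    unconstrained nuisance) to the mean TAC; the cubic part of the fit
    becomes the shared baseline shape.  Stage 2 fits intercept + amplitude
    of that shape per parcel.
    """
    if mean_tac is None:
        raise ValueError("P3MT requires the cortical-mean TAC (mean_tac)")
    mean_tac = np.asarray(mean_tac, dtype=float)
    if len(mean_tac) != tac.n_frames:
        raise ValueError("mean_tac must be on the same frame grid as the TACs")
    keep, t, Y, task = _prepare(tac, spec)
    Xp = _poly_design(t)
    X1 = Xp if task is None else np.column_stack([Xp, task])
    coef1, _ = _ols(X1, mean_tac[keep])
    curve = Xp @ coef1[: Xp.shape[1]]  # cubic part only: the baseline shape
    X2 = np.column_stack([np.ones_like(t), curve])
    coef2, fitted = _ols(X2, Y)
    return BaselineFit(spec=spec, frames_kept=keep, frame_mid=t, regressors=X2,
                       coefficients=coef2, fitted=fitted, residuals=Y - fitted,
                       extras={"stage1_curve": curve, "stage1_coef": coef1})


def fit_mt(tac: FramedTac, mean_tac: np.ndarray, spec: BaselineSpec) -> BaselineFit:
    """Cortical-mean TAC regressed from each parcel (intercept + amplitude)."""
    if mean_tac is None:
        raise ValueError("MT requires the cortical-mean TAC (mean_tac)")
    mean_tac = np.asarray(mean_tac, dtype=float)
    if len(mean_tac) != tac.n_frames:
        raise ValueError("mean_tac must be on the same frame grid as the TACs")
    keep, t, Y, _ = _prepare(tac, spec)
    m = mean_tac[keep]
    if np.ptp(m) < 1e-12 * max(1.0, np.abs(m).max()):
        raise ValueError("mean_tac is constant (collinear with the intercept)")
    X = np.column_stack([np.ones_like(t), m])
    coef, fitted = _ols(X, Y)
    return BaselineFit(spec=spec, frames_kept=keep, frame_mid=t, regressors=X,
                       coefficients=coef, fitted=fitted, residuals=Y - fitted)


def sa_basis(aif: ArterialInput, tac: FramedTac,
             beta_grid: np.ndarray) -> np.ndarray:
    """Spectral-analysis basis on the TAC frame grid.

    Column j is the convolution of the AIF with ``exp(-beta_j t)`` computed
    on the fine AIF grid and then frame-averaged exactly like the TAC data;
    the final column is the beta = 0 (irreversible trapping) integral term.
    """
    scan = tac.n_frames * tac.frame_dur
    if aif.times[-1] + 1e-9 < scan:
        raise ValueError("AIF grid does not cover the TAC scan duration")
    fine = np.empty((len(aif.times), len(beta_grid) + 1))
    for j, beta in enumerate(beta_grid):
        fine[:, j] = _conv_trapz(aif.values, np.exp(-beta * aif.times), aif.dt)
    fine[:, -1] = aif.cumulative()
    _, framed = frame_average(fine, aif.dt, tac.frame_dur, scan)
    return framed


def fit_sa(tac: FramedTac, aif: ArterialInput, spec: BaselineSpec) -> BaselineFit:
    """Spectral-analysis baseline with non-negative spectral coefficients.

    The design is ``[intercept | AIF (x) exp(-beta_j t) | integral term]``
    with the spectral coefficients constrained >= 0 (standard in spectral
    analysis of tracer kinetics) and the intercept unconstrained.  A task
    nuisance, when given, is appended unconstrained and excluded from the
    returned baseline.
    """
    if aif is None:
        raise ValueError("SA requires the arterial input function (aif)")
    betas = spec.sa_beta_grid if spec.sa_beta_grid is not None else default_sa_beta_grid()
    keep, t, Y, task = _prepare(tac, spec)
    basis_full = sa_basis(aif, tac, betas)
    basis = basis_full[keep]
    n_spec = basis.shape[1]
    cols = [np.ones_like(t), basis]
    if task is not None:
        cols.append(task)
    X = np.column_stack(cols)
    free = np.zeros(X.shape[1], dtype=bool)
    free[0] = True
    if task is not None:
        free[-1] = True
    # normalize columns so NNLS sees comparable scales
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    Xn = X / norms
    P = Y.shape[1]
    coef = np.empty((X.shape[1], P))
    for p in range(P):
        coef[:, p] = _nnls_mixed(Xn, Y[:, p], free) / norms
    full_fit = X @ coef
    n_base = 1 + n_spec
    fitted = X[:, :n_base] @ coef[:n_base]
    nuis = full_fit - fitted if task is not None else None
    return BaselineFit(spec=spec, frames_kept=keep, frame_mid=t,
                       regressors=X[:, :n_base], coefficients=coef[:n_base],
                       fitted=fitted, residuals=Y - full_fit,
                       nuisance_fitted=nuis,
                       extras={"beta_grid": betas, "task_coef":
                               coef[-1] if task is not None else None})


#: shared decay-rate bounds for EXP2 (1/min): the rates represent the AIF
#: equilibration rate and the tissue clearance rate k2 + k3, both of which
#: live in the effective FDG kinetic regime (the same span the SA spectral
#: grid covers).  Sub-minute bolus transients lie outside this family by
#: construction — the model is derived for infusion-equilibration inputs.
EXP2_MU_BOUNDS = (1e-3, 1.0)


def _exp2_design(t: np.ndarray, mu1: float, mu2: float,
                 anchored: bool = True) -> np.ndarray:
    """EXP2 basis at rates (mu1, mu2).

    Anchored form: two columns ``g_mu(t) = exp(-mu t) - 1 + mu t`` — the
    compartment-model solution family for a saturating infusion input,
    which satisfies B(0) = 0 and B'(0) = 0 (a decay-corrected tissue curve
    starts at zero activity with zero slope).  Free form: the unconstrained
    ``{1, t, e^{-mu1 t}, e^{-mu2 t}}`` family.
    """
    if anchored:
        return np.column_stack([np.exp(-mu1 * t) - 1.0 + mu1 * t,
                                np.exp(-mu2 * t) - 1.0 + mu2 * t])
    return np.column_stack([np.ones_like(t), t,
                            np.exp(-mu1 * t), np.exp(-mu2 * t)])


def _exp2_to_poly(coef: np.ndarray, mus: np.ndarray,
                  anchored: bool) -> np.ndarray:
    """Express fitted coefficients in the (c0, c1, c2, c3) convention of
    ``B(t) = c0 + c1 t + c2 e^{-mu1 t} + c3 e^{-mu2 t}``."""
    if not anchored:
        return coef
    c2, c3 = coef
    mu1, mu2 = mus[:, 0], mus[:, 1]
    return np.vstack([-(c2 + c3), c2 * mu1 + c3 * mu2, c2, c3])


def fit_exp2(tac: FramedTac, spec: BaselineSpec, *, anchored: bool = True,
             n_grid: int = 10) -> BaselineFit:
    """Linear-plus-biexponential baseline fitted per parcel.

    The default (anchored) model is the analytic two-tissue baseline for a
    constant-infusion input approaching plateau: a linear trend plus two
    decaying exponentials constrained by B(0) = 0, B'(0) = 0, with decay
    rates shared-bounded to the FDG kinetic regime (``EXP2_MU_BOUNDS``).
    ``anchored=False`` frees all four amplitudes.

    Fitting is variable-projection nonlinear least squares: amplitudes are
    linear given ``(mu1, mu2)``, so a deterministic multi-start over a
    log-spaced rate grid picks the best pair per parcel (ties broken by
    smaller mu1), then a bounded local refinement polishes the rates.
    """
    keep, t, Y, _ = _prepare(tac, spec)
    if keep.sum() < 20:
        raise ValueError("need at least 20 frames after exclusion")
    P = Y.shape[1]
    mu_lo, mu_hi = EXP2_MU_BOUNDS
    mu1_grid = np.logspace(np.log10(2 * mu_lo), np.log10(mu_hi), n_grid)
    mu2_grid = np.logspace(np.log10(mu_lo), np.log10(mu_hi / 2), n_grid)
    best_sse = np.full(P, np.inf)
    best_pair = np.zeros((P, 2))
    for mu1 in mu1_grid:
        for mu2 in mu2_grid:
            if mu1 <= mu2:
                continue
            X = _exp2_design(t, mu1, mu2, anchored)
            _, fitted = _ols(X, Y)
            sse = ((Y - fitted) ** 2).sum(axis=0)
            better = sse < best_sse * (1 - 1e-12)
            tie = np.isclose(sse, best_sse, rtol=1e-12) & (mu1 < best_pair[:, 0])
            upd = better | tie
            best_sse[upd] = sse[upd]
            best_pair[upd] = (mu1, mu2)

    if not np.isfinite(best_sse).all():
        raise BaselineFitError("EXP2 grid search failed for some parcels",
                               best=best_pair)

    n_amp = 2 if anchored else 4
    coefs = np.empty((n_amp, P))
    fitted = np.empty_like(Y)
    mus = np.empty((P, 2))
    lb = [np.log(mu_lo), -30.0]
    ub = [np.log(mu_hi), np.log(0.999)]
    for p in range(P):
        y = Y[:, p]
        mu1_0, mu2_0 = best_pair[p]

        def resid(x):
            mu1 = np.exp(x[0])
            mu2 = mu1 * np.exp(x[1])
            X = _exp2_design(t, mu1, mu2, anchored)
            c, *_ = np.linalg.lstsq(X, y, rcond=None)
            return X @ c - y

        x0 = np.clip([np.log(mu1_0), np.log(mu2_0 / mu1_0)], lb, ub)
        sol = least_squares(resid, x0, bounds=(lb, ub),
                            xtol=1e-13, ftol=1e-13, gtol=1e-13)
        mu1 = float(np.exp(sol.x[0]))
        mu2 = mu1 * float(np.exp(sol.x[1]))
        X = _exp2_design(t, mu1, mu2, anchored)
        c, fit_p = _ols(X, y)
        if ((y - fit_p) ** 2).sum() > best_sse[p]:
            # refinement stalled; keep grid optimum
            mu1, mu2 = mu1_0, mu2_0
            X = _exp2_design(t, mu1, mu2, anchored)
            c, fit_p = _ols(X, y)
        coefs[:, p] = c
        fitted[:, p] = fit_p
        mus[p] = (mu1, mu2)
    return BaselineFit(spec=spec, frames_kept=keep, frame_mid=t, regressors=None,
                       coefficients=coefs, fitted=fitted, residuals=Y - fitted,
                       extras={"mu": mus, "anchored": anchored,
                               "poly_coef": _exp2_to_poly(coefs, mus, anchored)})


def detrend(tac: FramedTac, spec: BaselineSpec, *,
            aif: ArterialInput | None = None,
            mean_tac: np.ndarray | None = None) -> BaselineFit:
    """Dispatch to the baseline fitter named by ``spec.method``.

    ``aif`` is required for SA; ``mean_tac`` (full-grid cortical mean) for
    P3MT and MT.  When ``mean_tac`` is omitted for those methods it is
    computed as the unweighted mean across the parcels of ``tac`` if the
    TAC has more than one parcel, otherwise an error names the missing
    input.
    """
    method = spec.method
    if method in ("P3MT", "MT") and mean_tac is None:
        if tac.n_parcels > 1:
            mean_tac = tac.mean_tac()
        else:
            raise ValueError(f"{method} requires mean_tac")
    if method == "P3":
        return fit_p3(tac, spec)
    if method == "P3MT":
        return fit_p3mt(tac, mean_tac, spec)
    if method == "MT":
        return fit_mt(tac, mean_tac, spec)
    if method == "SA":
        if aif is None:
            raise ValueError("SA requires aif")
        return fit_sa(tac, aif, spec)
    if method == "EXP2":
        return fit_exp2(tac, spec)
    raise ValueError(f"unknown baseline method {method!r}")
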