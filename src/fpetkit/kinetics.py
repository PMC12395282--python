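"""FDG tracer kinetics: arterial input functions, the reversible two-tissue
compartment model, frame averaging, and Patlak graphical analysis.

The arterial input function (AIF) of an infusion study is modeled as the
convolution of a decaying biexponential impulse response

.. math:: h(t) = a_1 e^{-\\lambda_1 t} + a_2 e^{-\\lambda_2 t}

with the tracer delivery schedule ``r(t)`` — a constant rate for
constant-infusion (CI) protocols, or a constant rate plus a short bolus
rectangle for bolus-plus-constant-infusion (B+CI) protocols.  The relative
bolus size ``K_bol`` is expressed in minutes of constant infusion delivering
an equivalent dose, so the rectangle carries area ``K_bol * rate``.

Tissue time-activity curves (TACs) follow the reversible two-tissue
compartment model of FDG: free tracer in tissue (C1) and phosphorylated
FDG-6-phosphate (C2),

.. math::

    dC_1/dt &= K_1 C_a(t) - (k_2 + k_3) C_1 + k_4 C_2 \\\\
    dC_2/dt &= k_3 C_1 - k_4 C_2

integrated with an implicit (backward) Euler scheme on a uniform grid.
All activities are in arbitrary units and all times in minutes; data are
assumed decay-corrected, so CI TACs rise monotonically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.optimize import least_squares, nnls

__all__ = [
    "InfusionSchedule",
    "BiexpResponse",
    "ArterialInput",
    "KineticParams",
    "ContinuousTac",
    "FramedTac",
    "PatlakResult",
    "AifFitError",
    "DEFAULT_DT",
    "LITERATURE_RATE_CONSTANTS",
    "make_aif",
    "fit_aif",
    "simulate_tac",
    "simulate_tac_matrix",
    "reference_tac_ode",
    "frame_tac",
    "frame_average",
    "patlak_ki",
]

#: default simulation step: 1 second, expressed in minutes.  16-s and 30-s
#: frames are integer multiples of this grid.
DEFAULT_DT = 1.0 / 60.0

#: literature rate constants for gray-matter FDG kinetics
#: (K1 in mL/min/g, k2..k4 in 1/min).
LITERATURE_RATE_CONSTANTS = (0.102, 0.13, 0.062, 0.0068)

_GRID_ATOL = 1e-9


@dataclass(frozen=True)
class InfusionSchedule:
    """Tracer delivery schedule.

    Parameters
    ----------
    protocol:
        ``"CI"`` (constant infusion) or ``"B+CI"`` (bolus plus constant
        infusion).
    duration:
        Scan/infusion duration in minutes.
    infusion_rate:
        Constant delivery rate in arbitrary dose units per minute.
    kbol:
        Relative bolus size in minutes (B+CI only): the bolus dose equals
        ``kbol * infusion_rate``.
    bolus_width:
        Width in minutes of the rectangle approximating the bolus.
    """

    protocol: str
    duration: float
    infusion_rate: float = 1.0
    kbol: float = 0.0
    bolus_width: float = 1.0

    def __post_init__(self) -> None:
        if self.protocol not in ("CI", "B+CI"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.infusion_rate < 0:
            raise ValueError("infusion_rate must be non-negative")
        if self.kbol < 0:
            raise ValueError("kbol must be non-negative")
        if self.protocol == "CI" and self.kbol != 0:
            raise ValueError("kbol must be zero for a CI protocol")
        if self.protocol == "B+CI":
            if self.bolus_width <= 0:
                raise ValueError("bolus_width must be positive")
            if self.kbol > 0 and self.bolus_width >= self.kbol:
                raise ValueError("bolus_width must be much smaller than kbol")


@dataclass(frozen=True)
class BiexpResponse:
    """Decaying biexponential impulse response of the arterial pool.

    Amplitudes are non-negative and rates are ordered ``lam1 > lam2 > 0``
    (fast then slow).
    """

    a1: float
    a2: float
    lam1: float
    lam2: float

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.a1 == 0 and self.a2 == 0:
            raise ValueError("at least one amplitude must be positive")
        if not (self.lam1 >= self.lam2 > 0):
            raise ValueError("rates must satisfy lam1 >= lam2 > 0")

    def kernel(self, t: np.ndarray) -> np.ndarray:
        """Evaluate ``h(t)`` on an array of times (minutes)."""
        t = np.asarray(t, dtype=float)
        return self.a1 * np.exp(-self.lam1 * t) + self.a2 * np.exp(-self.lam2 * t)


@dataclass
class ArterialInput:
    """AIF time course (arbitrary units) on a fine uniform grid."""

    times: np.ndarray
    values: np.ndarray
    response: BiexpResponse
    schedule: InfusionSchedule

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def cumulative(self) -> np.ndarray:
        """Running integral of the AIF on its own grid (trapezoid rule)."""
        return cumulative_trapezoid(self.values, dx=self.dt, initial=0.0)


@dataclass(frozen=True)
class KineticParams:
    """Two-tissue compartment rate constants.

    ``K1`` is blood-to-tissue transport (mL/min/g); ``k2`` efflux back to
    blood, ``k3`` phosphorylation, ``k4`` dephosphorylation (all 1/min).
    """

    K1: float
    k2: float
    k3: float
    k4: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("rate constants must be non-negative")

    @classmethod
    def literature(cls) -> "KineticParams":
        """Literature gray-matter values used throughout this package."""
        return cls(*LITERATURE_RATE_CONSTANTS)

    def ki_irreversible(self) -> float:
        """Analytic Patlak net influx rate in the k4 = 0 limit,
        ``K1 * k3 / (k2 + k3)``."""
        return self.K1 * self.k3 / (self.k2 + self.k3)


@dataclass
class ContinuousTac:
    """Noise-free compartment concentrations on the simulation grid."""

    times: np.ndarray
    c1: np.ndarray
    c2: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.c1 + self.c2

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class FramedTac:
    """Frame-averaged time-activity data: frames x parcels.

    ``values`` is always two-dimensional; a single TAC is a one-column
    matrix.  Frame timestamps are frame midpoints in minutes.
    """

    frame_mid: np.ndarray
    frame_dur: float
    values: np.ndarray
    parcels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.frame_mid):
            self.values = self.values.T
        if not self.parcels:
            self.parcels = [f"parcel_{i:03d}" for i in range(self.values.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]

    def series(self, j: int = 0) -> np.ndarray:
        return self.values[:, j]

    def mean_tac(self) -> np.ndarray:
        """Unweighted mean across parcels (the 'cortical mean' TAC)."""
        return self.values.mean(axis=1)

    def copy(self) -> "FramedTac":
        return FramedTac(self.frame_mid.copy(), self.frame_dur,
                         self.values.copy(), list(self.parcels))


@dataclass
class PatlakResult:
    ki: float
    intercept: float
    n_points: int


class AifFitError(RuntimeError):
    """AIF fit failed to converge; carries the best parameters seen so far."""

    def __init__(self, message: str, best: BiexpResponse | None = None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# AIF construction and fitting


def _conv_trapz(f: np.ndarray, g: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoid-rule discrete convolution of two series on a shared grid."""
    n = len(f)
    out = np.convolve(f, g)[:n] * dt
    # trapezoid endpoint correction: half weight at s = 0 and s = t
    out -= 0.5 * dt * (f[0] * g + f * g[0])
    return out


def infusion_rate_series(schedule: InfusionSchedule, times: np.ndarray) -> np.ndarray:
    """Delivery rate r(t) sampled on ``times``."""
    r = np.full(len(times), float(schedule.infusion_rate))
    if schedule.protocol == "B+CI" and schedule.kbol > 0:
        height = schedule.kbol * schedule.infusion_rate / schedule.bolus_width
        r[times <= schedule.bolus_width + _GRID_ATOL] += height
    return r


def make_aif(schedule: InfusionSchedule, response: BiexpResponse,
             dt: float = DEFAULT_DT) -> ArterialInput:
    """Build an AIF as the convolution of the biexponential response with the
    infusion paradigm.

    Parameters
    ----------
    schedule:
        Delivery protocol (CI or B+CI).
    response:
        Biexponential impulse response of the arterial concentration.
    dt:
        Grid step in minutes; must not exceed the shortest frame duration
        used downstream.

    Returns
    -------
    ArterialInput
        AIF on ``t = 0, dt, ..., duration`` with ``values[0] == 0``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(schedule.duration / dt)) + 1
    times = np.arange(n) * dt
    r = infusion_rate_series(schedule, times)
    h = response.kernel(times)
    values = _conv_trapz(r, h, dt)
    values[0] = 0.0
    np.maximum(values, 0.0, out=values)
    return ArterialInput(times=times, values=values, response=response,
                         schedule=schedule)


def _aif_model_at(samples_t: np.ndarray, schedule: InfusionSchedule,
                  response: BiexpResponse, dt: float) -> np.ndarray:
    aif = make_aif(schedule, response, dt)
    return np.interp(samples_t, aif.times, aif.values)


def fit_aif(times, values, schedule: InfusionSchedule, *,
            dt: float = 0.05, n_starts: int = 8) -> BiexpResponse:
    """Fit the biexponential-response AIF model to sampled AIF data.

    Nonlinear least squares over ``(a1, a2, lam1, lam2)`` with amplitudes
    constrained non-negative, using deterministic multi-start on a
    log-spaced rate grid (biexponential fits are multi-modal).  Rates are
    returned sorted so that ``lam1 >= lam2``.

    Raises
    ------
    AifFitError
        If no start converges; the exception carries the best-so-far
        parameters in its ``best`` attribute.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 8:
        raise ValueError("need at least 8 AIF samples")
    if times.max() - times.min() <= 20:
        raise ValueError("AIF samples must span more than 20 minutes")

    if np.allclose(values, 0.0):
        return BiexpResponse(a1=0.0, a2=1e-12, lam1=1.0, lam2=0.01)

    scale = float(np.max(np.abs(values)))

    def residual(x):
        a1, a2, l1, l2 = x
        resp = BiexpResponse(a1=max(a1, 0.0) + 1e-15, a2=max(a2, 0.0),
                             lam1=max(l1, l2) + 1e-12, lam2=min(l1, l2))
        return _aif_model_at(times, schedule, resp, dt) - values

    lam1_grid = np.logspace(-1, 0.7, n_starts)  # ~0.1 .. 5 /min
    best = None
    best_cost = np.inf
    for lam1 in lam1_grid:
        lam2 = lam1 / 20.0
        # linear amplitude initialization for this rate pair
        col1 = _aif_model_at(times, schedule,
                             BiexpResponse(1.0, 0.0, lam1, lam2), dt)
        col2 = _aif_model_at(times, schedule,
                             BiexpResponse(0.0, 1.0, lam1, lam2), dt)
        amps, _ = nnls(np.column_stack([col1, col2]), values)
        x0 = [max(amps[0], 1e-6 * scale), max(amps[1], 1e-8 * scale), lam1, lam2]
        try:
            sol = least_squares(residual, x0,
                                bounds=([0, 0, 1e-4, 1e-5], [np.inf] * 2 + [50.0, 10.0]),
                                xtol=1e-12, ftol=1e-12)
        except ValueError:
            continue
        if sol.cost < best_cost:
            best_cost = sol.cost
            best = sol.x
    if best is None:
        raise AifFitError("all AIF fit starts failed", best=None)
    a1, a2, l1, l2 = best
    if l1 < l2:
        a1, a2, l1, l2 = a2, a1, l2, l1
    if l1 == l2:
        l1 = l2 * (1 + 1e-9)
    resp = BiexpResponse(a1=a1, a2=a2, lam1=l1, lam2=l2)
    rms = math.sqrt(2 * best_cost / len(times))
    if rms > 0.25 * scale:
        raise AifFitError(
            f"AIF fit did not converge (residual RMS {rms:.3g} vs scale {scale:.3g})",
            best=resp)
    return resp


# ---------------------------------------------------------------------------
# Compartment simulation


def _check_uniform_grid(times: np.ndarray) -> float:
    steps = np.diff(times)
    dt = float(steps[0])
    if not np.allclose(steps, dt, rtol=0, atol=_GRID_ATOL):
        raise ValueError("time grid must be uniform")
    return dt


def simulate_tac_matrix(aif: ArterialInput, K1, k2, k3, k4,
                        k3_scale: np.ndarray | None = None) -> np.ndarray:
    """Implicit-Euler integration of the two-tissue model for many parcels.

    Parameters
    ----------
    aif:
        Arterial input on a uniform grid.
    K1, k2, k3, k4:
        Scalars or length-P arrays of rate constants (one entry per parcel).
    k3_scale:
        Optional length-n multiplicative time course applied to ``k3``
        (time-varying phosphorylation, e.g. task modulation).

    Returns
    -------
    ndarray of shape (n_times, P)
        Total tissue concentration ``C1 + C2``.
    """
    dt = _check_uniform_grid(aif.times)
    K1, k2, k3, k4 = np.broadcast_arrays(
        *[np.atleast_1d(np.asarray(v, dtype=float)) for v in (K1, k2, k3, k4)])
    if min(K1.min(), k2.min(), k3.min(), k4.min()) < 0:
        raise ValueError("rate constants must be non-negative")
    ca = np.asarray(aif.values, dtype=float)
    n, p = len(ca), len(K1)
    c1 = np.zeros(p)
    c2 = np.zeros(p)
    out = np.zeros((n, p))
    time_varying = k3_scale is not None
    if not time_varying:
        a11 = 1.0 + dt * (k2 + k3)
        a12 = -dt * k4
        a21 = -dt * k3
        a22 = 1.0 + dt * k4
        det = a11 * a22 - a12 * a21
    for i in range(1, n):
        if time_varying:
            k3_i = k3 * k3_scale[i]
            a11 = 1.0 + dt * (k2 + k3_i)
            a21 = -dt * k3_i
            a12 = -dt * k4
            a22 = 1.0 + dt * k4
            det = a11 * a22 - a12 * a21
        b1 = c1 + dt * K1 * ca[i]
        b2 = c2
        c1 = (a22 * b1 - a12 * b2) / det
        c2 = (a11 * b2 - a21 * b1) / det
        out[i, :] = c1 + c2
    return out


def simulate_tac(aif: ArterialInput, params: KineticParams,
                 dt: float | None = None) -> ContinuousTac:
    """Simulate a single noise-free TAC with the implicit Euler scheme.

    The AIF grid must be uniform; ``dt``, if given, must match it.  Each
    backward-Euler step solves the 2x2 linear system
    ``(I - dt*A) C[n+1] = C[n] + dt*b[n+1]`` exactly.
    """
    grid_dt = _check_uniform_grid(aif.times)
    if dt is not None and not math.isclose(dt, grid_dt, abs_tol=_GRID_ATOL):
        raise ValueError("dt does not match the AIF grid step")
    dt = grid_dt
    ca = np.asarray(aif.values, dtype=float)
    n = len(ca)
    c1 = np.zeros(n)
    c2 = np.zeros(n)
    k2k3 = params.k2 + params.k3
    a11 = 1.0 + dt * k2k3
    a12 = -dt * params.k4
    a21 = -dt * params.k3
    a22 = 1.0 + dt * params.k4
    det = a11 * a22 - a12 * a21
    for i in range(1, n):
        b1 = c1[i - 1] + dt * params.K1 * ca[i]
        b2 = c2[i - 1]
        c1[i] = (a22 * b1 - a12 * b2) / det
        c2[i] = (a11 * b2 - a21 * b1) / det
    return ContinuousTac(times=aif.times.copy(), c1=c1, c2=c2)


def reference_tac_ode(aif: ArterialInput, params: KineticParams,
                      rtol: float = 1e-10, atol: float = 1e-12) -> np.ndarray:
    """High-accuracy adaptive-solver total TAC on the AIF grid.

    Independent cross-check for the implicit Euler scheme: integrates the
    same ODE system with ``scipy.integrate.solve_ivp`` (LSODA) using linear
    interpolation of the AIF between grid points.
    """
    times = aif.times
    values = aif.values

    def rhs(t, y):
        ca = np.interp(t, times, values)
        c1, c2 = y
        return [params.K1 * ca - (params.k2 + params.k3) * c1 + params.k4 * c2,
                params.k3 * c1 - params.k4 * c2]

    sol = solve_ivp(rhs, (times[0], times[-1]), [0.0, 0.0], t_eval=times,
                    method="LSODA", rtol=rtol, atol=atol)
    return sol.y[0] + sol.y[1]


# ---------------------------------------------------------------------------
# Framing and Patlak analysis


def frame_average(values: np.ndarray, dt: float, frame_duration: float,
                  scan_duration: float) -> tuple[np.ndarray, np.ndarray]:
    """Average a finely sampled series into frames.

    Frame value = trapezoid mean of the series over the frame window, which
    is exact at the frame midpoint for linear series.  Returns
    ``(frame_mid, framed_values)``; ``values`` may be 1-D or (n, P).
    """
    steps = int(round(frame_duration / dt))
    if abs(steps * dt - frame_duration) > 1e-6:
        raise ValueError("frame_duration must be a multiple of the grid step")
    n_frames = int(scan_duration / frame_duration + 1e-9)
    values = np.asarray(values, dtype=float)
    one_d = values.ndim == 1
    if one_d:
        values = values[:, None]
    if (n_frames * steps) > len(values) - 1:
        raise ValueError("scan_duration not covered by the simulation grid")
    cum = cumulative_trapezoid(values, dx=dt, axis=0, initial=0.0)
    idx = np.arange(n_frames + 1) * steps
    framed = np.diff(cum[idx], axis=0) / frame_duration
    mid = (np.arange(n_frames) + 0.5) * frame_duration
    return mid, (framed[:, 0] if one_d else framed)


def frame_tac(tac: ContinuousTac, frame_duration: float,
              scan_duration: float) -> FramedTac:
    """Bin a continuous TAC into frames of the stated duration."""
    mid, vals = frame_average(tac.total, tac.dt, frame_duration, scan_duration)
    return FramedTac(frame_mid=mid, frame_dur=frame_duration, values=vals)


def patlak_ki(tac: FramedTac, aif: ArterialInput, t_star: float = 30.0,
              parcel: int = 0) -> PatlakResult:
    """Patlak graphical estimate of the net influx rate Ki.

    Ordinary least squares of ``y = TAC / Ca`` on
    ``x = (integral of Ca) / Ca`` restricted to frames with midpoint
    ``>= t_star``; the slope is Ki (1/min).
    """
    mid = tac.frame_mid
    if t_star >= mid[-1]:
        raise ValueError("t_star must lie within the scan")
    ca_mid = np.interp(mid, aif.times, aif.values)
    int_ca_mid = np.interp(mid, aif.times, aif.cumulative())
    keep = mid >= t_star
    if keep.sum() < 10:
        raise ValueError("need at least 10 frames after t_star")
    if np.any(ca_mid[keep] <= 0):
        raise ValueError("AIF must be strictly positive after t_star")
    x = int_ca_mid[keep] / ca_mid[keep]
    y = tac.values[keep, parcel] / ca_mid[keep]
    slope, intercept = np.polyfit(x, y, 1)
    return PatlakResult(ki=float(slope), intercept=float(intercept),
                        n_points=int(keep.sum()))
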