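"""GLM-based task analysis of detrended fPET-FDG data.

Implements block task/sham regressors, subject-level GLMs (baseline model +
task regressor), percent signal change (PSC), random-effects group
statistics, Benjamini-Hochberg FDR control, and parcel aggregation (the
desk-scale counterpart of spatial smoothing).

In constant-infusion fPET the task effect of interest is a change of the
TAC *slope* during task blocks, so the canonical task regressor is the
running integral of the block boxcar (a piecewise-linear "ramp" with unit
slope during on-blocks).  Applying such a regressor to task-free data is a
sham analysis: any systematic group-level effect it detects is artifactual
and traces back to residual baseline patterning correlated with the
regressor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BlockDesign",
    "TaskRegressor",
    "GlmResult",
    "GroupResult",
    "ShamSelection",
    "T_CAP",
    "build_task_regressor",
    "select_sham_regressors",
    "fit_subject_glm",
    "percent_signal_change",
    "late_baseline_slope",
    "group_random_effects",
    "fdr_correct",
    "aggregate_parcels",
    "contiguous_grouping",
]

#: sentinel cap for infinite t-scores (zero between-subject variance)
T_CAP = 1e6


@dataclass(frozen=True)
class BlockDesign:
    """Alternating on/off block paradigm (all durations in minutes)."""

    on_duration: float = 10.0
    off_duration: float = 10.0
    initial_rest: float = 0.0
    scan_duration: float = 95.0

    def __post_init__(self) -> None:
        if self.on_duration <= 0 or self.off_duration <= 0:
            raise ValueError("on/off durations must be positive")
        if self.initial_rest < 0:
            raise ValueError("initial_rest must be non-negative")
        if self.scan_duration <= 0:
            raise ValueError("scan_duration must be positive")

    def boxcar(self, t: np.ndarray) -> np.ndarray:
        """1 during on-blocks, 0 otherwise."""
        t = np.asarray(t, dtype=float)
        phase = np.mod(t - self.initial_rest, self.on_duration + self.off_duration)
        return np.where((t >= self.initial_rest) & (phase < self.on_duration),
                        1.0, 0.0)

    def on_time(self, t: np.ndarray) -> np.ndarray:
        """Cumulative on-block time (minutes) up to each t: the exact
        integral of the boxcar."""
        t = np.asarray(t, dtype=float)
        period = self.on_duration + self.off_duration
        shifted = np.clip(t - self.initial_rest, 0.0, None)
        full = np.floor(shifted / period)
        partial = np.minimum(shifted - full * period, self.on_duration)
        return full * self.on_duration + partial


@dataclass
class TaskRegressor:
    """Task/sham regressor sampled at frame mid-times.

    ``values`` is demeaned (as entered into the GLM); ``raw`` keeps the
    undemeaned series.  For the ramp shape, ``on_slope`` is the regressor's
    slope during on-blocks (1 unit of regressor per minute).
    """

    values: np.ndarray
    raw: np.ndarray
    design: BlockDesign
    shape: str = "ramp"
    on_slope: float = 1.0


@dataclass
class GlmResult:
    """Per-parcel subject-level GLM output."""

    beta_task: np.ndarray
    se_task: np.ndarray
    t_task: np.ndarray
    dof: int
    residuals: np.ndarray
    psc: np.ndarray | None = None
    collinear: bool = False


@dataclass
class GroupResult:
    """Random-effects group summary across subjects."""

    group_t: np.ndarray
    p: np.ndarray
    q_mask: np.ndarray
    mean_psc: np.ndarray | None
    n_subjects: int
    fdr_cutoff: float = 0.0
    capped: np.ndarray | None = None


@dataclass
class ShamSelection:
    """Sham regressors ranked by correlation with a reference residual."""

    ranked: list            # (BlockDesign, TaskRegressor, r), sorted by r desc
    positive: tuple         # argmax r
    null: tuple             # argmin |r|
    negative: tuple         # most negative r with |r| in [0.2, 0.6] if any

    @property
    def picks(self):
        return {"positive": self.positive, "null": self.null,
                "negative": self.negative}


def build_task_regressor(design: BlockDesign, frame_times,
                         shape: str = "ramp") -> TaskRegressor:
    """Sample a block regressor at frame mid-times.

    ``shape="boxcar"`` gives the 0/1 block indicator; ``shape="ramp"`` its
    running time-integral (unit slope during on-blocks, flat during off),
    which models the slope change a metabolic task effect induces in a
    cumulative TAC.  The returned values are demeaned.
    """
    t = np.asarray(frame_times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("frame_times must be sorted")
    if design.scan_duration + 1e-9 < t[-1]:
        raise ValueError("block design is shorter than the scan")
    if shape == "boxcar":
        raw = design.boxcar(t)
        on_slope = 0.0
    elif shape == "ramp":
        raw = design.on_time(t)
        on_slope = 1.0
    else:
        raise ValueError(f"unknown regressor shape {shape!r}")
    return TaskRegressor(values=raw - raw.mean(), raw=raw, design=design,
                         shape=shape, on_slope=on_slope)


def residual_projector(basis: np.ndarray) -> np.ndarray:
    """Residual-maker matrix M = I - B (B'B)^-1 B' of a design ``basis``."""
    B = np.atleast_2d(basis)
    return np.eye(B.shape[0]) - B @ np.linalg.pinv(B)


def select_sham_regressors(candidates, reference_residual, frame_times,
                           shape: str = "ramp",
                           orthogonalize_to: np.ndarray | None = None
                           ) -> ShamSelection:
    """Rank candidate block designs by Pearson correlation of their
    regressor with a reference residual pattern.

    When ``orthogonalize_to`` (a baseline design matrix on the same frame
    grid) is given, both the regressor and the reference are projected
    orthogonal to it before correlating.  This is the correlation that
    actually drives GLM bias: the task coefficient responds only to the
    regressor component the baseline model cannot absorb, so e.g. a ramp
    regressor's dominant linear trend — which any baseline fit removes —
    must not dilute the ranking.

    Returns all candidates sorted by r (descending) plus three convenience
    picks: the most positively correlated, the most nearly uncorrelated,
    and a moderately negative one (most-negative r with |r| in [0.2, 0.6];
    falls back to the most negative overall if none lands in the band).
    """
    ref = np.asarray(reference_residual, dtype=float)
    if np.ptp(ref) == 0:
        raise ValueError("reference residual is constant")
    M = (residual_projector(orthogonalize_to)
         if orthogonalize_to is not None else None)
    if M is not None:
        ref = M @ ref
    entries = []
    for design in candidates:
        reg = build_task_regressor(design, frame_times, shape=shape)
        v = M @ reg.values if M is not None else reg.values
        r = float(stats.pearsonr(v, ref)[0])
        entries.append((design, reg, r))
    ranked = sorted(entries, key=lambda e: -e[2])
    positive = ranked[0]
    null = min(entries, key=lambda e: abs(e[2]))
    in_band = [e for e in entries if -0.6 <= e[2] <= -0.2]
    negative = min(in_band or entries, key=lambda e: e[2])
    return ShamSelection(ranked=ranked, positive=positive, null=null,
                         negative=negative)


def _stack_design(baseline: np.ndarray, task: np.ndarray) -> np.ndarray:
    return np.column_stack([baseline, task])


def fit_subject_glm(tac_values: np.ndarray, baseline_regressors: np.ndarray,
                    task: TaskRegressor, *,
                    cond_threshold: float = 1e8) -> GlmResult:
    """Per-parcel OLS of the TAC on [baseline regressors | task].

    Parameters
    ----------
    tac_values:
        Kept-frame data, shape (n, P).
    baseline_regressors:
        Shared design of shape (n, k), or per-parcel designs of shape
        (n, k, P) (e.g. the fitted SA/EXP2 baseline curve per parcel).
    task:
        Task regressor on the same kept-frame grid.

    The task coefficient, its classical standard error, t = beta/se, and
    the residuals are returned.  A design whose standardized condition
    number exceeds ``cond_threshold`` triggers a collinearity warning but
    results are still returned.
    """
    Y = np.atleast_2d(np.asarray(tac_values, dtype=float))
    if Y.shape[0] != len(task.values):
        Y = Y.T
    n, P = Y.shape
    tv = task.values

    def check_cond(X):
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return np.linalg.cond(X / sd) > cond_threshold

    collinear = False
    if baseline_regressors.ndim == 2:
        X = _stack_design(baseline_regressors, tv)
        k = X.shape[1]
        collinear = check_cond(X)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        fitted = X @ coef
        resid = Y - fitted
        dof = n - k
        sigma2 = (resid ** 2).sum(axis=0) / dof
        xtx_inv = np.linalg.pinv(X.T @ X)
        beta = coef[-1]
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[-1, -1], 0.0))
    else:
        k = baseline_regressors.shape[1] + 1
        dof = n - k
        beta = np.empty(P)
        se = np.empty(P)
        resid = np.empty_like(Y)
        for p in range(P):
            X = _stack_design(baseline_regressors[:, :, p], tv)
            collinear = collinear or check_cond(X)
            c, *_ = np.linalg.lstsq(X, Y[:, p], rcond=None)
            r = Y[:, p] - X @ c
            resid[:, p] = r
            s2 = (r ** 2).sum() / dof
            xtx_inv = np.linalg.pinv(X.T @ X)
            beta[p] = c[-1]
            se[p] = np.sqrt(max(s2 * xtx_inv[-1, -1], 0.0))
    if collinear:
        warnings.warn("task regressor nearly collinear with baseline design",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                         np.sign(beta) * T_CAP)
    return GlmResult(beta_task=beta, se_task=se, t_task=tstat, dof=dof,
                     residuals=resid, collinear=bool(collinear))


def late_baseline_slope(fitted_baseline: np.ndarray, frame_mid: np.ndarray,
                        late_window: float | None = None) -> np.ndarray:
    """OLS slope of the fitted baseline over the late part of the scan.

    ``late_window`` is the length in minutes of the trailing window;
    default is the final third of the kept scan.
    """
    B = np.atleast_2d(np.asarray(fitted_baseline, dtype=float))
    if B.shape[0] != len(frame_mid):
        B = B.T
    span = frame_mid[-1] - frame_mid[0]
    if late_window is None:
        late_window = span / 3.0
    if late_window <= 0 or late_window > span:
        raise ValueError("late_window must lie inside the kept scan")
    sel = frame_mid >= frame_mid[-1] - late_window
    t = frame_mid[sel]
    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, B[sel], rcond=None)
    return coef[1]


def percent_signal_change(result: GlmResult, fitted_baseline: np.ndarray,
                          task: TaskRegressor, frame_mid: np.ndarray,
                          late_window: float | None = None) -> np.ndarray:
    """PSC per parcel: the task-induced on-block slope relative to the late
    baseline slope.

    ``PSC = 100 * beta_task * on_slope / slope_late`` where ``on_slope`` is
    the ramp regressor's slope during on-blocks (units/min) and
    ``slope_late`` is the OLS slope of the fitted baseline over the late
    window.  Parcels with non-positive late baseline slope get NaN (PSC
    undefined there).  The result is also stored on ``result.psc``.
    """
    if task.shape != "ramp":
        raise ValueError("PSC requires a ramp-shaped task regressor")
    slope_late = late_baseline_slope(fitted_baseline, frame_mid, late_window)
    with np.errstate(divide="ignore", invalid="ignore"):
        psc = 100.0 * result.beta_task * task.on_slope / slope_late
    psc = np.where(slope_late > 0, psc, np.nan)
    result.psc = psc
    return psc


def group_random_effects(results: list[GlmResult],
                         q: float = 0.05) -> GroupResult:
    """One-sample random-effects t-test across subjects' task betas.

    Per parcel: t = mean(beta) / (sd(beta)/sqrt(n)) with dof = n - 1 and a
    two-sided p; parcels with zero between-subject variance get the capped
    sentinel ``+-T_CAP`` (flagged in ``capped``).  Mean PSC is averaged
    over subjects where defined.  FDR control is applied across parcels.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 subjects for group inference")
    betas = np.vstack([r.beta_task for r in results])
    if np.isnan(betas).any():
        raise ValueError("missing subject beta values")
    n, P = betas.shape
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    capped = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~capped, mean / np.where(capped, 1.0, sd / np.sqrt(n)),
                     np.sign(mean) * T_CAP)
    t = np.where(capped & (mean == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.minimum(np.abs(t), T_CAP), df=n - 1)
    mask, cutoff = fdr_correct(p, q)
    pscs = [r.psc for r in results if r.psc is not None]
    mean_psc = np.nanmean(np.vstack(pscs), axis=0) if len(pscs) == len(results) else None
    return GroupResult(group_t=t, p=p, q_mask=mask, mean_psc=mean_psc,
                       n_subjects=n, fdr_cutoff=cutoff, capped=capped)


def fdr_correct(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up across parcels.

    Returns the boolean significance mask and the realized p cutoff (the
    largest p declared significant; 0.0 when nothing passes).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mask = multipletests(p, alpha=q, method="fdr_bh")[0]
    cutoff = float(p[mask].max()) if mask.any() else 0.0
    return mask, cutoff


def contiguous_grouping(n_parcels: int, n_groups: int) -> np.ndarray:
    """Map parcels to ``n_groups`` contiguous, near-equal-size groups."""
    if not (1 <= n_groups <= n_parcels):
        raise ValueError("need 1 <= n_groups <= n_parcels")
    return (np.arange(n_parcels) * n_groups) // n_parcels


def aggregate_parcels(tac, grouping) -> "FramedTac":
    """Merge parcels into coarser groups (unweighted mean TAC per group).

    ``grouping`` assigns a group label to every parcel (array-like of
    length n_parcels); group order follows first appearance so the identity
    grouping returns the input unchanged.
    """
    from .kinetics import FramedTac  # local import to avoid cycle

    labels = np.asarray(grouping)
    if len(labels) != tac.n_parcels:
        raise ValueError("grouping must cover all parcels")
    order = []
    seen = {}
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(order)
            order.append(lab)
    out = np.empty((tac.n_frames, len(order)))
    names = []
    for j, lab in enumerate(order):
        members = labels == lab
        if not members.any():
            raise ValueError(f"empty group {lab!r}")
        out[:, j] = tac.values[:, members].mean(axis=1)
        names.append(str(lab))
    return FramedTac(frame_mid=tac.frame_mid.copy(), frame_dur=tac.frame_dur,
                     values=out, parcels=names)
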