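"""Synthetic multi-subject fPET-FDG cohorts.

Generates parcel-level time-activity data with the statistical structure
the downstream analysis assumes and that empirical resting-state infusion
datasets exhibit: regionally varying kinetic rate constants (lognormal
around literature gray-matter values, guaranteeing positivity),
inter-subject variability of the arterial input function, frame-wise noise
whose variance grows over the scan (decay-correction amplification of
counting noise), and optional injected task effects of known percent
signal change.

Everything is driven by a single integer seed through
``numpy.random.SeedSequence`` spawning, so a cohort is bit-identically
reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .glm import BlockDesign
from .kinetics import (DEFAULT_DT, ArterialInput, BiexpResponse, FramedTac,
                       InfusionSchedule, KineticParams, frame_average,
                       make_aif, simulate_tac_matrix)

__all__ = [
    "TaskSpec",
    "CohortSpec",
    "SyntheticCohort",
    "DEFAULT_RESPONSE",
    "DEFAULT_RESPONSE_CI",
    "DEFAULT_RESPONSE_BCI",
    "PHYSICAL_DECAY_RATE",
    "sample_regional_kinetics",
    "generate_subject",
    "inject_task_effect",
    "add_noise",
    "generate_cohort",
    "late_slope",
]

#: physical decay rate of F-18, ln(2) / 109.77 min
PHYSICAL_DECAY_RATE = math.log(2.0) / 109.77

#: reference frame length (minutes) at which ``noise_scale`` is defined
NOISE_REF_FRAME = 1.0

#: Biexponential arterial-response centers, one per protocol, mirroring the
#: per-dataset AIF fits such responses come from.  Under constant infusion
#: the identifiable input dynamics are the minutes-scale equilibration
#: phase (~4-min time constant) plus a slow quasi-linear rise; a bolus
#: additionally reveals the sub-minute vascular distribution phase
#: (~20-second time constant), producing the early overshoot that
#: equilibrates the B+CI signal quickly.
DEFAULT_RESPONSE_CI = BiexpResponse(a1=1.0, a2=0.05, lam1=0.25, lam2=0.012)
DEFAULT_RESPONSE_BCI = BiexpResponse(a1=1.0, a2=0.02, lam1=3.0, lam2=0.012)

#: kept for backward-compatible imports: the CI default
DEFAULT_RESPONSE = DEFAULT_RESPONSE_CI


@dataclass(frozen=True)
class TaskSpec:
    """Injected task effect.

    ``k3_modulation`` rescales the phosphorylation rate during on-blocks
    (a time-varying coefficient in the kinetic ODE); ``additive_ramp`` adds
    a ramp of slope ``effect_size x late-baseline-slope`` during on-blocks
    (exactly controllable ground truth).
    """

    design: BlockDesign
    mode: str = "additive_ramp"
    effect_size: float = 0.04

    def __post_init__(self) -> None:
        if self.mode not in ("k3_modulation", "additive_ramp"):
            raise ValueError(f"unknown task effect mode {self.mode!r}")
        if not -0.5 < self.effect_size < 0.5:
            raise ValueError("effect_size must lie in (-0.5, 0.5)")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults mirror the illustrative empirical constant-infusion analysis:
    24 subjects, 100 cortical parcels, 95-minute CI scans at 16-second
    frames, literature gray-matter kinetics.
    """

    n_subjects: int = 24
    n_parcels: int = 100
    schedule: InfusionSchedule = field(
        default_factory=lambda: InfusionSchedule("CI", duration=95.0))
    frame_duration: float = 16.0 / 60.0
    kinetics_center: KineticParams = field(
        default_factory=KineticParams.literature)
    kinetics_cv: float = 0.15
    subject_aif_cv: float = 0.10
    noise_scale: float = 0.01
    response_center: BiexpResponse | None = None  # resolved per protocol
    dt: float = DEFAULT_DT
    task: TaskSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_parcels < 1:
            raise ValueError("need at least one subject and one parcel")
        if min(self.kinetics_cv, self.subject_aif_cv, self.noise_scale) < 0:
            raise ValueError("CVs and noise_scale must be non-negative")

    @classmethod
    def bci_default(cls, **kw) -> "CohortSpec":
        """B+CI counterpart: 105-minute scans, 30-second frames,
        K_bol = 19.3 minutes."""
        kw.setdefault("schedule", InfusionSchedule(
            "B+CI", duration=105.0, kbol=19.3, bolus_width=1.0))
        kw.setdefault("frame_duration", 0.5)
        return cls(**kw)

    def resolved_response(self) -> BiexpResponse:
        """Response center, defaulting by protocol (CI vs B+CI)."""
        if self.response_center is not None:
            return self.response_center
        return (DEFAULT_RESPONSE_BCI if self.schedule.protocol == "B+CI"
                else DEFAULT_RESPONSE_CI)


@dataclass
class SyntheticCohort:
    """A generated cohort plus its full ground truth."""

    spec: CohortSpec
    tacs: list[FramedTac]            # per subject, noisy
    tacs_noisefree: list[FramedTac]  # per subject, before noise
    aifs: list[ArterialInput]        # per subject
    parcel_params: np.ndarray        # (P, 4): K1, k2, k3, k4 per parcel
    true_psc: np.ndarray             # (P,): injected PSC per parcel (0 if no task)

    @property
    def frame_mid(self) -> np.ndarray:
        return self.tacs[0].frame_mid


def _lognormal_around(center: float, cv: float, size, rng) -> np.ndarray:
    """Mean-preserving lognormal draws around ``center`` with fractional CV."""
    if cv == 0 or center == 0:
        return np.full(size, float(center))
    sigma2 = math.log1p(cv * cv)
    mu = math.log(center) - 0.5 * sigma2
    draws = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)
    if not np.isfinite(draws).all():
        raise ValueError("non-finite kinetic draws; reduce the CV")
    return draws


def sample_regional_kinetics(spec: CohortSpec,
                             rng: np.random.Generator) -> np.ndarray:
    """Per-parcel rate constants drawn lognormally around the center.

    Returns an array of shape (n_parcels, 4) with columns K1, k2, k3, k4.
    """
    c = spec.kinetics_center
    out = np.column_stack([
        _lognormal_around(v, spec.kinetics_cv, spec.n_parcels, rng)
        for v in (c.K1, c.k2, c.k3, c.k4)])
    return out


def _perturb_response(resp: BiexpResponse, cv: float,
                      rng: np.random.Generator) -> BiexpResponse:
    a1, a2, l1, l2 = (
        _lognormal_around(v, cv, 1, rng)[0]
        for v in (resp.a1, resp.a2, resp.lam1, resp.lam2))
    if l1 < l2:
        l1, l2 = l2, l1
        a1, a2 = a2, a1
    return BiexpResponse(a1=a1, a2=max(a2, 0.0), lam1=l1, lam2=l2)


def late_slope(framed: FramedTac, frac: float = 1.0 / 3.0) -> np.ndarray:
    """Per-parcel OLS slope over the trailing fraction of the scan."""
    t = framed.frame_mid
    sel = t >= t[-1] - frac * (t[-1] - t[0])
    X = np.column_stack([np.ones(sel.sum()), t[sel]])
    coef, *_ = np.linalg.lstsq(X, framed.values[sel], rcond=None)
    return coef[1]


def inject_task_effect(framed: FramedTac, design: BlockDesign, mode: str,
                       effect_size: float, *,
                       aif: ArterialInput | None = None,
                       parcel_params: np.ndarray | None = None
                       ) -> tuple[FramedTac, np.ndarray]:
    """Apply a task effect of known size to a noise-free framed TAC.

    ``additive_ramp`` adds ``effect_size * slope_late_p`` of extra slope
    during on-blocks to each parcel p; its ground-truth PSC is exactly
    ``100 * effect_size``.  ``k3_modulation`` re-simulates the kinetics
    with ``k3 -> k3 * (1 + effect_size)`` during on-blocks (requires the
    subject AIF and the per-parcel rate constants); its ground-truth PSC
    follows the net-influx-rate ratio
    ``100 * ((1 + d)(k2 + k3) / (k2 + k3(1 + d)) - 1)``.

    Returns the modified TAC and the per-parcel true PSC (%).
    """
    P = framed.n_parcels
    if effect_size == 0:
        return framed.copy(), np.zeros(P)
    if mode == "additive_ramp":
        ramp = design.on_time(framed.frame_mid)          # minutes of on-time
        slopes = late_slope(framed)                      # signal units / min
        out = framed.copy()
        out.values = out.values + np.outer(ramp, effect_size * slopes)
        return out, np.full(P, 100.0 * effect_size)
    if mode == "k3_modulation":
        if aif is None or parcel_params is None:
            raise ValueError("k3_modulation requires aif and parcel_params")
        k3_scale = 1.0 + effect_size * design.boxcar(aif.times)
        K1, k2, k3, k4 = parcel_params.T
        totals = simulate_tac_matrix(aif, K1, k2, k3, k4, k3_scale=k3_scale)
        scan = framed.n_frames * framed.frame_dur
        mid, vals = frame_average(totals, aif.dt, framed.frame_dur, scan)
        out = FramedTac(frame_mid=mid, frame_dur=framed.frame_dur,
                        values=vals, parcels=list(framed.parcels))
        d = effect_size
        truth = 100.0 * ((1 + d) * (k2 + k3) / (k2 + k3 * (1 + d)) - 1.0)
        return out, truth
    raise ValueError(f"unknown task effect mode {mode!r}")


def add_noise(framed: FramedTac, noise_scale: float, frame_duration: float,
              rng: np.random.Generator) -> FramedTac:
    """Add decay-correction-amplified Gaussian frame noise.

    Per-frame standard deviation:
    ``noise_scale * late_mean_p * sqrt(ref_frame / frame_duration)
    * exp(+lambda_phys * t / 2)`` with lambda_phys = ln 2 / 109.77 per min
    and ref_frame = 1 minute — shorter frames collect fewer counts, and
    decay correction inflates late-scan noise exponentially.  ``late_mean``
    is the per-parcel mean signal over the final 10 minutes.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    out = framed.copy()
    if noise_scale == 0:
        return out
    t = framed.frame_mid
    late = t >= t[-1] - 10.0
    late_mean = framed.values[late].mean(axis=0)
    sd = (noise_scale * late_mean[None, :]
          * math.sqrt(NOISE_REF_FRAME / frame_duration)
          * np.exp(0.5 * PHYSICAL_DECAY_RATE * t)[:, None])
    out.values = out.values + rng.standard_normal(out.values.shape) * sd
    return out


def generate_subject(spec: CohortSpec, parcel_params: np.ndarray,
                     subject_index: int, seed_seq: np.random.SeedSequence
                     ) -> tuple[FramedTac, FramedTac, ArterialInput, np.ndarray]:
    """Generate one subject: AIF, noise-free parcel TACs, noisy TACs.

    Returns ``(noisy, noisefree, aif, true_psc)``.
    """
    rng = np.random.default_rng(seed_seq)
    resp = _perturb_response(spec.resolved_response(), spec.subject_aif_cv, rng)
    aif = make_aif(spec.schedule, resp, spec.dt)
    K1, k2, k3, k4 = parcel_params.T
    totals = simulate_tac_matrix(aif, K1, k2, k3, k4)
    scan = spec.schedule.duration
    mid, vals = frame_average(totals, spec.dt, spec.frame_duration, scan)
    noisefree = FramedTac(frame_mid=mid, frame_dur=spec.frame_duration,
                          values=vals)
    true_psc = np.zeros(spec.n_parcels)
    if spec.task is not None:
        noisefree, true_psc = inject_task_effect(
            noisefree, spec.task.design, spec.task.mode,
            spec.task.effect_size, aif=aif, parcel_params=parcel_params)
    noisy = add_noise(noisefree, spec.noise_scale, spec.frame_duration, rng)
    return noisy, noisefree, aif, true_psc


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort, bit-identically reproducible from the spec."""
    root = np.random.SeedSequence(spec.seed)
    kin_seq, *subj_seqs = root.spawn(spec.n_subjects + 1)
    parcel_params = sample_regional_kinetics(
        spec, np.random.default_rng(kin_seq))
    tacs, tacs_nf, aifs = [], [], []
    true_psc = np.zeros(spec.n_parcels)
    for s in range(spec.n_subjects):
        noisy, noisefree, aif, psc = generate_subject(
            spec, parcel_params, s, subj_seqs[s])
        tacs.append(noisy)
        tacs_nf.append(noisefree)
        aifs.append(aif)
        true_psc = psc
    return SyntheticCohort(spec=spec, tacs=tacs, tacs_noisefree=tacs_nf,
                           aifs=aifs, parcel_params=parcel_params,
                           true_psc=true_psc)
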