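"""Readers/writers and the reproducible analysis pipeline.

The canonical interchange format for parcel-level fPET data is delimited
text (CSV): TAC tables carry ``frame_mid_min`` and ``frame_dur_min``
columns followed by one column per parcel; AIF tables carry ``time_min``
and ``value``.  Readers validate rather than coerce: shuffled frames,
non-numeric cells and duplicate parcel names are rejected with the
offending location named.

``run_pipeline`` ties the stages together — synthetic cohort, sham
regressor selection, the five baseline models with and without exclusion
of the initial 10 minutes, subject GLMs and group statistics — and writes
a self-describing output directory (resolved config, seeds, versions,
summary grid).
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baselines import METHODS, BaselineSpec, detrend
from .cohort import CohortSpec, SyntheticCohort, TaskSpec, generate_cohort
from .glm import (BlockDesign, build_task_regressor, fit_subject_glm,
                  group_random_effects, percent_signal_change,
                  select_sham_regressors)
from .kinetics import (ArterialInput, BiexpResponse, FramedTac,
                       InfusionSchedule, KineticParams)

__all__ = [
    "read_tac_table",
    "write_tac_table",
    "read_aif_table",
    "write_aif_table",
    "load_config",
    "save_config",
    "default_demo_config",
    "cohort_spec_from_config",
    "run_pipeline",
    "sham_group_analysis",
    "extract_parcel_tacs",
]

log = logging.getLogger("fpetkit")

_TIME_COLS = ("frame_mid_min", "frame_dur_min")


def write_tac_table(path, tac: FramedTac) -> None:
    """Write a framed TAC matrix as CSV (times + one column per parcel)."""
    df = pd.DataFrame({"frame_mid_min": tac.frame_mid,
                       "frame_dur_min": np.full(tac.n_frames, tac.frame_dur)})
    for j, name in enumerate(tac.parcels):
        df[name] = tac.values[:, j]
    df.to_csv(path, index=False, float_format="%.17g")


def read_tac_table(path) -> FramedTac:
    """Read and validate a framed TAC table.

    Frame mid-times must be strictly increasing and frame durations
    uniform; parcel names must be unique and all cells numeric.
    """
    with open(path) as fh:  # pandas silently renames duplicate headers
        header = [c.strip() for c in fh.readline().rstrip("\n").split(",")]
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate parcel names: {dupes}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _TIME_COLS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    parcel_cols = [c for c in df.columns if c not in _TIME_COLS]
    if not parcel_cols:
        raise ValueError("no parcel columns found")
    try:
        data = df.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric cell in TAC table: {err}") from err
    mids = data["frame_mid_min"].to_numpy()
    bad = np.nonzero(np.diff(mids) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"frame times not strictly increasing at data row {bad[0] + 1} "
            f"(frame_mid_min={mids[bad[0] + 1]:g})")
    durs = data["frame_dur_min"].to_numpy()
    if not np.allclose(durs, durs[0], rtol=0, atol=1e-9):
        bad = int(np.nonzero(~np.isclose(durs, durs[0]))[0][0])
        raise ValueError(f"non-uniform frame duration at data row {bad}")
    return FramedTac(frame_mid=mids, frame_dur=float(durs[0]),
                     values=data[parcel_cols].to_numpy(),
                     parcels=list(parcel_cols))


def write_aif_table(path, aif: ArterialInput) -> None:
    pd.DataFrame({"time_min": aif.times, "value": aif.values}).to_csv(
        path, index=False, float_format="%.17g")


def read_aif_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an AIF sample table; returns (times, values)."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_min", "value"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    t = df["time_min"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("AIF times must be strictly increasing")
    return t, df["value"].to_numpy(dtype=float)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def default_demo_config() -> dict:
    """Small null-CI demonstration run: 6 subjects, 40 parcels, three sham
    regressors against all five baseline methods at both exclusions."""
    return {
        "seed": 0,
        "cohort": {
            "n_subjects": 6,
            "n_parcels": 40,
            "protocol": "CI",
            "duration_min": 95.0,
            "frame_sec": 16.0,
            "kinetics_cv": 0.15,
            "subject_aif_cv": 0.10,
            "noise_scale": 0.01,
        },
        "sham": {
            "on_min": 10.0,
            "off_min": 10.0,
            "initial_rest_grid_min": [float(r) for r in range(0, 20, 2)],
        },
        "methods": list(METHODS),
        "exclude_initial_min": [0.0, 10.0],
        "fdr_q": 0.05,
    }


def cohort_spec_from_config(config: dict) -> CohortSpec:
    c = config.get("cohort", {})
    protocol = c.get("protocol", "CI")
    duration = float(c.get("duration_min", 95.0))
    if protocol == "B+CI":
        schedule = InfusionSchedule("B+CI", duration=duration,
                                    kbol=float(c.get("kbol_min", 19.3)),
                                    bolus_width=float(c.get("bolus_width_min", 1.0)))
    else:
        schedule = InfusionSchedule("CI", duration=duration)
    task = None
    if "task" in c and c["task"]:
        tconf = c["task"]
        task = TaskSpec(design=BlockDesign(
            on_duration=float(tconf.get("on_min", 10.0)),
            off_duration=float(tconf.get("off_min", 10.0)),
            initial_rest=float(tconf.get("initial_rest_min", 0.0)),
            scan_duration=duration),
            mode=tconf.get("mode", "additive_ramp"),
            effect_size=float(tconf.get("effect_size", 0.04)))
    kin = c.get("kinetics", None)
    center = (KineticParams(*[float(kin[k]) for k in ("K1", "k2", "k3", "k4")])
              if kin else KineticParams.literature())
    return CohortSpec(
        n_subjects=int(c.get("n_subjects", 24)),
        n_parcels=int(c.get("n_parcels", 100)),
        schedule=schedule,
        frame_duration=float(c.get("frame_sec", 16.0)) / 60.0,
        kinetics_center=center,
        kinetics_cv=float(c.get("kinetics_cv", 0.15)),
        subject_aif_cv=float(c.get("subject_aif_cv", 0.10)),
        noise_scale=float(c.get("noise_scale", 0.01)),
        task=task,
        seed=int(config.get("seed", 0)),
    )


def sham_group_analysis(cohort, method: str, design, *,
                        exclude_initial: float = 0.0, fdr_q: float = 0.05,
                        tacs=None):
    """Detrend + sham GLM + group statistics for one analysis condition.

    Applies the named baseline method (with the sham regressor as nuisance
    where the method uses the mean TAC or the AIF, i.e. P3MT and SA) to
    every subject, fits the subject GLMs, computes PSC and aggregates to a
    random-effects group result.  ``tacs`` overrides the cohort's TAC list
    (e.g. parcel-aggregated data).  Returns (GroupResult, subject results).
    """
    results = []
    subject_tacs = cohort.tacs if tacs is None else tacs
    for s, tac in enumerate(subject_tacs):
        spec = BaselineSpec(method=method, exclude_initial=exclude_initial)
        if method in ("P3MT", "SA"):
            spec.task_nuisance = build_task_regressor(design, tac.frame_mid).raw
        fit = detrend(tac, spec, aif=cohort.aifs[s])
        task = build_task_regressor(design, fit.frame_mid)
        if method in ("SA", "EXP2"):
            base_reg = np.stack(
                [np.ones_like(fit.fitted), fit.fitted], axis=1)  # (n, 2, P)
        else:
            base_reg = fit.regressors
        res = fit_subject_glm(tac.values[fit.frames_kept], base_reg, task)
        percent_signal_change(res, fit.fitted, task, fit.frame_mid)
        results.append(res)
    return group_random_effects(results, q=fdr_q), results


def _analysis_cell(cohort: SyntheticCohort, method: str, exclude: float,
                   regressor_entry, fdr_q: float) -> dict:
    """Run one method x exclusion x sham-regressor analysis to group level."""
    design, _, r_ref = regressor_entry
    group, _ = sham_group_analysis(cohort, method, design,
                                   exclude_initial=exclude, fdr_q=fdr_q)
    finite_t = np.clip(group.group_t, -1e3, 1e3)
    return {
        "method": method,
        "exclude_initial_min": exclude,
        "regressor_rest_min": design.initial_rest,
        "regressor_residual_r": r_ref,
        "group_t_rms": float(np.sqrt((finite_t ** 2).mean())),
        "mean_t": float(finite_t.mean()),
        "n_significant": int(group.q_mask.sum()),
        "n_parcels": int(group.group_t.size),
        "mean_psc": float(np.nanmean(group.mean_psc)),
        "mean_abs_significant_psc": float(
            np.nanmean(np.abs(group.mean_psc[group.q_mask]))
            if group.q_mask.any() else 0.0),
    }


def run_pipeline(config: dict, out_dir) -> pd.DataFrame:
    """Execute the full sham-GLM analysis grid and write artifacts.

    Stages: generate the synthetic cohort; detrend every subject with P3MT
    to obtain the reference residual pattern; select three sham regressors
    (high-positive, near-zero, moderately negative correlation with that
    pattern); then run every baseline method x exclusion x sham regressor
    to group level.  Writes the summary grid, per-subject TAC/AIF tables,
    the resolved configuration and version info to ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.get("cohort", {}).get("n_parcels", 1):
        raise ValueError("configuration requests zero parcels")
    spec = cohort_spec_from_config(config)
    log.info("generating cohort: %d subjects, %d parcels",
             spec.n_subjects, spec.n_parcels)
    cohort = generate_cohort(spec)

    # reference residual pattern: cross-subject mean P3MT residual
    ref_spec = BaselineSpec(method="P3MT", exclude_initial=0.0)
    ref_resids = [detrend(tac, ref_spec).mean_residual() for tac in cohort.tacs]
    reference = np.mean(ref_resids, axis=0)

    sham_conf = config.get("sham", {})
    scan = spec.schedule.duration
    candidates = [BlockDesign(on_duration=float(sham_conf.get("on_min", 10.0)),
                              off_duration=float(sham_conf.get("off_min", 10.0)),
                              initial_rest=float(rest), scan_duration=scan)
                  for rest in sham_conf.get("initial_rest_grid_min",
                                            list(range(0, 20, 2)))]
    from .baselines import _poly_design
    sel = select_sham_regressors(
        candidates, reference, cohort.tacs[0].frame_mid,
        orthogonalize_to=_poly_design(cohort.tacs[0].frame_mid))
    picks = [("positive", sel.positive), ("null", sel.null),
             ("negative", sel.negative)]

    rows = []
    for method in config.get("methods", list(METHODS)):
        for exclude in config.get("exclude_initial_min", [0.0, 10.0]):
            for label, entry in picks:
                log.info("analysis cell: %s exclude=%g sham=%s",
                         method, exclude, label)
                cell = _analysis_cell(cohort, method.upper(), float(exclude),
                                      entry, float(config.get("fdr_q", 0.05)))
                cell["sham"] = label
                rows.append(cell)
    grid = pd.DataFrame(rows)
    grid.to_csv(out / "summary_grid.csv", index=False)

    for s, tac in enumerate(cohort.tacs):
        write_tac_table(out / f"sub-{s:02d}_tac.csv", tac)
        write_aif_table(out / f"sub-{s:02d}_aif.csv", cohort.aifs[s])
    truth = pd.DataFrame(cohort.parcel_params, columns=["K1", "k2", "k3", "k4"])
    truth["true_psc"] = cohort.true_psc
    truth.to_csv(out / "ground_truth.csv", index=False)

    resolved = dict(config)
    resolved["_resolved"] = {
        "fpetkit_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "seed": int(config.get("seed", 0)),
        "sham_picks": {label: {"initial_rest_min": e[0].initial_rest,
                               "residual_r": round(e[2], 6)}
                       for label, e in picks},
    }
    save_config(out / "config_resolved.yaml", resolved)
    with open(out / "versions.json", "w") as fh:
        json.dump(resolved["_resolved"], fh, indent=2)
    return grid


def extract_parcel_tacs(volume_path, labels_path, frame_duration: float
                        ) -> FramedTac:
    """Optional volumetric import shim: mean TAC within each label of a 4-D
    image.  Requires ``nibabel``; the core package never depends on it."""
    try:
        import nibabel as nib
    except ImportError as err:  # pragma: no cover
        raise ImportError("volumetric import requires nibabel") from err
    img = np.asarray(nib.load(str(volume_path)).dataobj)
    labels = np.asarray(nib.load(str(labels_path)).dataobj)
    if img.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, frames)")
    ids = [int(v) for v in np.unique(labels) if v != 0]
    n_frames = img.shape[3]
    values = np.empty((n_frames, len(ids)))
    for j, lab in enumerate(ids):
        mask = labels == lab
        values[:, j] = img[mask].mean(axis=0)
    mid = (np.arange(n_frames) + 0.5) * frame_duration
    return FramedTac(frame_mid=mid, frame_dur=frame_duration, values=values,
                     parcels=[f"label_{lab}" for lab in ids])
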