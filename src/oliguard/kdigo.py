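"""KDIGO staging of hourly trajectories and oliguric AKI 2/3 episode detection.

Urine-output staging follows the consecutive-hours reading of the KDIGO
criteria: at each hour the stage is derived from the maximal run of
consecutive hours *ending there* below a rate threshold —

* stage 1: rate < 0.5 ml/kg/h for 6–12 consecutive hours,
* stage 2: rate < 0.5 ml/kg/h for more than 12 consecutive hours,
* stage 3: rate < 0.3 ml/kg/h for at least 24 consecutive hours, or anuria
  (zero output) for at least 12 consecutive hours.

Missing hours break runs: no oliguria is assumed where none was observed.

Creatinine staging is relative to a baseline defined as the lowest value
recorded across all of the patient's admissions: stage 3 at >= 3x baseline or
an absolute value >= 4.0 mg/dL, stage 2 at >= 2x, stage 1 at >= 1.5x or an
absolute rise >= 0.3 mg/dL.

The composite endpoint — hospital-acquired oliguric AKI stage 2/3 — requires
a *simultaneous* reduction in urine output and increase in creatinine: the
episode onset is the first hour with urine stage >= 2 such that the
creatinine stage reaches a configurable floor (default >= 1) somewhere within
a +/- ``co_window_h`` window (default 12 h).  Whether the source endpoint
demanded creatinine stage >= 1 or >= 2 is not documented; both the floor and
the window are therefore explicit parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import HourlyTrajectory

__all__ = [
    "UNKNOWN_STAGE",
    "BaselineCreatinine",
    "AKIEpisode",
    "baseline_creatinine",
    "stage_by_urine",
    "stage_by_creatinine",
    "detect_oliguric_aki23",
    "label_trajectory",
]

#: Sentinel stage for hours where the underlying measurement is missing.
UNKNOWN_STAGE = -1

UO_STAGE1_THRESHOLD = 0.5  # ml/kg/h
UO_STAGE3_THRESHOLD = 0.3  # ml/kg/h
ANURIA_RATE = 0.0


@dataclass(frozen=True)
class BaselineCreatinine:
    """Reference creatinine: the minimum over all provided measurements."""

    patient_id: str
    value_mg_dl: float
    source: str  # "this-stay minimum" | "across-readmissions minimum"


@dataclass(frozen=True)
class AKIEpisode:
    """A detected oliguric AKI stage 2/3 episode."""

    patient_id: str
    onset_hour: int
    max_stage: int
    uo_criterion_met: bool = True
    scr_criterion_met: bool = True


def baseline_creatinine(
    patient_id: str, values_by_stay: list[np.ndarray] | np.ndarray
) -> BaselineCreatinine:
    """Lowest recorded creatinine; across readmissions, the lowest anywhere."""
    if isinstance(values_by_stay, np.ndarray):
        values_by_stay = [values_by_stay]
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in values_by_stay if len(v)]) \
        if any(len(v) for v in values_by_stay) else np.array([])
    if pooled.size == 0:
        raise ValueError(f"patient {patient_id}: no creatinine measurements")
    if np.any(pooled <= 0):
        raise ValueError("creatinine values must be positive")
    source = (
        "across-readmissions minimum" if len(values_by_stay) > 1 else "this-stay minimum"
    )
    return BaselineCreatinine(patient_id, float(pooled.min()), source)


def stage_by_urine(uo_norm: np.ndarray) -> np.ndarray:
    """Per-hour urine-output KDIGO stage track.

    One forward pass maintains the lengths of the runs of consecutive
    observed hours ending at ``h`` with rate < 0.5 (``r``), < 0.3 (``r3``)
    and == 0 (``ra``); the stage at ``h`` follows from those run lengths.
    Returns ``UNKNOWN_STAGE`` where the hour itself is missing.
    """
    uo = np.asarray(uo_norm, dtype=float)
    n = uo.size
    track = np.full(n, UNKNOWN_STAGE, dtype=int)
    r = r3 = ra = 0
    for h in range(n):
        v = uo[h]
        if np.isnan(v):
            r = r3 = ra = 0
            continue
        r = r + 1 if v < UO_STAGE1_THRESHOLD else 0
        r3 = r3 + 1 if v < UO_STAGE3_THRESHOLD else 0
        ra = ra + 1 if v == ANURIA_RATE else 0
        if r3 >= 24 or ra >= 12:
            track[h] = 3
        elif r > 12:
            track[h] = 2
        elif 6 <= r <= 12:
            track[h] = 1
        else:
            track[h] = 0
    return track


def stage_by_creatinine(scr_mg_dl: np.ndarray, baseline: float) -> np.ndarray:
    """Per-hour creatinine KDIGO stage track relative to ``baseline``."""
    if baseline <= 0:
        raise ValueError("baseline creatinine must be positive")
    scr = np.asarray(scr_mg_dl, dtype=float)
    track = np.full(scr.size, UNKNOWN_STAGE, dtype=int)
    obs = ~np.isnan(scr)
    v = scr[obs]
    ratio = v / baseline
    stage = np.zeros(v.size, dtype=int)
    stage[(ratio >= 1.5) | (v - baseline >= 0.3)] = 1
    stage[ratio >= 2.0] = 2
    stage[(ratio >= 3.0) | (v >= 4.0)] = 3
    track[obs] = stage
    return track


def detect_oliguric_aki23(
    uo_track: np.ndarray,
    scr_track: np.ndarray,
    patient_id: str = "",
    co_window_h: int = 12,
    scr_stage_floor: int = 1,
) -> AKIEpisode | None:
    """First hour where urine stage >= 2 co-occurs with a creatinine rise.

    Co-occurrence means creatinine stage >= ``scr_stage_floor`` at some hour
    within ``[h - co_window_h, h + co_window_h]`` (clipped to the stay).
    Returns ``None`` when the composite condition never holds.
    """
    uo_track = np.asarray(uo_track)
    scr_track = np.asarray(scr_track)
    if uo_track.shape != scr_track.shape:
        raise ValueError("stage tracks must be aligned")
    n = uo_track.size
    scr_hit = scr_track >= scr_stage_floor
    for h in range(n):
        if uo_track[h] >= 2:
            lo = max(0, h - co_window_h)
            hi = min(n, h + co_window_h + 1)
            if scr_hit[lo:hi].any():
                return AKIEpisode(
                    patient_id=patient_id,
                    onset_hour=h,
                    max_stage=int(uo_track[h:].max()),
                    uo_criterion_met=True,
                    scr_criterion_met=True,
                )
    return None


def label_trajectory(
    traj: HourlyTrajectory,
    baseline: BaselineCreatinine,
    co_window_h: int = 12,
    scr_stage_floor: int = 1,
) -> AKIEpisode | None:
    """Stage both streams of a trajectory and run episode detection."""
    uo_track = stage_by_urine(traj.uo_norm)
    scr_track = stage_by_creatinine(traj.scr_mg_dl, baseline.value_mg_dl)
    return detect_oliguric_aki23(
        uo_track,
        scr_track,
        patient_id=traj.patient_id,
        co_window_h=co_window_h,
        scr_stage_floor=scr_stage_floor,
    )
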