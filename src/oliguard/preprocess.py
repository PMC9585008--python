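"""Hourly regularization of irregular ICU urine-output and creatinine streams.

Nurse-charted urine output arrives at irregular intervals, with each record
holding the volume accumulated since the previous record.  Laboratory
creatinine arrives whenever a sample was drawn.  Downstream staging and
prediction require a constant 1-hour grid, so this module implements:

* cumulative-split resampling of urine volumes across the hours each record
  covers, provided the silent gap is shorter than ``gap_max_h`` (default 9 h);
* last-observation-carried-forward filling of creatinine, capped at fills
  spanning less than 4 days (95 filled hours beyond the measured bin);
* ideal-body-weight (IBW) normalization of urine output to ml/h/kg, with IBW
  from the Devine formula evaluated at the midpoint of a de-identified height
  range.

Hour bins are half-open ``[h, h+1)`` anchored at admission; a record whose
timestamp falls exactly on a bin boundary closes the earlier bin.  Missing
hours are represented as ``nan``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HourlyTrajectory",
    "compute_ibw",
    "resample_urine_hourly",
    "fill_creatinine",
    "build_trajectory",
]

#: Silent gaps of at least this many whole hours are left missing rather than
#: back-filled from the next cumulative urine record.
URINE_GAP_MAX_H = 9.0

#: A creatinine value is carried forward into at most this many subsequent
#: missing hourly bins (fills must span < 4 days = 96 h, so 95 carried bins).
CREATININE_CARRY_MAX_H = 95

MGDL_PER_UMOLL = 1.0 / 88.4  # µmol/L -> mg/dL, applied only when asked


@dataclass
class HourlyTrajectory:
    """Per-patient hourly grid of urine output and creatinine.

    All three sequences share one length, ``floor(stay hours)``.  ``uo_norm``
    is ``uo_ml_per_h / ibw_kg`` wherever urine output is observed; missing
    bins propagate as ``nan``.
    """

    patient_id: str
    uo_ml_per_h: np.ndarray
    uo_norm: np.ndarray
    scr_mg_dl: np.ndarray
    ibw_kg: float
    age_group: int = 0
    sex: str = "male"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.uo_ml_per_h)
        if not (len(self.uo_norm) == len(self.scr_mg_dl) == n):
            raise ValueError("trajectory sequences must share one length")

    @property
    def n_hours(self) -> int:
        return len(self.uo_ml_per_h)

    def truncated(self, n_hours: int) -> "HourlyTrajectory":
        """Copy of the trajectory cut to its first ``n_hours`` bins."""
        return HourlyTrajectory(
            patient_id=self.patient_id,
            uo_ml_per_h=self.uo_ml_per_h[:n_hours].copy(),
            uo_norm=self.uo_norm[:n_hours].copy(),
            scr_mg_dl=self.scr_mg_dl[:n_hours].copy(),
            ibw_kg=self.ibw_kg,
            age_group=self.age_group,
            sex=self.sex,
            meta=dict(self.meta),
        )


def compute_ibw(sex: str, height_range_cm: tuple[float, float]) -> float:
    """Ideal body weight (kg) from sex and a (possibly degenerate) height range.

    De-identified records report height as a closed range, e.g. 170–179 cm;
    the midpoint is taken as the height.  IBW follows the Devine formula,
    2.3 kg per inch over 5 ft (0.9059 kg/cm over 152.4 cm):

        male:   50   + 0.9059 * (h - 152.4)
        female: 45.5 + 0.9059 * (h - 152.4)

    The result is floored at 40 kg so very short patients do not produce
    implausibly small normalization denominators.
    """
    lo, hi = float(height_range_cm[0]), float(height_range_cm[1])
    if lo > hi:
        raise ValueError(f"height range inverted: {lo}-{hi}")
    if lo < 120.0 or hi > 220.0:
        raise ValueError(f"height range {lo}-{hi} cm outside plausible [120, 220]")
    h = (lo + hi) / 2.0
    if sex == "male":
        ibw = 50.0 + 0.9059 * (h - 152.4)
    elif sex == "female":
        ibw = 45.5 + 0.9059 * (h - 152.4)
    else:
        raise ValueError(f"unknown sex code: {sex!r}")
    return max(ibw, 40.0)


def parse_height_range(text: str) -> tuple[float, float]:
    """Parse the ``"lo-hi"`` height-range encoding (cm)."""
    lo, _, hi = text.partition("-")
    return float(lo), float(hi)


def resample_urine_hourly(
    times_h: np.ndarray,
    volumes_ml: np.ndarray,
    stay_h: float,
    gap_max_h: float = URINE_GAP_MAX_H,
) -> np.ndarray:
    """Spread cumulative urine records onto an hourly grid.

    ``times_h`` are record times in hours since admission (strictly
    increasing); each ``volumes_ml`` entry is the volume accumulated since the
    previous record (or since admission for the first).  A record at time *t*
    closes ``g`` whole hourly bins since the end of the previously covered
    bin.  If ``g < gap_max_h`` the volume is split equally over those ``g``
    bins; otherwise the silent bins stay missing and the whole volume is
    assigned to the record's own bin.  Bins after the last record stay
    missing.  Returns an array of length ``floor(stay_h)`` with ``nan`` for
    missing bins.
    """
    times_h = np.asarray(times_h, dtype=float)
    volumes_ml = np.asarray(volumes_ml, dtype=float)
    n_bins = int(math.floor(stay_h))
    out = np.full(n_bins, np.nan)
    if times_h.size == 0 or n_bins == 0:
        return out
    if np.any(times_h < 0) or np.any(times_h > stay_h + 1e-9):
        raise ValueError("urine record outside the admission interval")
    if np.any(np.diff(times_h) <= 0):
        raise ValueError("urine record times must be strictly increasing")
    if np.any(volumes_ml < 0):
        raise ValueError("urine volumes must be non-negative")

    covered_until = 0  # first hourly bin not yet covered by any record
    for t, vol in zip(times_h, volumes_ml):
        end_bin = int(math.ceil(t))  # boundary timestamps close the earlier bin
        end_bin = min(end_bin, n_bins)
        g = end_bin - covered_until
        if g <= 0:
            # second record inside an already-covered hour: accumulate there
            tgt = min(max(end_bin - 1, 0), n_bins - 1)
            out[tgt] = (0.0 if np.isnan(out[tgt]) else out[tgt]) + vol
            continue
        if g < gap_max_h:
            out[covered_until:end_bin] = vol / g
        else:
            # long silent gap: volume attribution across it would be fiction
            out[end_bin - 1] = vol
        covered_until = end_bin
    return out


def fill_creatinine(
    times_h: np.ndarray,
    values_mg_dl: np.ndarray,
    stay_h: float,
    carry_max_h: int = CREATININE_CARRY_MAX_H,
    umol_per_l: bool = False,
) -> np.ndarray:
    """Place creatinine measurements on the hourly grid with capped LOCF.

    Each measurement lands in its hour bin (several in one bin: the latest
    wins) and is carried forward into at most ``carry_max_h`` subsequent
    missing bins.  Bins before the first measurement, and beyond the cap,
    stay ``nan``.  Set ``umol_per_l`` when values arrive in µmol/L.
    """
    times_h = np.asarray(times_h, dtype=float)
    values = np.asarray(values_mg_dl, dtype=float)
    n_bins = int(math.floor(stay_h))
    out = np.full(n_bins, np.nan)
    if times_h.size == 0 or n_bins == 0:
        return out
    if np.any(values <= 0):
        raise ValueError("creatinine values must be positive")
    if np.any(np.diff(times_h) <= 0):
        raise ValueError("creatinine record times must be strictly increasing")
    if umol_per_l:
        values = values * MGDL_PER_UMOLL

    measured = np.full(n_bins, np.nan)
    for t, v in zip(times_h, values):
        b = int(math.floor(t))
        if t > 0 and t == math.floor(t):
            b -= 1  # boundary timestamp belongs to the earlier bin
        if 0 <= b < n_bins:
            measured[b] = v  # last value in the bin wins

    last_val = np.nan
    age = 0
    for h in range(n_bins):
        if not np.isnan(measured[h]):
            last_val = measured[h]
            age = 0
            out[h] = last_val
        elif not np.isnan(last_val) and age < carry_max_h:
            age += 1
            out[h] = last_val
        # else: before first measurement or past the cap -> stays nan
    return out


def build_trajectory(
    patient_id: str,
    uo_hourly_ml: np.ndarray,
    scr_hourly: np.ndarray,
    ibw_kg: float,
    age_group: int = 0,
    sex: str = "male",
) -> HourlyTrajectory:
    """Assemble an :class:`HourlyTrajectory`, normalizing urine output by IBW."""
    uo_hourly_ml = np.asarray(uo_hourly_ml, dtype=float)
    scr_hourly = np.asarray(scr_hourly, dtype=float)
    if len(uo_hourly_ml) != len(scr_hourly):
        raise ValueError(
            f"length mismatch: uo {len(uo_hourly_ml)} vs scr {len(scr_hourly)}"
        )
    if ibw_kg <= 0:
        raise ValueError("ibw_kg must be positive")
    with np.errstate(invalid="ignore"):
        if np.nanmin(uo_hourly_ml, initial=0.0) < 0:
            raise ValueError("negative urine volume")
    uo_norm = uo_hourly_ml / ibw_kg  # nan propagates bin-wise
    return HourlyTrajectory(
        patient_id=patient_id,
        uo_ml_per_h=uo_hourly_ml,
        uo_norm=uo_norm,
        scr_mg_dl=scr_hourly,
        ibw_kg=float(ibw_kg),
        age_group=age_group,
        sex=sex,
    )
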