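"""Reproducible synthetic ICU cohorts with oliguric-AKI 2/3 signatures.

Real development and validation of urine-output early-warning models relies
on access-controlled ICU databases.  This module generates cohorts with the
statistical structure that the analysis pipeline assumes, so every
downstream stage (resampling, staging, windowing, model fitting, evaluation)
is exercised end to end without any data download:

* irregular nurse-charted urine-output records — each record carries the
  volume accumulated since the previous record — with gamma-distributed
  inter-record intervals whose median is configurable (about 1.3 h for a
  high-frequency "Amsterdam-like" regime, about 2.4 h for an "eICU-like"
  one);
* sparse laboratory creatinine records (median interval about 16 h vs 23 h
  in the two regimes);
* log-normal ICU stay lengths, a configurable age-group/sex mix, and height
  reported only as a 10-cm range (as in de-identified exports), forcing the
  pipeline through the range-midpoint ideal-body-weight path;
* in a configurable fraction of patients (default 4.2%), one hospital-
  acquired event: a contiguous oliguric phase (hourly rate clipped at
  ``event_depth``, default 0.25 ml/kg/h, lasting longer than 12 h) starting
  at least 24 h after admission and at least 12 h before discharge, with
  creatinine rising to at least twice its pre-event level within +/- 12 h of
  onset so the simultaneity-based endpoint is reachable.  Non-event patients
  keep their hourly rate at or above 0.6 ml/kg/h and can never satisfy the
  stage 2/3 urine criterion.

Ground truth (who has an event, and when) is written to a separate
``truth.csv`` that the pipeline never reads; only tests and audits use it.
Identical configurations (including the seed) produce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import kdigo
from .preprocess import compute_ibw

__all__ = [
    "GeneratorConfig",
    "RawCohort",
    "amsterdam_like",
    "eicu_like",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

AGE_GROUPS = ("18-39", "40-49", "50-59", "60-69", "70-79", "80+")

#: Median of the unit-scale gamma with shape 2 (numerical root of the
#: incomplete gamma function); scales inter-record intervals to a target median.
_GAMMA2_UNIT_MEDIAN = 1.6783469900166608

_EPOCH = pd.Timestamp("2014-01-01 00:00:00")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Defaults emulate the high-frequency European acquisition regime: urine
    charted about every 1.3 h (median), creatinine about every 16 h, a 4.2%
    event prevalence, 71% male, and the age mix concentrated in the 60-79
    bands.  ``eicu_like()`` provides the sparser US regime.
    """

    n_patients: int = 2000
    prevalence: float = 0.042
    uo_interval_median_h: float = 1.3
    scr_interval_median_h: float = 16.2
    stay_median_h: float = 40.0
    stay_sigma: float = 0.8  # log-normal shape of stay length
    age_group_weights: tuple[float, ...] = (0.068, 0.073, 0.155, 0.282, 0.306, 0.117)
    male_fraction: float = 0.711
    mortality_fraction: float = 0.089
    baseline_uo_rate: float = 1.5  # ml/h/kg healthy-state mean
    baseline_uo_sd: float = 0.35  # between-patient spread of the mean
    uo_noise_sd: float = 0.25  # hour-to-hour noise on the rate
    uo_floor_healthy: float = 0.6  # healthy rates never fall below this
    baseline_scr_mean: float = 0.85  # mg/dL
    baseline_scr_sd: float = 0.15
    scr_noise_sd: float = 0.04
    event_depth: float = 0.25  # ml/h/kg ceiling during the oliguric phase
    event_duration_min_h: float = 16.0
    event_duration_max_h: float = 36.0
    prodrome_h: float = 36.0  # progressive decline toward oliguria before the phase
    recovery_h: float = 12.0  # climb back to baseline after the phase
    event_scr_fold: float = 2.5
    event_scr_ramp_h: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        for name in ("uo_interval_median_h", "scr_interval_median_h", "stay_median_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        w = np.asarray(self.age_group_weights, dtype=float)
        # printed cohort percentages can sum to 99.9 or 100.1; renormalized at draw
        if w.size != len(AGE_GROUPS) or np.any(w < 0) or not math.isclose(
            w.sum(), 1.0, rel_tol=0, abs_tol=5e-3
        ):
            raise ValueError("age_group_weights must be a probability vector over 6 groups")
        if not self.event_duration_min_h > 12.0:
            raise ValueError("oliguric phase must exceed 12 consecutive hours")
        if self.event_duration_max_h < self.event_duration_min_h:
            raise ValueError("event duration range inverted")
        if not 0.0 < self.event_depth < 0.5:
            raise ValueError("event_depth must sit below the 0.5 ml/kg/h oliguria line")
        if self.event_scr_fold < 2.0:
            raise ValueError("event_scr_fold must be >= 2 to reach creatinine stage 2")
        # Events need stay >= 24 h lead-in + phase + 12 h tail; reject configs
        # whose stay distribution essentially never reaches that.
        min_event_stay = 24.0 + self.event_duration_min_h + 12.0
        stay_p999 = self.stay_median_h * math.exp(3.09 * self.stay_sigma)
        if self.prevalence > 0 and stay_p999 < min_event_stay:
            raise ValueError(
                "event phase does not fit in the configured stay distribution: "
                f"need >= {min_event_stay:.0f} h, 99.9th percentile is {stay_p999:.0f} h"
            )


@dataclass
class RawCohort:
    """Demographics plus irregular measurement streams, as a bundle of tables.

    ``truth`` records the injected ground truth and is segregated from the
    pipeline inputs by construction.
    """

    demographics: pd.DataFrame
    uo_records: pd.DataFrame
    scr_records: pd.DataFrame
    truth: pd.DataFrame


def amsterdam_like(**overrides) -> GeneratorConfig:
    """High-frequency acquisition regime (urine ~1.3 h, creatinine ~16 h)."""
    return replace(GeneratorConfig(), **overrides)


def eicu_like(**overrides) -> GeneratorConfig:
    """Sparse acquisition regime (urine ~2.4 h, creatinine ~23 h, 3% events)."""
    base = GeneratorConfig(
        prevalence=0.030,
        uo_interval_median_h=2.4,
        scr_interval_median_h=23.2,
        stay_median_h=120.0,
        male_fraction=0.632,
        age_group_weights=(0.077, 0.074, 0.163, 0.233, 0.235, 0.218),
    )
    return replace(base, **overrides)


def _interval_times(rng: np.random.Generator, median_h: float, stay_h: float) -> np.ndarray:
    """Record times: gamma(shape 2) inter-record intervals with given median."""
    scale = median_h / _GAMMA2_UNIT_MEDIAN
    times = []
    t = float(rng.gamma(2.0, scale / 2.0))  # first record sooner: admission charting
    while t < stay_h:
        times.append(t)
        t += float(rng.gamma(2.0, scale))
    return np.asarray(times)


def _hourly_rate_curve(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    stay_h: float,
    onset_h: float | None,
    duration_h: float | None,
) -> np.ndarray:
    """True hourly urine rate (ml/h/kg) on a 1-h grid covering the stay.

    Event patients decline progressively from their healthy baseline to the
    oliguric depth over a prodrome, hold the depth through the phase, then
    recover; hourly rates inside the phase are clipped at ``event_depth`` so
    the phase is contiguous oliguria by construction.
    """
    n = int(math.ceil(stay_h))
    base = rng.normal(cfg.baseline_uo_rate, cfg.baseline_uo_sd)
    base = max(base, cfg.uo_floor_healthy + 3.0 * cfg.uo_noise_sd)
    rate = rng.normal(base, cfg.uo_noise_sd, size=n)
    rate = np.clip(rate, cfg.uo_floor_healthy, None)
    if onset_h is not None:
        hours = np.arange(n, dtype=float) + 0.5
        prodrome = cfg.prodrome_h * rng.uniform(0.75, 1.25)
        envelope = np.interp(
            hours,
            [onset_h - prodrome, onset_h, onset_h + duration_h,
             onset_h + duration_h + cfg.recovery_h],
            [base, cfg.event_depth, cfg.event_depth, base],
        )
        sick = envelope < base
        noisy = envelope + rng.normal(0.0, cfg.uo_noise_sd, size=n)
        lo = int(round(onset_h))
        hi = min(n, int(round(onset_h + duration_h)))
        rate[sick] = np.clip(noisy[sick], 0.02, None)
        rate[lo:hi] = np.clip(rate[lo:hi], 0.02, cfg.event_depth)
    return rate


def _volumes_from_rate(
    rate_per_kg: np.ndarray, ibw_kg: float, times_h: np.ndarray
) -> np.ndarray:
    """Integrate the hourly rate curve over each inter-record interval."""
    n = rate_per_kg.size
    knots = np.arange(n + 1, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(rate_per_kg)])  # ml/kg at whole hours
    cum_at = np.interp(np.clip(times_h, 0.0, n), knots, cum)
    prev = np.concatenate([[0.0], cum_at[:-1]])
    return (cum_at - prev) * ibw_kg


def _scr_value(
    t_h: float,
    baseline: float,
    cfg: GeneratorConfig,
    rise_start_h: float | None,
) -> float:
    if rise_start_h is None or t_h < rise_start_h:
        return baseline
    frac = min(1.0, (t_h - rise_start_h) / cfg.event_scr_ramp_h)
    return baseline * (1.0 + (cfg.event_scr_fold - 1.0) * frac)


def generate_cohort(config: GeneratorConfig) -> RawCohort:
    """Draw a full synthetic cohort from ``config`` (deterministic in the seed)."""
    config.validate()
    rng = np.random.Generator(np.random.PCG64(config.seed))
    mu = math.log(config.stay_median_h)
    age_w = np.asarray(config.age_group_weights, dtype=float)
    age_w = age_w / age_w.sum()

    demo_rows, uo_rows, scr_rows, truth_rows = [], [], [], []
    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        has_event = bool(rng.random() < config.prevalence)

        duration = onset = None
        if has_event:
            duration = float(
                rng.uniform(config.event_duration_min_h, config.event_duration_max_h)
            )
            need = 24.0 + duration + 12.0
            for _ in range(1000):
                stay_h = float(rng.lognormal(mu, config.stay_sigma))
                if stay_h >= need:
                    break
            else:
                raise RuntimeError("could not draw a stay long enough for an event")
            onset = float(rng.uniform(24.0, stay_h - 12.0 - duration))
        else:
            stay_h = max(float(rng.lognormal(mu, config.stay_sigma)), 6.0)

        sex = "male" if rng.random() < config.male_fraction else "female"
        age_group = AGE_GROUPS[int(rng.choice(len(AGE_GROUPS), p=age_w))]
        height = rng.normal(177.0 if sex == "male" else 164.0, 7.0)
        height = float(np.clip(height, 125.0, 210.0))
        lo = int(height // 10 * 10)
        height_range = f"{lo}-{lo + 9}"
        ibw = compute_ibw(sex, (lo, lo + 9))
        died = bool(rng.random() < config.mortality_fraction)

        admit = _EPOCH + pd.Timedelta(days=i)  # deterministic staggering
        discharge = (admit + pd.Timedelta(hours=stay_h)).floor('s')
        demo_rows.append(
            {
                "patient_id": pid,
                "sex": sex,
                "age_group": age_group,
                "height_range_cm": height_range,
                "admit_time": admit,
                "discharge_time": discharge,
                "died_in_hospital": int(died),
            }
        )

        scr_base = float(
            np.clip(rng.normal(config.baseline_scr_mean, config.baseline_scr_sd), 0.5, None)
        )
        rise_start = onset + float(rng.uniform(-6.0, 2.0)) if has_event else None

        # --- urine output stream ---------------------------------------
        rate = _hourly_rate_curve(rng, config, stay_h, onset, duration)
        uo_times = _interval_times(rng, config.uo_interval_median_h, stay_h)
        if uo_times.size:
            vols = _volumes_from_rate(rate, ibw, uo_times)
            for t, v in zip(uo_times, vols):
                uo_rows.append(
                    {
                        "patient_id": pid,
                        "timestamp": (admit + pd.Timedelta(hours=t)).floor("s"),
                        "volume_ml": round(float(v), 1),
                    }
                )

        # --- creatinine stream ------------------------------------------
        scr_times = list(_interval_times(rng, config.scr_interval_median_h, stay_h))
        if has_event:
            # confirmatory laboratory sample once the patient deteriorates,
            # guaranteeing an observed >= 2x rise within +/- 12 h of onset
            confirm_t = min(onset + float(rng.uniform(4.0, 10.0)), stay_h - 1e-6)
            scr_times.append(confirm_t)
        scr_times = np.unique(np.asarray(scr_times))
        for t in scr_times:
            v = _scr_value(float(t), scr_base, config, rise_start)
            v += float(rng.normal(0.0, config.scr_noise_sd))
            if rise_start is not None and t >= rise_start + config.event_scr_ramp_h:
                v = max(v, 2.05 * scr_base)  # noise must not mask the rise
            scr_rows.append(
                {
                    "patient_id": pid,
                    "timestamp": (admit + pd.Timedelta(hours=float(t))).floor("s"),
                    "value_mg_dl": round(max(v, 0.2), 2),
                }
            )

        # KDIGO stage 2 needs > 12 consecutive oliguric hours, so the *event*
        # onset — first hour the composite stage 2/3 condition holds — lags
        # the start of the decline.  It is computed exactly by staging the
        # generator's own true (pre-sampling) hourly curves.
        true_onset: float | str = ""
        if has_event:
            n_h = rate.size
            true_scr = np.array(
                [_scr_value(h + 0.5, scr_base, config, rise_start) for h in range(n_h)]
            )
            ep = kdigo.detect_oliguric_aki23(
                kdigo.stage_by_urine(rate),
                kdigo.stage_by_creatinine(true_scr, scr_base),
                patient_id=pid,
            )
            if ep is None:  # unreachable by construction of the phase
                raise RuntimeError(f"injected event for {pid} fails its own criteria")
            true_onset = ep.onset_hour
        truth_rows.append(
            {
                "patient_id": pid,
                "has_event": int(has_event),
                "true_onset_hour": true_onset,
                "oliguria_start_hour": round(onset, 2) if has_event else "",
            }
        )

    demographics = pd.DataFrame(
        demo_rows,
        columns=[
            "patient_id",
            "sex",
            "age_group",
            "height_range_cm",
            "admit_time",
            "discharge_time",
            "died_in_hospital",
        ],
    )
    uo_records = pd.DataFrame(uo_rows, columns=["patient_id", "timestamp", "volume_ml"])
    scr_records = pd.DataFrame(scr_rows, columns=["patient_id", "timestamp", "value_mg_dl"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "has_event", "true_onset_hour", "oliguria_start_hour"],
    )
    return RawCohort(demographics, uo_records, scr_records, truth)


_FILES = {
    "demographics": "demographics.csv",
    "uo_records": "urine_output.csv",
    "scr_records": "creatinine.csv",
    "truth": "truth.csv",
}


def write_cohort(cohort: RawCohort, directory: str | Path, overwrite: bool = False) -> list[Path]:
    """Write the four cohort CSVs; refuses to clobber unless ``overwrite``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for attr, fname in _FILES.items():
        path = directory / fname
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
        df = getattr(cohort, attr).copy()
        for col in ("timestamp", "admit_time", "discharge_time"):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
        df.to_csv(path, index=False)
        paths.append(path)
    return paths


def read_cohort(directory: str | Path, with_truth: bool = False) -> RawCohort:
    """Read a cohort written by :func:`write_cohort`.

    ``truth.csv`` is loaded only on explicit request; the analysis pipeline
    never asks for it.
    """
    directory = Path(directory)

    def _load(fname: str, time_cols: tuple[str, ...]) -> pd.DataFrame:
        df = pd.read_csv(directory / fname)
        for col in time_cols:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        return df

    demographics = _load(_FILES["demographics"], ("admit_time", "discharge_time"))
    uo = _load(_FILES["uo_records"], ("timestamp",))
    scr = _load(_FILES["scr_records"], ("timestamp",))
    if with_truth:
        truth = pd.read_csv(directory / _FILES["truth"])
    else:
        truth = pd.DataFrame(
            columns=["patient_id", "has_event", "true_onset_hour", "oliguria_start_hour"]
        )
    return RawCohort(demographics, uo, scr, truth)
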