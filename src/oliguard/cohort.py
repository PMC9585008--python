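"""Inclusion/exclusion, case truncation, and 12-h sliding-window extraction.

The study design predicts, for every hour of an ICU stay, whether an
oliguric AKI stage 2/3 episode will begin within the following 24 h, from
the preceding 12 h of IBW-normalized urine output plus simple covariates.
To guarantee a clinically useful lead time, the trajectory of every patient
who develops an episode is truncated 6 h before its onset before any
windows are cut, so each positive window ends at least 6 h ahead of the
event; control trajectories are used whole, admission to discharge.

Exclusion criteria applied before windowing (all thresholds configurable):
no urine records or more than 30% missing hourly urine bins; no creatinine
measurements; stay under 24 h; composite stage 2/3 already satisfied within
the first 12 h (a proxy for community-acquired AKI); cases whose onset is
too early to leave a full 12-h window after truncation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kdigo import AKIEpisode
from .preprocess import HourlyTrajectory

__all__ = [
    "ExclusionLog",
    "WINDOW_H",
    "HORIZON_H",
    "LEAD_H",
    "apply_inclusion_exclusion",
    "truncate_case_trajectory",
    "make_windows",
    "windows_table",
]

WINDOW_H = 12  # observation window length (hours)
HORIZON_H = 24  # prediction horizon (hours)
LEAD_H = 6  # guaranteed lead time: cases truncated this far before onset

REASONS = (
    "missing_uo",
    "missing_scr",
    "event_unlabelable",
    "stay_too_short",
    "aki_at_admission",
)


@dataclass
class ExclusionLog:
    """One decision per input patient; partition of the cohort is an invariant."""

    records: pd.DataFrame  # columns: patient_id, decision, reason

    @property
    def included_ids(self) -> list[str]:
        df = self.records
        return df.loc[df.decision == "included", "patient_id"].tolist()

    def counts(self) -> pd.Series:
        return self.records.groupby("reason", dropna=False).size()


def apply_inclusion_exclusion(
    trajectories: dict[str, HourlyTrajectory],
    episodes: dict[str, AKIEpisode | None],
    min_stay_h: int = 24,
    max_uo_missing_frac: float = 0.30,
    admission_aki_window_h: int = 12,
) -> ExclusionLog:
    """Screen every patient once and log the decision.

    Checks run in a fixed order (stay length, urine completeness, creatinine
    availability, AKI already present on admission, unlabelable case); the
    first failure determines the recorded reason.
    """
    rows = []
    for pid, traj in trajectories.items():
        episode = episodes.get(pid)
        reason = None
        if traj.n_hours < min_stay_h:
            reason = "stay_too_short"
        elif np.all(np.isnan(traj.uo_norm)) or (
            np.mean(np.isnan(traj.uo_norm)) > max_uo_missing_frac
        ):
            reason = "missing_uo"
        elif np.all(np.isnan(traj.scr_mg_dl)):
            reason = "missing_scr"
        elif episode is not None and episode.onset_hour < admission_aki_window_h:
            reason = "aki_at_admission"
        elif episode is not None and episode.onset_hour - LEAD_H < WINDOW_H:
            reason = "event_unlabelable"
        decision = "included" if reason is None else "excluded"
        rows.append({"patient_id": pid, "decision": decision, "reason": reason or ""})
    return ExclusionLog(pd.DataFrame(rows, columns=["patient_id", "decision", "reason"]))


def truncate_case_trajectory(
    traj: HourlyTrajectory, episode: AKIEpisode | None
) -> HourlyTrajectory:
    """Cut a case trajectory to ``[0, onset - 6)``; controls pass through whole."""
    if episode is None:
        return traj
    usable = episode.onset_hour - LEAD_H
    if usable < WINDOW_H:
        raise ValueError(
            f"patient {traj.patient_id}: onset at hour {episode.onset_hour} leaves "
            f"{usable} usable hours (< {WINDOW_H}); unlabelable"
        )
    return traj.truncated(usable)


def make_windows(
    traj: HourlyTrajectory,
    episode: AKIEpisode | None,
    baseline_mg_dl: float,
    window_h: int = WINDOW_H,
    horizon_h: int = HORIZON_H,
) -> pd.DataFrame:
    """Cut unit-stride sliding windows from an (already truncated) trajectory.

    A window ending at hour ``e`` spans bins ``[e - window_h, e)`` and is
    emitted only when all its urine bins are observed and creatinine is
    available at the window's last bin (needed as a covariate).  Its label is
    1 when the episode onset falls in ``(e, e + horizon_h]``.
    """
    n = traj.n_hours
    rows = []
    onset = episode.onset_hour if episode is not None else None
    uo_ok = ~np.isnan(traj.uo_norm)
    for e in range(window_h, n + 1):
        seg = traj.uo_norm[e - window_h : e]
        if not uo_ok[e - window_h : e].all():
            continue
        scr_now = traj.scr_mg_dl[e - 1]
        if np.isnan(scr_now):
            continue
        label = int(onset is not None and e < onset <= e + horizon_h)
        rows.append(
            {
                "patient_id": traj.patient_id,
                "window_end_hour": e,
                **{f"uo_h{i + 1}": seg[i] for i in range(window_h)},
                "age_group": traj.age_group,
                "sex": traj.sex,
                "scr_now": scr_now,
                "scr_ratio": scr_now / baseline_mg_dl,
                "label": label,
            }
        )
    cols = (
        ["patient_id", "window_end_hour"]
        + [f"uo_h{i + 1}" for i in range(window_h)]
        + ["age_group", "sex", "scr_now", "scr_ratio", "label"]
    )
    return pd.DataFrame(rows, columns=cols)


def windows_table(
    trajectories: dict[str, HourlyTrajectory],
    episodes: dict[str, AKIEpisode | None],
    baselines: dict[str, float],
    included_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Truncate-and-window every included patient into one samples table."""
    ids = included_ids if included_ids is not None else list(trajectories)
    parts = []
    for pid in ids:
        traj = truncate_case_trajectory(trajectories[pid], episodes.get(pid))
        w = make_windows(traj, episodes.get(pid), baselines[pid])
        if not w.empty:
            parts.append(w)
    if not parts:
        return make_windows(
            HourlyTrajectory("", np.array([]), np.array([]), np.array([]), 60.0),
            None,
            1.0,
        )
    return pd.concat(parts, ignore_index=True)
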