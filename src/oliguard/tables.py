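"""Published reference operating points and their arithmetic validation.

The external-validation study this pipeline re-implements reports, for each
model (multi-feature logistic regression, deep learning) and each test
cohort (AmsterdamUMC, eICU), two operating points — fixed 80% sensitivity
and the ROC knee point — each with sensitivity, specificity, LR+ and LR−
printed to two decimals.  Sensitivity and specificity are printed as whole
percentages, so the unrounded values behind a printed pair (s, p) can lie
anywhere in s ± 0.5 and p ± 0.5 percentage points.  ``validate_reference_tables``
recomputes each likelihood ratio from its own row's sensitivity/specificity
and flags the printed cells that cannot be produced by ANY value in that
rounding interval: those are internally inconsistent (likely typographical).
"""

from __future__ import annotations

import pandas as pd

from .evaluation import round_half_away

__all__ = ["REFERENCE_ROWS", "validate_reference_tables"]

# model, dataset, working point, reported auROC, sens %, spec %, LR+, LR-
REFERENCE_ROWS: tuple[dict, ...] = (
    {"model": "logistic", "dataset": "AmsterdamUMC", "working_point": "sensitivity_80",
     "auroc": 0.88, "sens_pct": 80, "spec_pct": 81, "lr_pos": 4.21, "lr_neg": 0.25},
    {"model": "logistic", "dataset": "AmsterdamUMC", "working_point": "knee_point",
     "auroc": 0.88, "sens_pct": 81, "spec_pct": 80, "lr_pos": 4.05, "lr_neg": 0.24},
    {"model": "logistic", "dataset": "eICU", "working_point": "sensitivity_80",
     "auroc": 0.85, "sens_pct": 80, "spec_pct": 75, "lr_pos": 3.20, "lr_neg": 0.31},
    {"model": "logistic", "dataset": "eICU", "working_point": "knee_point",
     "auroc": 0.85, "sens_pct": 77, "spec_pct": 78, "lr_pos": 3.52, "lr_neg": 0.29},
    {"model": "deep_learning", "dataset": "AmsterdamUMC", "working_point": "sensitivity_80",
     "auroc": 0.91, "sens_pct": 80, "spec_pct": 89, "lr_pos": 7.27, "lr_neg": 0.22},
    {"model": "deep_learning", "dataset": "AmsterdamUMC", "working_point": "knee_point",
     "auroc": 0.91, "sens_pct": 85, "spec_pct": 85, "lr_pos": 5.67, "lr_neg": 0.18},
    {"model": "deep_learning", "dataset": "eICU", "working_point": "sensitivity_80",
     "auroc": 0.89, "sens_pct": 80, "spec_pct": 84, "lr_pos": 5.00, "lr_neg": 0.20},
    {"model": "deep_learning", "dataset": "eICU", "working_point": "knee_point",
     "auroc": 0.89, "sens_pct": 82, "spec_pct": 82, "lr_pos": 4.50, "lr_neg": 0.22},
)

_HALF_PCT = 0.005  # printed integer percentages hide up to half a point


def _lr_intervals(sens_pct: float, spec_pct: float) -> tuple[tuple[float, float], tuple[float, float]]:
    s_lo, s_hi = sens_pct / 100 - _HALF_PCT, sens_pct / 100 + _HALF_PCT
    p_lo, p_hi = spec_pct / 100 - _HALF_PCT, spec_pct / 100 + _HALF_PCT
    lr_pos = (s_lo / (1 - p_lo), s_hi / (1 - p_hi))
    lr_neg = ((1 - s_hi) / p_hi, (1 - s_lo) / p_lo)
    return lr_pos, lr_neg


def validate_reference_tables() -> pd.DataFrame:
    """Recompute every printed LR from its row's sens/spec; flag impossibilities.

    A printed cell counts as consistent when it matches the LR of some
    sensitivity/specificity pair inside the half-percentage-point rounding
    interval, itself rounded to the printed two decimals (so an extra 0.005
    of slack on the LR).  The returned frame carries the recomputed point
    value, the achievable interval, and a consistency flag per cell.
    """
    rows = []
    for r in REFERENCE_ROWS:
        s, p = r["sens_pct"] / 100.0, r["spec_pct"] / 100.0
        (pos_lo, pos_hi), (neg_lo, neg_hi) = _lr_intervals(r["sens_pct"], r["spec_pct"])
        rows.append(
            {
                **r,
                "lr_pos_computed": round_half_away(s / (1 - p), 2),
                "lr_neg_computed": round_half_away((1 - s) / p, 2),
                "lr_pos_consistent": pos_lo - 0.005 <= r["lr_pos"] <= pos_hi + 0.005,
                "lr_neg_consistent": neg_lo - 0.005 <= r["lr_neg"] <= neg_hi + 0.005,
            }
        )
    return pd.DataFrame(rows)
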