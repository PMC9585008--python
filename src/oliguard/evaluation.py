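"""ROC analysis, operating points, and likelihood ratios.

Discrimination of the window scores is summarized exactly the way clinical
early-warning validations report it: the ROC curve (sensitivity against
1 − specificity over every score cut-off), its area (trapezoidal rule, which
equals the Mann–Whitney concordance probability with ties counted half),
the Hanley–McNeil standard error of the area, and two operating points —

* fixed sensitivity: the cut-off with the highest specificity among those
  reaching a target sensitivity (80% by convention);
* knee point: the cut-off closest, in Euclidean ROC distance, to the ideal
  corner of perfect sensitivity and specificity (Youden's J is available as
  an alternative).

Each operating point carries the positive and negative likelihood ratios,

    LR+ = sensitivity / (1 - specificity)        (> 1 is informative)
    LR- = (1 - sensitivity) / specificity        (< 1 is informative)

which multiply a patient's pre-test odds of the event after a positive or
negative alert.  Reported tables round to two decimals, half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

__all__ = [
    "ROCCurve",
    "OperatingPoint",
    "roc_curve",
    "auc_standard_error",
    "likelihood_ratios",
    "operating_point_fixed_sensitivity",
    "knee_point",
    "patient_level_scores",
    "render_report",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (matches how printed clinical tables round)."""
    if not math.isfinite(x):
        return x
    q = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


@dataclass
class ROCCurve:
    """Threshold sweep: ``sensitivity[i]``/``specificity[i]`` hold for
    ``score >= thresholds[i]`` calls; endpoints (1, 0) and (0, 1) included."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float  # fraction
    specificity: float  # fraction
    lr_pos: float
    lr_neg: float
    selection_rule: str


def roc_curve(scores, labels) -> ROCCurve:
    """Full threshold sweep with trapezoidal AUC and Hanley–McNeil SE."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        auc_se=auc_standard_error(auc, n_pos, n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc_standard_error(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil standard error of a trapezoidal AUC."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class counts must be positive")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """(LR+, LR-) from fractional sensitivity/specificity; ``inf`` at the poles."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    lr_pos = math.inf if specificity == 1.0 else sensitivity / (1.0 - specificity)
    lr_neg = math.inf if specificity == 0.0 else (1.0 - sensitivity) / specificity
    return lr_pos, lr_neg


def _make_point(roc: ROCCurve, i: int, rule: str) -> OperatingPoint:
    sens = float(roc.sensitivity[i])
    spec = float(roc.specificity[i])
    lr_pos, lr_neg = likelihood_ratios(sens, spec)
    return OperatingPoint(
        threshold=float(roc.thresholds[i]),
        sensitivity=sens,
        specificity=spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        selection_rule=rule,
    )


def operating_point_fixed_sensitivity(roc: ROCCurve, target: float = 0.80) -> OperatingPoint:
    """Highest-specificity cut-off among those with sensitivity >= ``target``.

    Ties on specificity break toward the higher threshold.
    """
    ok = np.flatnonzero(roc.sensitivity >= target)
    if ok.size == 0:
        raise ValueError(f"no threshold reaches sensitivity {target:.0%}")
    spec = roc.specificity[ok]
    best = spec.max()
    cand = ok[spec == best]
    i = cand[np.argmax(roc.thresholds[cand])]
    return _make_point(roc, int(i), f"fixed_sensitivity_{int(round(target * 100))}")


def knee_point(roc: ROCCurve, method: str = "distance") -> OperatingPoint:
    """Operating point nearest the ideal ROC corner.

    ``method='distance'`` minimizes sqrt((1-sens)^2 + (1-spec)^2), ties
    toward higher sensitivity; ``method='youden'`` maximizes sens + spec - 1.
    """
    if method == "distance":
        crit = -np.hypot(1.0 - roc.sensitivity, 1.0 - roc.specificity)
    elif method == "youden":
        crit = roc.sensitivity + roc.specificity - 1.0
    else:
        raise ValueError(f"unknown knee method {method!r}")
    best = crit.max()
    cand = np.flatnonzero(crit == best)
    i = cand[np.argmax(roc.sensitivity[cand])]
    return _make_point(roc, int(i), "knee_point")


def patient_level_scores(
    window_scores: pd.DataFrame, agg: str = "max"
) -> pd.Series:
    """Aggregate window scores (columns patient_id, score) per patient.

    ``max`` gives alert semantics — a patient flags if any window flags;
    ``mean`` is available as an alternative.
    """
    if agg not in ("max", "mean"):
        raise ValueError(f"unknown aggregation {agg!r}")
    return window_scores.groupby("patient_id")["score"].agg(agg)


def render_report(rows: list[dict], path=None) -> pd.DataFrame:
    """Tabulate per-(model, cohort, operating point) metrics, two-decimal cells.

    Each input row needs model, dataset, working_point, auroc, sensitivity
    and specificity as fractions, lr_pos, lr_neg.  LR cells are re-derived
    from the row's own (unrounded) sensitivity/specificity, so the printed
    table is internally consistent by construction.
    """
    out = []
    for r in rows:
        lr_pos, lr_neg = likelihood_ratios(r["sensitivity"], r["specificity"])
        out.append(
            {
                "model": r["model"],
                "dataset": r["dataset"],
                "working_point": r["working_point"],
                "auroc": round_half_away(r["auroc"], 3),
                "sensitivity_pct": round_half_away(100.0 * r["sensitivity"], 0),
                "specificity_pct": round_half_away(100.0 * r["specificity"], 0),
                "lr_pos": round_half_away(lr_pos, 2),
                "lr_neg": round_half_away(lr_neg, 2),
            }
        )
    df = pd.DataFrame(
        out,
        columns=[
            "model",
            "dataset",
            "working_point",
            "auroc",
            "sensitivity_pct",
            "specificity_pct",
            "lr_pos",
            "lr_neg",
        ],
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
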