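"""End-to-end orchestration: generate → preprocess → label → window → fit →
evaluate, mirroring the train-on-one-cohort / externally-validate-on-another
study design on synthetic data.

A single global seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence`` spawning, so each stage (cohort A generation,
cohort B generation, the train/test split, network initialization) is
independently reproducible.  Every filtering step logs patient counts so a
run can be audited like a cohort-selection flow diagram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cb
from . import evaluation as ev
from . import kdigo, models, preprocess, synthetic

__all__ = ["PipelineConfig", "PreprocessedCohort", "prepare_cohort", "run_study", "stage_seeds"]

log = logging.getLogger("oliguard")


def stage_seeds(global_seed: int, n: int = 8) -> list[int]:
    """Fan one global seed out to independent per-stage seeds (< 2^31)."""
    children = np.random.SeedSequence(global_seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


@dataclass
class PipelineConfig:
    """Everything a full study run depends on, in one validated object."""

    train_cohort: synthetic.GeneratorConfig = field(default_factory=synthetic.amsterdam_like)
    external_cohort: synthetic.GeneratorConfig = field(
        default_factory=lambda: synthetic.eicu_like()
    )
    co_window_h: int = 12
    scr_stage_floor: int = 1
    test_fraction: float = 0.30
    knee_method: str = "distance"
    patient_agg: str = "max"
    convnet: models.ConvNetSpec = field(default_factory=models.ConvNetSpec)
    seed: int = 0

    def validate(self) -> None:
        self.train_cohort.validate()
        self.external_cohort.validate()
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        for name in ("co_window_h", "scr_stage_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "train_cohort" in raw:
            kwargs["train_cohort"] = synthetic.GeneratorConfig(
                **{**raw["train_cohort"],
                   **({"age_group_weights": tuple(raw["train_cohort"]["age_group_weights"])}
                      if "age_group_weights" in raw["train_cohort"] else {})}
            )
        if "external_cohort" in raw:
            base = synthetic.eicu_like()
            kwargs["external_cohort"] = replace(base, **raw["external_cohort"])
        if "convnet" in raw:
            cn = dict(raw["convnet"])
            if "kernel_sizes" in cn:
                cn["kernel_sizes"] = tuple(cn["kernel_sizes"])
            kwargs["convnet"] = models.ConvNetSpec(**cn)
        for key in ("co_window_h", "scr_stage_floor", "test_fraction", "knee_method",
                    "patient_agg", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class PreprocessedCohort:
    """A cohort carried through preprocessing, labeling and windowing."""

    name: str
    trajectories: dict[str, preprocess.HourlyTrajectory]
    baselines: dict[str, float]
    episodes: dict[str, kdigo.AKIEpisode | None]
    exclusion_log: cb.ExclusionLog
    windows: pd.DataFrame

    @property
    def included_ids(self) -> list[str]:
        return self.exclusion_log.included_ids

    def patient_event_status(self) -> dict[str, int]:
        return {
            pid: int(self.episodes.get(pid) is not None) for pid in self.included_ids
        }


def _hours_since_admit(ts: pd.Series, admit: pd.Timestamp) -> np.ndarray:
    return (ts - admit).dt.total_seconds().to_numpy() / 3600.0


def prepare_cohort(
    raw: synthetic.RawCohort,
    name: str = "cohort",
    co_window_h: int = 12,
    scr_stage_floor: int = 1,
) -> PreprocessedCohort:
    """Resample, stage and window one raw cohort, logging each filtering step."""
    uo_by_pid = dict(tuple(raw.uo_records.groupby("patient_id", sort=False)))
    scr_by_pid = dict(tuple(raw.scr_records.groupby("patient_id", sort=False)))

    trajectories: dict[str, preprocess.HourlyTrajectory] = {}
    baselines: dict[str, float] = {}
    episodes: dict[str, kdigo.AKIEpisode | None] = {}
    no_scr: set[str] = set()

    for row in raw.demographics.itertuples(index=False):
        pid = row.patient_id
        stay_h = (row.discharge_time - row.admit_time).total_seconds() / 3600.0
        ibw = preprocess.compute_ibw(
            row.sex, preprocess.parse_height_range(row.height_range_cm)
        )

        uo = uo_by_pid.get(pid)
        if uo is not None:
            t = _hours_since_admit(uo["timestamp"], row.admit_time)
            uo_hourly = preprocess.resample_urine_hourly(
                t, uo["volume_ml"].to_numpy(float), stay_h
            )
        else:
            uo_hourly = np.full(int(np.floor(stay_h)), np.nan)

        scr = scr_by_pid.get(pid)
        if scr is not None and len(scr):
            t = _hours_since_admit(scr["timestamp"], row.admit_time)
            vals = scr["value_mg_dl"].to_numpy(float)
            scr_hourly = preprocess.fill_creatinine(t, vals, stay_h)
            baseline = kdigo.baseline_creatinine(pid, vals).value_mg_dl
        else:
            scr_hourly = np.full(int(np.floor(stay_h)), np.nan)
            baseline = np.nan
            no_scr.add(pid)

        traj = preprocess.build_trajectory(
            pid, uo_hourly, scr_hourly, ibw, age_group=row.age_group, sex=row.sex
        )
        trajectories[pid] = traj
        baselines[pid] = baseline
        if pid in no_scr:
            episodes[pid] = None
        else:
            episodes[pid] = kdigo.label_trajectory(
                traj,
                kdigo.BaselineCreatinine(pid, baseline, "this-stay minimum"),
                co_window_h=co_window_h,
                scr_stage_floor=scr_stage_floor,
            )

    exclusion_log = cb.apply_inclusion_exclusion(trajectories, episodes)
    included = exclusion_log.included_ids
    n_events = sum(episodes[p] is not None for p in included)
    log.info(
        "[%s] %d patients -> %d included (%d labeled events); exclusions: %s",
        name,
        len(trajectories),
        len(included),
        n_events,
        exclusion_log.counts().to_dict(),
    )
    windows = cb.windows_table(trajectories, episodes, baselines, included)
    log.info(
        "[%s] %d windows (%d positive)", name, len(windows), int(windows["label"].sum())
    )
    return PreprocessedCohort(name, trajectories, baselines, episodes, exclusion_log, windows)


def _patient_split(
    status: dict[str, int], test_fraction: float, seed: int
) -> tuple[set[str], set[str]]:
    """Patient-level train/test split, stratified by event status."""
    rng = np.random.Generator(np.random.PCG64(seed))
    train, test = set(), set()
    for label in (0, 1):
        ids = sorted(p for p, s in status.items() if s == label)
        ids = list(rng.permutation(ids))
        n_test = int(round(test_fraction * len(ids)))
        test.update(ids[:n_test])
        train.update(ids[n_test:])
    return train, test


def _evaluate(
    name: str,
    model_name: str,
    scores: np.ndarray,
    windows: pd.DataFrame,
    knee_method: str,
    patient_agg: str,
    patient_status: dict[str, int],
) -> dict:
    labels = windows["label"].to_numpy(int)
    roc = ev.roc_curve(scores, labels)
    op80 = ev.operating_point_fixed_sensitivity(roc, 0.80)
    knee = ev.knee_point(roc, knee_method)

    per_patient = ev.patient_level_scores(
        pd.DataFrame({"patient_id": windows["patient_id"], "score": scores}),
        agg=patient_agg,
    )
    pt_labels = np.array([patient_status[p] for p in per_patient.index])
    pt_roc = (
        ev.roc_curve(per_patient.to_numpy(), pt_labels)
        if 0 < pt_labels.sum() < len(pt_labels)
        else None
    )
    return {
        "model": model_name,
        "dataset": name,
        "roc": roc,
        "op_fixed80": op80,
        "op_knee": knee,
        "patient_auc": pt_roc.auc if pt_roc is not None else np.nan,
        "patient_auc_se": pt_roc.auc_se if pt_roc is not None else np.nan,
    }


def run_study(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Full study run; returns all fitted models, metrics and artifacts.

    Trains both predictors on a patient-level split of cohort A, evaluates
    on the held-out A split and on the independently generated cohort B, and
    (when ``outdir`` is given) writes windows, exclusion logs, predictions,
    metrics.csv and the rendered report.
    """
    config.validate()
    seeds = stage_seeds(config.seed)
    cohort_a_cfg = replace(config.train_cohort, seed=seeds[0])
    cohort_b_cfg = replace(config.external_cohort, seed=seeds[1])

    raw_a = synthetic.generate_cohort(cohort_a_cfg)
    raw_b = synthetic.generate_cohort(cohort_b_cfg)
    coh_a = prepare_cohort(raw_a, "cohort_A", config.co_window_h, config.scr_stage_floor)
    coh_b = prepare_cohort(raw_b, "cohort_B", config.co_window_h, config.scr_stage_floor)

    status_a = coh_a.patient_event_status()
    train_ids, test_ids = _patient_split(status_a, config.test_fraction, seeds[2])
    win_a = coh_a.windows
    tr = win_a[win_a.patient_id.isin(train_ids)].reset_index(drop=True)
    te = win_a[win_a.patient_id.isin(test_ids)].reset_index(drop=True)
    log.info(
        "split: %d train / %d test patients; %d / %d windows",
        len(train_ids), len(test_ids), len(tr), len(te),
    )

    logistic = models.LogisticWindowClassifier().fit(
        models.feature_matrix(tr), tr["label"].to_numpy(int)
    )
    convnet = models.ParallelConv1DClassifier(
        replace(config.convnet, seed=seeds[3])
    ).fit(models.uo_matrix(tr), tr["label"].to_numpy(int), groups=tr["patient_id"])

    results, predictions = [], []
    eval_sets = [("cohort_A_test", te, status_a), ("cohort_B_external", coh_b.windows,
                                                   coh_b.patient_event_status())]
    for name, windows, status in eval_sets:
        for model_name, scores in (
            ("logistic", logistic.score_windows(models.feature_matrix(windows))),
            ("deep_learning", convnet.score_windows(models.uo_matrix(windows))),
        ):
            results.append(
                _evaluate(name, model_name, scores, windows,
                          config.knee_method, config.patient_agg, status)
            )
            predictions.append(
                pd.DataFrame(
                    {
                        "patient_id": windows["patient_id"],
                        "window_end_hour": windows["window_end_hour"],
                        "score": scores,
                        "model_name": model_name,
                        "dataset": name,
                    }
                )
            )

    report_rows = []
    for r in results:
        for op in (r["op_fixed80"], r["op_knee"]):
            report_rows.append(
                {
                    "model": r["model"],
                    "dataset": r["dataset"],
                    "working_point": op.selection_rule,
                    "auroc": r["roc"].auc,
                    "sensitivity": op.sensitivity,
                    "specificity": op.specificity,
                    "lr_pos": op.lr_pos,
                    "lr_neg": op.lr_neg,
                }
            )
    report = ev.render_report(report_rows)

    out = {
        "config": config,
        "cohorts": {"A": coh_a, "B": coh_b},
        "models": {"logistic": logistic, "deep_learning": convnet},
        "split": {"train": train_ids, "test": test_ids},
        "results": results,
        "report": report,
        "predictions": pd.concat(predictions, ignore_index=True),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tag, coh in (("A", coh_a), ("B", coh_b)):
            coh.windows.to_csv(outdir / f"windows_{tag}.csv", index=False)
            coh.exclusion_log.records.to_csv(outdir / f"exclusions_{tag}.csv", index=False)
        out["predictions"].to_csv(outdir / "predictions.csv", index=False)
        report.to_csv(outdir / "metrics.csv", index=False)
        models.save_model(logistic, outdir / "model_logistic.json")
        models.save_model(convnet, outdir / "model_convnet.json")
    return out
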