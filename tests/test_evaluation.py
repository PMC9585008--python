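"""ROC curves, AUC standard error, operating points, likelihood ratios."""

import math

import numpy as np
import pytest

from oliguard.evaluation import (
    auc_standard_error,
    knee_point,
    likelihood_ratios,
    operating_point_fixed_sensitivity,
    patient_level_scores,
    render_report,
    roc_curve,
    round_half_away,
)


def pair_counting_auc(scores, labels):
    """Mann-Whitney concordance oracle: ties between classes count half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auc == 1.0

    def test_all_tied_scores(self):
        roc = roc_curve([0.5] * 10, [0, 1] * 5)
        assert roc.auc == pytest.approx(0.5)

    def test_small_example_equals_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(0.75)
        assert roc.auc == pytest.approx(pair_counting_auc(scores, labels))

    def test_random_scores_equal_pair_counting(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 80))
            scores = np.round(rng.random(n), 2)  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert roc_curve(scores, labels).auc == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_endpoints_and_monotonicity(self, rng):
        roc = roc_curve(rng.random(200), rng.integers(0, 2, 200))
        assert (np.diff(roc.sensitivity) >= 0).all() or (np.diff(roc.sensitivity) <= 0).all()
        pts = set(zip(roc.sensitivity, roc.specificity))
        assert (0.0, 1.0) in pts and (1.0, 0.0) in pts

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])


class TestAUCStandardError:
    def test_formula_at_half(self):
        # A=0.5: Q1=1/3, Q2=1/3; var = (0.25 + (n-1)/12 * 2) / n^2
        n = 10
        expected = math.sqrt((0.25 + 2 * (n - 1) * (1 / 3 - 0.25)) / (n * n))
        assert auc_standard_error(0.5, n, n) == pytest.approx(expected)

    def test_perfect_auc_has_zero_se(self):
        assert auc_standard_error(1.0, 30, 50) == 0.0

    def test_se_shrinks_with_sample_size(self):
        ses = [auc_standard_error(0.85, n, 4 * n) for n in (10, 40, 160, 640)]
        assert all(a > b for a, b in zip(ses, ses[1:]))

    def test_out_of_range_auc_rejected(self):
        with pytest.raises(ValueError):
            auc_standard_error(1.2, 5, 5)


class TestLikelihoodRatios:
    @pytest.mark.parametrize(
        "sens,spec,lr_pos,lr_neg",
        [
            (0.80, 0.89, 7.27, 0.22),  # high-specificity operating point
            (0.80, 0.81, 4.21, 0.25),
            (0.80, 0.75, 3.20, 0.27),
            (1.00, 0.50, 2.00, 0.00),
        ],
    )
    def test_two_decimal_values(self, sens, spec, lr_pos, lr_neg):
        lp, ln = likelihood_ratios(sens, spec)
        assert round_half_away(lp, 2) == lr_pos
        assert round_half_away(ln, 2) == lr_neg

    def test_infinite_flags_at_poles(self):
        lp, _ = likelihood_ratios(0.9, 1.0)
        _, ln = likelihood_ratios(0.9, 0.0)
        assert math.isinf(lp) and math.isinf(ln)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratios(1.1, 0.5)


def _random_roc(rng, n=400):
    scores = rng.random(n)
    labels = (rng.random(n) < 0.4 + 0.4 * scores).astype(int)
    return roc_curve(scores, labels)


class TestOperatingPoints:
    def test_fixed_sensitivity_matches_exhaustive_scan(self, rng):
        for _ in range(10):
            roc = _random_roc(rng)
            op = operating_point_fixed_sensitivity(roc, 0.80)
            best = max(
                (
                    (roc.specificity[i], roc.thresholds[i], i)
                    for i in range(len(roc.thresholds))
                    if roc.sensitivity[i] >= 0.80
                ),
            )
            assert op.specificity == roc.specificity[best[2]]
            assert op.sensitivity >= 0.80

    def test_perfect_classifier_full_specificity(self):
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        op = operating_point_fixed_sensitivity(roc, 0.80)
        assert op.specificity == 1.0

    def test_unreachable_target_rejected(self):
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        with pytest.raises(ValueError, match="sensitivity"):
            operating_point_fixed_sensitivity(roc, 1.01)

    def test_knee_matches_exhaustive_distance_scan(self, rng):
        for _ in range(10):
            roc = _random_roc(rng)
            op = knee_point(roc)
            d = np.hypot(1 - roc.sensitivity, 1 - roc.specificity)
            assert np.hypot(1 - op.sensitivity, 1 - op.specificity) == pytest.approx(d.min())

    def test_knee_of_perfect_classifier_is_corner(self):
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        op = knee_point(roc)
        assert (op.sensitivity, op.specificity) == (1.0, 1.0)

    def test_youden_variant(self, rng):
        roc = _random_roc(rng)
        op = knee_point(roc, method="youden")
        j = roc.sensitivity + roc.specificity - 1
        assert op.sensitivity + op.specificity - 1 == pytest.approx(j.max())


class TestPatientAggregation:
    def test_max_and_mean(self):
        import pandas as pd

        df = pd.DataFrame(
            {"patient_id": ["a", "a", "a", "b"], "score": [0.1, 0.7, 0.3, 0.2]}
        )
        assert patient_level_scores(df, "max")["a"] == 0.7
        assert patient_level_scores(df, "mean")["a"] == pytest.approx(1.1 / 3)
        assert patient_level_scores(df)["b"] == 0.2

    def test_patient_auc_matches_pair_counting(self, prepared_2000, rng):
        import pandas as pd

        win = prepared_2000.windows
        scores = rng.random(len(win))  # any scores: the identity under test
        per_pat = patient_level_scores(
            pd.DataFrame({"patient_id": win.patient_id, "score": scores})
        )
        status = prepared_2000.patient_event_status()
        labels = np.array([status[p] for p in per_pat.index])
        roc = roc_curve(per_pat.to_numpy(), labels)
        assert roc.auc == pytest.approx(
            pair_counting_auc(per_pat.to_numpy(), labels), abs=1e-12
        )


class TestReport:
    def _rows(self):
        return [
            {
                "model": m,
                "dataset": "A",
                "working_point": wp,
                "auroc": 0.9,
                "sensitivity": 0.8,
                "specificity": 0.85,
                "lr_pos": None,
                "lr_neg": None,
            }
            for m in ("logistic", "deep_learning")
            for wp in ("fixed_sensitivity_80", "knee_point")
        ]

    def test_two_models_two_points_make_four_rows(self):
        assert len(render_report(self._rows())) == 4

    def test_lr_cells_reproducible_from_sens_spec_cells(self, rng):
        rows = []
        for _ in range(10):
            s, p = rng.uniform(0.5, 1.0), rng.uniform(0.3, 0.99)
            rows.append(
                {
                    "model": "m",
                    "dataset": "d",
                    "working_point": "w",
                    "auroc": 0.8,
                    "sensitivity": s,
                    "specificity": p,
                    "lr_pos": None,
                    "lr_neg": None,
                }
            )
        df = render_report(rows)
        for (_, row), src in zip(df.iterrows(), rows):
            lp, ln = likelihood_ratios(src["sensitivity"], src["specificity"])
            assert row.lr_pos == round_half_away(lp, 2)
            assert row.lr_neg == round_half_away(ln, 2)

    def test_empty_metrics_write_header_only(self, tmp_path):
        path = tmp_path / "metrics.csv"
        render_report([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("model,")

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(0.125, 2) == 0.13
        assert round_half_away(-0.125, 2) == -0.13
        assert round_half_away(4.205, 2) == 4.21
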