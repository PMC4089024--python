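"""Ordinal spot scoring, aggregation, classification and plate QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgscreen.scoring import (
    BinConfigError,
    CLASS_NO_DATA,
    DEFAULT_BINS,
    aggregate_and_classify,
    confusion_metrics,
    grade_spot,
    plate_qc,
    relative_growth_ratio,
    score_screen,
)
from cgscreen.synth import SimConfig, simulate_screen


class TestRelativeGrowthRatio:
    @pytest.mark.parametrize(
        "args,expected",
        [((0.5, 1.0, 0.5, 1.0), 1.0), ((0.05, 1.0, 0.5, 1.0), 0.1), ((0.2, 0.8, 1.0, 1.0), 0.25)],
    )
    def test_direct_arithmetic(self, args, expected):
        assert relative_growth_ratio(*args) == pytest.approx(expected)

    @given(
        st.tuples(*[st.floats(0.01, 10.0) for _ in range(4)]),
        st.floats(0.001, 1000.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, vals, c):
        base = relative_growth_ratio(*vals)
        scaled = relative_growth_ratio(*(v * c for v in vals))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_failed_untreated_growth_is_unscoreable_not_fatal(self):
        assert relative_growth_ratio(0.5, 0.0, 1.0, 1.0) is None
        assert relative_growth_ratio(0.5, 1.0, 0.0, 1.0) is None
        assert relative_growth_ratio(0.5, 1.0, 1.0, 0.0) is None


class TestGradeSpot:
    @pytest.mark.parametrize(
        "r,score",
        [
            (1.0, 0),
            (0.05, 3),
            (2.0, -2),
            (0.10, 3),     # sensitive-side edges inclusive
            (0.35, 2),
            (0.60, 1),
            (0.61, 0),
            (1.29, 0),
            (1.30, -1),    # wild-type bin's upper edge is exclusive
            (1.74, -1),
            (1.75, -2),
            (0.0, 3),
        ],
    )
    def test_default_bins(self, r, score):
        assert grade_spot(r) == score

    def test_unscoreable_stays_unscored(self):
        assert grade_spot(None) is None
        assert grade_spot(float("nan")) is None

    @given(st.floats(0.0, 3.0), st.floats(0.0, 3.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_non_increasing_in_r(self, r1, r2):
        lo, hi = sorted((r1, r2))
        assert grade_spot(lo) >= grade_spot(hi)

    def test_non_monotone_bins_rejected(self):
        with pytest.raises(BinConfigError):
            grade_spot(0.5, bins=((0.5, 3), (0.2, 2)))
        with pytest.raises(BinConfigError):
            grade_spot(0.5, bins=((0.2, 1), (0.5, 2)))


class TestAggregateAndClassify:
    @pytest.mark.parametrize(
        "scores,final,cls",
        [
            ([0, 0, 0, 0, 0, 0], 0, "unaffected"),
            ([3, 3, 2, 2, 1, 1], 12, "sensitive"),   # top observed grade range 10-12
            ([-1, -1, 0, 0, 0, 0], -2, "resistant"),
            ([1, 1, 0, 0, 0, 0], 2, "unaffected"),   # below the sensitive cut of 3
            ([1, 1, 1, 0, 0, 0], 3, "sensitive"),
        ],
    )
    def test_published_threshold_rule(self, scores, final, cls):
        res = aggregate_and_classify("s", scores, n_design_spots=6)
        assert (res.final_score, res.classification) == (final, cls)

    def test_empty_scores_give_no_data(self):
        assert aggregate_and_classify("s", []).classification == CLASS_NO_DATA

    def test_under_half_of_design_spots_gives_no_data(self):
        res = aggregate_and_classify("s", [3, 3, None, None, None, None], n_design_spots=6)
        assert res.classification == CLASS_NO_DATA
        res = aggregate_and_classify("s", [3, 0, 0, None, None, None], n_design_spots=6)
        assert res.classification == "sensitive"

    def test_unscoreable_spots_are_dropped_not_zeroed(self):
        res = aggregate_and_classify("s", [2, 1, None, 0, None, 0], n_design_spots=6)
        assert res.final_score == 3 and res.n_spots_scored == 4

    @given(st.lists(st.one_of(st.none(), st.integers(-2, 3)), max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_sum_and_partition(self, scores):
        res = aggregate_and_classify("s", scores)
        scored = [s for s in scores if s is not None]
        if not scored:
            assert res.classification == CLASS_NO_DATA
            return
        assert res.final_score == sum(scored)
        k = len(scored)
        assert -2 * k <= res.final_score <= 3 * k
        expected = (
            "sensitive" if res.final_score >= 3
            else "resistant" if res.final_score <= -2
            else "unaffected"
        )
        assert res.classification == expected


class TestPlateQC:
    def test_healthy_controls_pass(self, clean_screen):
        _, growth, _, layouts = clean_screen
        report = plate_qc(growth, layouts)
        assert report.failed == [] and report.unevaluable == []
        assert len(report.passed) > 0

    def test_overdosed_wildtype_fails(self, clean_screen):
        _, growth, _, layouts = clean_screen
        g = growth.copy()
        pid = layouts[0].plate_id
        mask = (
            (g["strain_id"] == "BY4741")
            & (g["plate_id"] == pid)
            & (g["concentration"] > 0)
            & (g["replicate"] == 1)
        )
        g.loc[mask, "growth"] *= 0.05  # wild-type control wiped out on one plate
        report = plate_qc(g, layouts)
        assert any(p == pid and r == 1 for p, r, _ in report.failed)

    def test_missing_sensitive_control_is_unevaluable(self, clean_screen):
        _, growth, _, layouts = clean_screen
        import copy

        broken = copy.deepcopy(layouts)
        del broken[0].wells["H12"]
        report = plate_qc(growth, broken)
        assert any(p == broken[0].plate_id for p, r, _ in report.unevaluable)


class TestEndToEnd:
    def test_failing_plates_are_excluded_from_aggregation(self, small_screen):
        _, growth, _, layouts = small_screen
        g = growth.copy()
        pid = layouts[0].plate_id
        wt_mask = (g["strain_id"] == "BY4741") & (g["plate_id"] == pid) & (g["concentration"] > 0)
        g.loc[wt_mask, "growth"] *= 0.05
        results, qc = score_screen(g, layouts)
        assert not qc.plate_rep_ok(pid, 1)
        on_plate = [s for s in layouts[0].wells.values() if s.startswith("STR")]
        sub = results[results["strain_id"].isin(on_plate)]
        # both replicates of the plate failed -> under half the design spots
        assert (sub["classification"] == CLASS_NO_DATA).all()

    def test_recovery_on_noisy_screen(self, small_screen):
        _, growth, truth, layouts = small_screen
        results, _ = score_screen(growth, layouts)
        m = confusion_metrics(truth, results)
        assert m["sensitivity"] >= 0.95
        assert m["specificity"] >= 0.9
        assert m["resistant_recall"] >= 0.9

    def test_noise_free_recovery_is_perfect(self, clean_screen):
        _, growth, truth, layouts = clean_screen
        results, _ = score_screen(growth, layouts)
        m = confusion_metrics(truth, results)
        assert m["sensitivity"] == m["specificity"] == m["resistant_recall"] == 1.0

    def test_plate_reference_mode_also_recovers_clean_screen(self, clean_screen):
        _, growth, truth, layouts = clean_screen
        results, _ = score_screen(growth, layouts, wt_reference="plate")
        m = confusion_metrics(truth, results)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0
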