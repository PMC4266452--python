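"""Free-concentration algebra, window classification and contingency metrics."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from silicoqt.dose_response import CurvePoint, DoseResponseCurve
from silicoqt.tqt_eval import (
    ContingencyTable,
    TQTRecord,
    build_contingency,
    classify,
    free_plasma_concentration,
    summary_table,
)


class TestFreeConcentration:
    def test_unit_identity(self):
        assert free_plasma_concentration(411.0, 0.0, 411.0) == pytest.approx(1.0)

    def test_fully_bound_is_zero(self):
        assert free_plasma_concentration(5000.0, 100.0, 300.0) == 0.0

    def test_hand_arithmetic(self):
        # 500 ng/mL, 50% bound, MW 250: (500/250) x 0.5 = 1 µM
        assert free_plasma_concentration(500.0, 50.0, 250.0) == pytest.approx(1.0)

    def test_linear_in_cmax_and_fraction_unbound(self):
        base = free_plasma_concentration(100.0, 80.0, 400.0)
        assert free_plasma_concentration(300.0, 80.0, 400.0) == pytest.approx(3 * base)
        assert free_plasma_concentration(100.0, 60.0, 400.0) == pytest.approx(2 * base)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            free_plasma_concentration(100.0, 50.0, 0.0)
        with pytest.raises(ValueError):
            free_plasma_concentration(-1.0, 50.0, 300.0)
        with pytest.raises(ValueError):
            free_plasma_concentration(100.0, 101.0, 300.0)

    def test_record_derives_free_conc(self):
        rec = TQTRecord("x", cmax=500.0, percent_bound=50.0,
                        molecular_weight=250.0, delta_qtc=7.0)
        assert rec.free_conc == pytest.approx(1.0)
        assert rec.observed_positive


def _ramp_curve(cross_at=1.0, low=0.0, high=10.0):
    """Synthetic curve rising from `low` to `high`, crossing 5 ms near cross_at."""
    conc = np.logspace(-3, 2, 20)
    mid = np.log10(cross_at)
    deltas = low + (high - low) / (1 + 10 ** (-(np.log10(conc) - mid) * 2))
    return DoseResponseCurve(
        compound_id="x", model="m", dataset="Q", control_apd90=300.0,
        points=[CurvePoint(c, 300 + d, float(d)) for c, d in zip(conc, deltas)],
    )


class TestClassify:
    def test_flat_curve_is_negative_for_any_window(self):
        flat = _ramp_curve(high=0.0)
        for fold in (1, 10, 100):
            assert not classify(flat, 0.05, fold)

    def test_window_recovers_distant_crossing(self):
        # crossing at ~1 µM; estimated TQT concentration 0.05 µM
        curve = _ramp_curve(cross_at=1.0)
        assert not classify(curve, 0.05, 1)
        assert classify(curve, 0.05, 100)

    def test_threshold_boundary_is_inclusive(self):
        conc = np.logspace(-3, 2, 5)
        curve = DoseResponseCurve(
            compound_id="x", model="m", dataset="Q", control_apd90=300.0,
            points=[CurvePoint(c, 305.0, 5.0) for c in conc],
        )
        assert classify(curve, 1.0, 1)

    def test_point_evaluation_equals_interpolated_threshold_test(self):
        from silicoqt.dose_response import interpolate_delta

        curve = _ramp_curve(cross_at=0.3)
        for conc in (0.01, 0.3, 3.0, 50.0):
            assert classify(curve, conc, 1) == (interpolate_delta(curve, conc) >= 5.0)

    def test_repolarisation_failure_in_window_counts_positive(self):
        conc = np.logspace(-3, 2, 5)
        pts = [CurvePoint(c, 300.0, 0.0) for c in conc[:-1]]
        pts.append(CurvePoint(conc[-1], None, None, "repolarisation_failure"))
        curve = DoseResponseCurve("x", "m", "Q", 300.0, pts)
        assert not classify(curve, 1.0, 1)
        assert classify(curve, 1.0, 1000)

    def test_window_outside_grid_clamps_with_warning(self):
        curve = _ramp_curve()
        with pytest.warns(UserWarning, match="outside the simulated grid"):
            classify(curve, 1e-8, 1)

    @settings(derandomize=True, max_examples=60)
    @given(
        cross_at=st.floats(1e-2, 1e1),
        tqt_conc=st.floats(1e-3, 1e2),
        folds=st.lists(st.floats(1, 1e3), min_size=2, max_size=5),
    )
    def test_positive_is_monotone_in_fold_window(self, cross_at, tqt_conc, folds):
        curve = _ramp_curve(cross_at=cross_at)
        verdicts = [classify(curve, tqt_conc, f) for f in sorted(folds)]
        # once positive, wider windows stay positive (nested maxima)
        assert verdicts == sorted(verdicts)


class TestContingency:
    def test_worked_example(self):
        pairs = [(True, 10.0)] * 2 + [(False, 8.0)] + [(False, 1.0)] * 3
        t = build_contingency(pairs)
        assert (t.tp, t.fn, t.fp, t.tn) == (2, 1, 0, 3)
        assert t.sensitivity == Fraction(200, 3)  # 66.7 %
        assert t.specificity == Fraction(100)
        assert t.accuracy == Fraction(500, 6)     # 83.3 %
        assert t.metrics_percent(1) == {
            "sensitivity": 66.7, "specificity": 100.0, "accuracy": 83.3,
        }

    def test_all_correct_is_all_100(self):
        t = build_contingency([(True, 9.0), (False, 0.0), (True, 5.0)])
        assert t.sensitivity == t.specificity == t.accuracy == Fraction(100)

    def test_no_observed_positives_leaves_sensitivity_undefined(self):
        t = build_contingency([(False, 0.0), (True, 1.0)])
        assert t.sensitivity is None
        assert t.metrics_percent()["sensitivity"] is None

    def test_observed_positive_threshold_inclusive(self):
        t = build_contingency([(True, 5.0)])
        assert t.tp == 1 and t.fp == 0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(
        st.tuples(st.booleans(), st.floats(-20, 30, allow_nan=False)),
        min_size=1, max_size=40,
    ))
    def test_metric_identities(self, pairs):
        t = build_contingency(pairs)
        observed_pos = sum(1 for _, d in pairs if d >= 5.0)
        assert t.tp + t.fn == observed_pos
        assert t.total == len(pairs)
        if t.sensitivity is not None and t.specificity is not None:
            # accuracy is the prevalence-weighted average of sens/spec
            weighted = (
                t.sensitivity * (t.tp + t.fn) + t.specificity * (t.tn + t.fp)
            ) / t.total
            assert t.accuracy == weighted


class TestSummaryTable:
    def test_single_combination_matches_build_contingency(self):
        curve = _ramp_curve(cross_at=0.1)
        records = [
            TQTRecord("x", cmax=100.0, percent_bound=0.0,
                      molecular_weight=100.0, delta_qtc=12.0),  # free 1 µM
        ]
        table = summary_table({("m", "Q", "x"): curve}, records, fold_windows=[1.0])
        row = table.iloc[0]
        assert row["n"] == 1 and row["tp"] == 1
        assert row["sensitivity"] == 100.0

    def test_synthetic_cohort_with_crossings_inside_windows(self):
        # every compound's crossing lies within its 10x window -> sens 100 %
        curves, records = {}, []
        for i, cross in enumerate((0.05, 0.2, 1.0)):
            cid = f"c{i}"
            curves[("m", "Q", cid)] = _ramp_curve(cross_at=cross)
            records.append(TQTRecord(cid, cmax=cross * 300.0, percent_bound=0.0,
                                     molecular_weight=300.0, delta_qtc=9.0))
        table = summary_table(curves, records, fold_windows=[10.0])
        assert table.iloc[0]["sensitivity"] == 100.0

    def test_missing_curve_marks_unavailable(self):
        curve = _ramp_curve()
        records = [
            TQTRecord("x", 100.0, 0.0, 100.0, 12.0),
            TQTRecord("y", 100.0, 0.0, 100.0, 0.0),
        ]
        table = summary_table({("m", "Q", "x"): curve}, records, fold_windows=[1.0])
        assert table.iloc[0]["n"] == 1 and table.iloc[0]["n_missing"] == 1
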