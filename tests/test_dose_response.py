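"""Concentration grid, dataset->channel mapping, sweeps and interpolation."""

import numpy as np
import pytest

from silicoqt.channel_pharm import Channel, ChannelAffinity, Source
from silicoqt.dose_response import (
    CurvePoint,
    Dataset,
    DoseResponseCurve,
    MissingAffinityError,
    assemble_scale_factors,
    interpolate_delta,
    make_grid,
    run_sweep,
)
from conftest import TEST_TOL, pure_ikr_compound


class TestGrid:
    def test_default_is_20_points_1nM_to_100uM(self):
        grid = make_grid()
        assert len(grid.points) == 20
        assert grid.points[0] == pytest.approx(1e-3)
        assert grid.points[-1] == pytest.approx(1e2)

    def test_uniform_log_spacing(self):
        steps = np.diff(np.log10(make_grid().points))
        assert np.allclose(steps, 5.0 / 19.0)

    def test_two_point_grid_is_the_endpoints(self):
        assert make_grid(0.5, 2.0, 2).points == (0.5, 2.0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_grid(1.0, 0.1)
        with pytest.raises(ValueError):
            make_grid(0.0, 1.0)


class TestScaleFactors:
    def test_zero_concentration_means_no_block(self, pic50_panel):
        affs = pic50_panel.affinities("dofetilide")
        factors = assemble_scale_factors(affs, "Q", 0.0)
        assert set(factors) == {"IKr", "IKs", "INa", "ICaL", "Ito"}
        assert all(v == 1.0 for v in factors.values())

    def test_dofetilide_manual_herg_halves_ikr_at_its_ic50(self, pic50_panel):
        # manual hERG pIC50 = 8.0 -> IC50 = 0.01 µM
        affs = pic50_panel.affinities("dofetilide")
        factors = assemble_scale_factors(affs, "MQ", 0.01)
        assert factors["IKr"] == pytest.approx(0.5)
        # Quattro dataset keeps its own (weaker) hERG potency
        q = assemble_scale_factors(affs, "Q", 0.01)
        assert q["IKr"] > 0.9

    def test_bq2_leaves_ito_unblocked_at_any_concentration(self, pic50_panel):
        affs = pic50_panel.affinities("dofetilide")
        factors = assemble_scale_factors(affs, "BQ2", 100.0)
        assert "Ito" not in factors  # absent data, never scaled
        assert factors["IKr"] < 0.1  # Barracuda hERG 6.2 blocks hard at 100 µM

    def test_missing_required_affinity_is_named(self, pic50_panel):
        # alvimopan has no Barracuda screen
        affs = pic50_panel.affinities("alvimopan")
        with pytest.raises(MissingAffinityError, match="alvimopan.*IKr.*B"):
            assemble_scale_factors(affs, "BQ2", 1.0)


def _curve(points):
    return DoseResponseCurve(
        compound_id="x", model="m", dataset="Q", control_apd90=300.0,
        points=[CurvePoint(*p) for p in points],
    )


class TestInterpolation:
    def test_grid_point_returns_exactly(self):
        c = _curve([(0.1, 301.0, 1.0), (1.0, 305.0, 5.0), (10.0, 310.0, 10.0)])
        assert interpolate_delta(c, 1.0) == 5.0

    def test_log_midpoint_linearity(self):
        c = _curve([(0.1, 300.0, 0.0), (10.0, 310.0, 10.0)])
        assert interpolate_delta(c, 1.0) == pytest.approx(5.0)

    def test_clamps_outside_grid(self):
        c = _curve([(0.1, 300.0, 0.0), (10.0, 310.0, 10.0)])
        assert interpolate_delta(c, 1e-5) == 0.0
        assert interpolate_delta(c, 1e4) == 10.0

    def test_flagged_bracket_propagates_flag(self):
        c = _curve([
            (0.1, 300.0, 0.0),
            (1.0, None, None, "repolarisation_failure"),
            (10.0, 310.0, 10.0),
        ])
        assert interpolate_delta(c, 0.3) == "repolarisation_failure"

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            interpolate_delta(_curve([]), 1.0)


class TestSweep:
    def test_inactive_compound_changes_nothing(self, control_steady, pic50_panel):
        # all pIC50 = 0: at most 0.01 % block anywhere on the grid
        affs = [
            ChannelAffinity("inert", ch, Source.Q, 0.0)
            for ch in (Channel.IKr, Channel.IKs, Channel.INa, Channel.ICaL, Channel.Ito)
        ]
        # the control must be deeply converged here: residual pacing drift,
        # not channel block, is the only signal an inert compound could show
        spec, res = control_steady["tentusscher2006"]
        curve = run_sweep(
            affs, spec, "Q", grid=make_grid(1e-3, 1e2, 5),
            convergence_tol=2e-5, max_paces=250, control_state=res.final_state,
        )
        assert len(curve.points) == 5
        for p in curve.points:
            assert p.numeric and abs(p.delta_apd90) < 0.5

    def test_sweep_is_deterministic(self, control_steady):
        spec, res = control_steady["tentusscher2006"]
        kwargs = dict(
            grid=make_grid(0.1, 10.0, 3), convergence_tol=TEST_TOL,
            max_paces=20, control_state=res.final_state,
        )
        a = run_sweep(pure_ikr_compound(6.0), spec, "Q", **kwargs)
        b = run_sweep(pure_ikr_compound(6.0), spec, "Q", **kwargs)
        assert [p.apd90 for p in a.points] == [p.apd90 for p in b.points]
        assert a.control_apd90 == b.control_apd90

    def test_warm_start_agrees_with_cold_start(self, control_steady):
        # guards against spurious hysteresis from the sequential ramp
        spec, res = control_steady["tentusscher2006"]
        grid = make_grid(0.1, 10.0, 3)
        warm = run_sweep(
            pure_ikr_compound(6.0), spec, "Q", grid=grid,
            convergence_tol=TEST_TOL, max_paces=60, control_state=res.final_state,
        )
        for point in warm.points:
            cold = run_sweep(
                pure_ikr_compound(6.0), spec, "Q",
                grid=make_grid(point.concentration, point.concentration * 1.001, 2),
                convergence_tol=TEST_TOL, max_paces=60, control_state=res.final_state,
            )
            assert cold.points[0].apd90 == pytest.approx(point.apd90, abs=1.0)

    def test_mq_equals_q_when_manual_and_quattro_herg_agree(self, control_steady):
        spec, res = control_steady["tentusscher2006"]
        affs = pure_ikr_compound(5.5)
        affs.append(ChannelAffinity("synthblocker", Channel.IKr, Source.M, 5.5))
        kwargs = dict(
            grid=make_grid(1.0, 10.0, 3), convergence_tol=TEST_TOL,
            max_paces=20, control_state=res.final_state,
        )
        q = run_sweep(affs, spec, "Q", **kwargs)
        mq = run_sweep(affs, spec, "MQ", **kwargs)
        assert [p.apd90 for p in q.points] == [p.apd90 for p in mq.points]

    def test_output_preserves_grid_order(self, control_steady):
        spec, res = control_steady["tentusscher2006"]
        curve = run_sweep(
            pure_ikr_compound(5.0), spec, "Q", grid=make_grid(1e-2, 1e1, 4),
            convergence_tol=TEST_TOL, max_paces=10, control_state=res.final_state,
        )
        conc = [p.concentration for p in curve.points]
        assert conc == sorted(conc)
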