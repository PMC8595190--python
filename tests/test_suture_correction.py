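"""Suture-correction solvers against the explicit outflow-network oracle."""

import numpy as np
import pytest

from sutureflow import (
    CaseLabel,
    CorrectionProblem,
    EyeParameters,
    FluidProperties,
    ImplantGeometry,
    InfeasibleError,
    Placement,
    iop_increase_sweep,
    predicted_iop_after_suture,
    required_resistance_ratio,
    resistance_ratio,
    suture_diameter_for_target,
    tube_pressure_drop,
)
from sutureflow.geometry import SutureConfig

from conftest import network_p_c2, network_required_ratio


def _problem(eye, geo, fluid, **kw):
    return CorrectionProblem(eye=eye, geometry=geo, fluid=fluid, **kw)


class TestRequiredResistanceRatio:
    def test_no_change_needs_unity_ratio(self, eye, narrow, fluid):
        for p1 in [4.0, 10.5, 14.0]:
            prob = _problem(eye, narrow, fluid, p_c1_mmhg=p1, p_c2_target_mmhg=p1)
            assert required_resistance_ratio(prob) == 1.0

    def test_both_closed_hand_arithmetic(self, eye, fluid):
        """Independent SI-unit hand computation of the closed-regime ratio.

        ratio = 1 + (pi D_i^4 / (128 L_v mu Q_0)) * dp for a 2 mm Hg rise
        through a 100 um, 11 mm tube at Q_0 = 1.7 ul/min, mu = 0.75 mPa s.
        """
        geo = ImplantGeometry(100.0, 11.0)
        prob = _problem(eye, geo, fluid, p_c1_mmhg=4.0, p_c2_target_mmhg=6.0)
        di, lv, mu = 100e-6, 11e-3, 0.75e-3
        q0 = 1.7e-9 / 60
        dp = 2.0 * 133.322
        expected = 1.0 + np.pi * di**4 * dp / (128 * lv * mu * q0)
        assert required_resistance_ratio(prob) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_target(self, eye, narrow, fluid):
        ratios = [
            required_resistance_ratio(
                _problem(eye, narrow, fluid, p_c1_mmhg=4.0, p_c2_target_mmhg=t)
            )
            for t in np.linspace(4.0, 20.0, 40)
        ]
        assert np.all(np.diff(ratios) > 0)

    def test_case_selection_follows_p_ev(self, eye, narrow, fluid):
        from sutureflow.suture_correction import classify_case

        assert classify_case(4.0, 8.0, 10.5) == CaseLabel.BOTH_CLOSED
        assert classify_case(4.0, 12.0, 10.5) == CaseLabel.MIXED
        assert classify_case(10.5, 12.0, 10.5) == CaseLabel.MIXED  # equality is closed
        assert classify_case(11.0, 12.0, 10.5) == CaseLabel.BOTH_OPEN

    def test_large_pg_approximation_converges(self, narrow, fluid):
        """The approximate open-regime formula meets the exact one as p_g grows."""
        rel_diffs = []
        for pg in [40.0, 200.0, 2000.0, 20000.0]:
            eye = EyeParameters(p_g_mmhg=pg, p_ev_mmhg=10.5)
            exact = required_resistance_ratio(_problem(
                eye, narrow, fluid, p_c1_mmhg=12.0, p_c2_target_mmhg=14.0))
            approx = required_resistance_ratio(_problem(
                eye, narrow, fluid, p_c1_mmhg=12.0, p_c2_target_mmhg=14.0,
                use_large_pg_approximation=True))
            rel_diffs.append(abs(exact - approx) / exact)
        assert all(a > b for a, b in zip(rel_diffs, rel_diffs[1:]))
        assert rel_diffs[-1] < 1e-3

    def test_infeasible_targets(self, eye, narrow, fluid):
        with pytest.raises(InfeasibleError):
            required_resistance_ratio(
                _problem(eye, narrow, fluid, p_c1_mmhg=8.0, p_c2_target_mmhg=5.0)
            )
        with pytest.raises(InfeasibleError):
            required_resistance_ratio(
                _problem(eye, narrow, fluid, p_c1_mmhg=8.0, p_c2_target_mmhg=36.0)
            )

    @pytest.mark.parametrize("p_r", [0.0, 1.5])
    @pytest.mark.parametrize(
        "p_c1,p_c2",
        [(12.0, 16.0), (6.0, 9.0), (8.0, 14.0), (10.5, 13.0)],
    )
    def test_matches_explicit_network_solution(self, fluid, p_r, p_c1, p_c2):
        """The closed-form bleb-pressure elimination must coincide with the
        explicit solution of the full network (tube, bleb, trabecular branch
        with conserved R_b) — the five unknowns solved directly."""
        eye = EyeParameters(p_g_mmhg=35.0, p_ev_mmhg=10.5, p_r_mmhg=p_r)
        geo = ImplantGeometry(100.0, 11.0)
        got = required_resistance_ratio(
            _problem(eye, geo, fluid, p_c1_mmhg=p_c1, p_c2_target_mmhg=p_c2)
        )
        oracle = network_required_ratio(eye, geo, fluid, p_c1, p_c2)
        assert got == pytest.approx(oracle, rel=1e-9)

    def test_matches_network_on_randomized_parameters(self):
        rng = np.random.default_rng(1234)
        for _ in range(25):
            pg = rng.uniform(25, 50)
            pev = rng.uniform(6, 14)
            pr = rng.uniform(0, 2)
            p1 = rng.uniform(pr + 0.5, pg - 6)
            p2 = rng.uniform(p1, pg - 3)
            eye = EyeParameters(pg, pev, pr, rng.uniform(1.5, 2.5), rng.uniform(0, 0.3))
            geo = ImplantGeometry(rng.uniform(50, 310), rng.uniform(5, 20))
            fluid = FluidProperties(rng.uniform(0.6, 1.0))
            got = required_resistance_ratio(
                _problem(eye, geo, fluid, p_c1_mmhg=p1, p_c2_target_mmhg=p2)
            )
            oracle = network_required_ratio(eye, geo, fluid, p1, p2)
            assert got == pytest.approx(oracle, rel=1e-9)


class TestForwardPrediction:
    def test_no_suture_no_change(self, eye, narrow, fluid):
        for p1 in [4.0, 12.0]:
            sol = predicted_iop_after_suture(
                _problem(eye, narrow, fluid, p_c1_mmhg=p1, d_s_um=0.0)
            )
            assert sol.p_c2_mmhg == p1

    def test_worked_narrow_bore_example(self, eye, narrow, fluid):
        # 35 um coaxial suture in a 100 um tube, hypotonic eye: ~2 mm Hg rise
        sol = predicted_iop_after_suture(_problem(
            eye, narrow, fluid, p_c1_mmhg=5.0, d_s_um=35.0,
            placement=Placement.CONCENTRIC))
        assert sol.case_label == CaseLabel.BOTH_CLOSED
        assert sol.p_c2_mmhg - 5.0 == pytest.approx(2.0, rel=0.10)

    def test_both_closed_equals_extra_tube_drop(self, eye, fluid):
        geo = ImplantGeometry(100.0, 11.0)
        suture = SutureConfig(40.0, Placement.CONCENTRIC)
        sol = predicted_iop_after_suture(_problem(
            eye, geo, fluid, p_c1_mmhg=4.0, d_s_um=40.0,
            placement=Placement.CONCENTRIC))
        assert sol.case_label == CaseLabel.BOTH_CLOSED
        extra = tube_pressure_drop(eye.q0_ul_min, geo, suture, fluid) - \
            tube_pressure_drop(eye.q0_ul_min, geo, None, fluid)
        assert sol.p_c2_mmhg == pytest.approx(4.0 + extra, rel=1e-9)

    def test_wide_bore_insensitive_to_moderate_sutures(self, eye, baerveldt, fluid):
        # a free suture settles on the tube wall; up to 250 um in a 305 um
        # bore it barely moves the IOP
        for p1 in [2.0, 5.0, 10.0]:
            for ds in [100.0, 150.0, 250.0]:
                sol = predicted_iop_after_suture(_problem(
                    eye, baerveldt, fluid, p_c1_mmhg=p1, d_s_um=ds,
                    placement=Placement.WALL_TOUCHING))
                assert sol.p_c2_mmhg - p1 < 0.5
        # at 100-150 um the increment is negligible in either placement
        for ds in [100.0, 150.0]:
            sol = predicted_iop_after_suture(_problem(
                eye, baerveldt, fluid, p_c1_mmhg=2.0, d_s_um=ds,
                placement=Placement.CONCENTRIC))
            assert sol.p_c2_mmhg - 2.0 < 0.1

    @pytest.mark.parametrize("p_c1", [3.0, 9.0, 10.5, 12.0, 16.0])
    def test_matches_explicit_network_all_cases(self, eye, fluid, p_c1):
        geo = ImplantGeometry(100.0, 11.0)
        for ds in [20.0, 40.0, 60.0]:
            sol = predicted_iop_after_suture(_problem(
                eye, geo, fluid, p_c1_mmhg=p_c1, d_s_um=ds,
                placement=Placement.CONCENTRIC))
            kappa = ds / 100.0
            oracle = network_p_c2(
                eye, geo, fluid, p_c1, resistance_ratio(kappa, "concentric")
            )
            assert sol.p_c2_mmhg == pytest.approx(oracle, rel=1e-9)

    def test_monotone_in_suture_diameter(self, eye, fluid):
        geo = ImplantGeometry(100.0, 11.0)
        for p1 in [4.0, 12.0]:
            p2s = [predicted_iop_after_suture(_problem(
                eye, geo, fluid, p_c1_mmhg=p1, d_s_um=ds,
                placement=Placement.CONCENTRIC)).p_c2_mmhg
                for ds in np.linspace(5.0, 90.0, 30)]
            assert np.all(np.diff(p2s) > 0)

    def test_case_continuity_in_p_c1(self, eye, fluid):
        # p_c2(p_c1) is continuous across both_closed -> mixed -> both_open
        geo = ImplantGeometry(100.0, 11.0)
        p1s = np.linspace(1.0, 18.0, 600)
        p2s, cases = [], []
        for p1 in p1s:
            sol = predicted_iop_after_suture(_problem(
                eye, geo, fluid, p_c1_mmhg=float(p1), d_s_um=40.0,
                placement=Placement.CONCENTRIC))
            p2s.append(sol.p_c2_mmhg)
            cases.append(sol.case_label)
        assert len(set(cases)) == 3  # all three cases visited
        assert np.abs(np.diff(p2s)).max() < 0.1


class TestInverseDesign:
    def test_target_equal_measured_gives_no_suture(self, eye, narrow, fluid):
        sol = suture_diameter_for_target(
            _problem(eye, narrow, fluid, p_c1_mmhg=5.0, p_c2_target_mmhg=5.0)
        )
        assert sol.d_s_um == 0.0
        assert sol.upper_bound_note

    def test_worked_inverse_example(self, eye, narrow, fluid):
        # +2 mm Hg in the 100 um tube: concentric suture around 35 um
        sol = suture_diameter_for_target(_problem(
            eye, narrow, fluid, p_c1_mmhg=5.0, p_c2_target_mmhg=7.0,
            placement=Placement.CONCENTRIC))
        assert sol.case_label == CaseLabel.BOTH_CLOSED
        assert sol.d_s_um == pytest.approx(35.0, rel=0.10)

    def test_wall_touching_needs_thicker_suture(self, eye, narrow, fluid):
        cc = suture_diameter_for_target(_problem(
            eye, narrow, fluid, p_c1_mmhg=5.0, p_c2_target_mmhg=7.0,
            placement=Placement.CONCENTRIC))
        wt = suture_diameter_for_target(_problem(
            eye, narrow, fluid, p_c1_mmhg=5.0, p_c2_target_mmhg=7.0,
            placement=Placement.WALL_TOUCHING))
        assert wt.d_s_um > cc.d_s_um

    @pytest.mark.parametrize("p_c1,target", [
        (3.0, 5.0), (3.0, 9.5), (5.0, 12.0), (12.0, 15.0), (10.5, 11.5),
    ])
    def test_forward_inverse_round_trip_concentric(self, eye, fluid, p_c1, target):
        geo = ImplantGeometry(100.0, 11.0)
        inv = suture_diameter_for_target(_problem(
            eye, geo, fluid, p_c1_mmhg=p_c1, p_c2_target_mmhg=target,
            placement=Placement.CONCENTRIC))
        fwd = predicted_iop_after_suture(_problem(
            eye, geo, fluid, p_c1_mmhg=p_c1, d_s_um=inv.d_s_um,
            placement=Placement.CONCENTRIC))
        assert abs(fwd.p_c2_mmhg - target) <= 1e-4

    def test_forward_inverse_round_trip_randomized(self, fluid):
        rng = np.random.default_rng(99)
        for _ in range(15):
            eye = EyeParameters(
                rng.uniform(28, 45), rng.uniform(8, 12), 0.0,
                rng.uniform(1.5, 2.5), 0.15,
            )
            geo = ImplantGeometry(rng.uniform(60, 150), rng.uniform(6, 15))
            p1 = rng.uniform(1.0, 14.0)
            target = rng.uniform(p1, min(p1 + 8, eye.p_g_mmhg - 5))
            inv = suture_diameter_for_target(_problem(
                eye, geo, fluid, p_c1_mmhg=p1, p_c2_target_mmhg=target,
                placement=Placement.CONCENTRIC))
            fwd = predicted_iop_after_suture(_problem(
                eye, geo, fluid, p_c1_mmhg=p1, d_s_um=inv.d_s_um,
                placement=Placement.CONCENTRIC))
            assert abs(fwd.p_c2_mmhg - target) <= 1e-4

    def test_suture_alone_insufficient_reported(self, eye, fluid):
        # a huge-bore, very short tube needs a resistance ratio beyond what
        # any straight wall-touching suture can deliver
        prob = _problem(eye, ImplantGeometry(300000.0, 0.01), fluid,
                        p_c1_mmhg=2.0, p_c2_target_mmhg=10.0,
                        placement=Placement.WALL_TOUCHING)
        with pytest.raises(InfeasibleError, match="insufficient"):
            suture_diameter_for_target(prob)


class TestSweep:
    def test_sweep_structure_and_failure_markers(self, eye, fluid):
        geo = ImplantGeometry(100.0, 11.0)
        df = iop_increase_sweep(eye, geo, Placement.CONCENTRIC,
                                [4.0, 8.0, 12.0], [0.0, 40.0, 120.0])
        assert list(df.columns) == ["p_c1_mmHg", "D_s_um", "p_c2_mmHg", "case"]
        assert len(df) == 9
        bad = df[df.D_s_um == 120.0]  # suture thicker than the bore
        assert (bad.case == "error").all() and bad.p_c2_mmHg.isna().all()

    def test_plateau_below_mixed_window(self, eye, fluid):
        # deep hypotony: the increase is independent of p_c1
        geo = ImplantGeometry(100.0, 11.0)
        df = iop_increase_sweep(eye, geo, Placement.CONCENTRIC,
                                [1.0, 2.0, 3.0, 4.0], [30.0])
        diffs = df.p_c2_mmHg - df.p_c1_mmHg
        assert df.case.eq("both_closed").all()
        assert np.ptp(diffs.values) < 1e-9

    def test_decreasing_above_p_ev(self, eye, fluid):
        geo = ImplantGeometry(100.0, 11.0)
        df = iop_increase_sweep(eye, geo, Placement.CONCENTRIC,
                                [11.0, 13.0, 15.0, 17.0], [40.0])
        diffs = (df.p_c2_mmHg - df.p_c1_mmHg).values
        assert np.all(np.diff(diffs) < 0)

    def test_mixed_window_shrinks_with_suture_diameter(self, eye, fluid):
        """The band of p_c1 in the mixed case collapses onto p_ev as D_s -> 0."""
        geo = ImplantGeometry(100.0, 11.0)
        p1_grid = np.linspace(0.5, 14.0, 250)

        def window_width(ds):
            df = iop_increase_sweep(eye, geo, Placement.CONCENTRIC, p1_grid, [ds])
            mixed = df[df.case == "mixed"]
            if mixed.empty:
                return 0.0
            return mixed.p_c1_mmHg.max() - mixed.p_c1_mmHg.min()

        widths = [window_width(ds) for ds in [60.0, 40.0, 20.0]]
        assert widths[0] > widths[1] > widths[2] >= 0.0
        upper = iop_increase_sweep(eye, geo, Placement.CONCENTRIC, p1_grid, [20.0])
        mixed = upper[upper.case == "mixed"]
        if not mixed.empty:
            assert mixed.p_c1_mmHg.max() <= eye.p_ev_mmhg + 1e-9
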