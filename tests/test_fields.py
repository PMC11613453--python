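import math

import numpy as np
import pytest

from vseprobe.fields import (
    InfeasibleSolutionError,
    SubstateComponent,
    VariantAnchors,
    VSECalibration,
    field_from_frequency,
    fit_tdm_field_line,
    scaled_tdm_components,
    solve_substates,
    tdm_from_intensity,
    total_field_photoproduct,
)
from vseprobe.normalize import ComponentRecord, StateRecord


def make_record(variant, state, components, envelope=None):
    comps = [ComponentRecord(f"P{i+1}", nu, nu, i_rt, i_rt, hb)
             for i, (nu, i_rt, hb) in enumerate(components)]
    env = envelope if envelope is not None else sum(c.intensity_RT for c in comps)
    return StateRecord(variant, state, 300.0, env, env, comps)


Y165O = VariantAnchors("Y165oCNF", "oCNF", -53.41, 7.767, 7.64)
F192O = VariantAnchors("F192oCNF", "oCNF", -45.40, 6.196, 12.86)
Y165P = VariantAnchors("Y165pCNF", "pCNF", -73.84, 9.564, 2.642)
F192P = VariantAnchors("F192pCNF", "pCNF", -28.76, 8.829, 1.516)


class TestTdmFromIntensity:
    @pytest.mark.parametrize(
        "intensity, anchors, expected",
        [
            (7.484, Y165O, 7.687),   # Lumi-F envelope
            (9.130, F192O, 5.220),   # Meta-F single band
        ],
    )
    def test_published_envelope_values(self, intensity, anchors, expected):
        assert tdm_from_intensity(intensity, anchors) == pytest.approx(expected, abs=1e-3)

    def test_reference_intensity_returns_reference_tdm(self, y165o_anchors):
        assert tdm_from_intensity(7.64, y165o_anchors) == pytest.approx(7.767, abs=1e-12)

    def test_rejects_non_positive_intensity(self, y165o_anchors):
        with pytest.raises(ValueError):
            tdm_from_intensity(0.0, y165o_anchors)


class TestTotalField:
    def test_y165o_lumi(self, cal):
        mu = tdm_from_intensity(7.484, Y165O)
        assert total_field_photoproduct(mu, Y165O, cal) == pytest.approx(-52.13, abs=0.01)

    def test_y165p_lumi_from_published_tdm(self, cal):
        assert total_field_photoproduct(14.618, Y165P, cal) == pytest.approx(-221.70, abs=0.01)

    def test_internal_standard_fixed_point(self, cal, y165o_anchors):
        assert total_field_photoproduct(
            y165o_anchors.mu_pfr, y165o_anchors, cal
        ) == pytest.approx(y165o_anchors.e_pfr_total, abs=1e-12)

    def test_degenerate_anchor_rejected(self, cal):
        anchors = VariantAnchors("X", "oCNF", -50.0, 4.44, 5.0)
        with pytest.raises(ZeroDivisionError):
            total_field_photoproduct(5.0, anchors, cal)

    def test_field_monotone_in_intensity(self, cal, y165o_anchors):
        # A < 0: brighter envelope -> more negative total field
        intensities = np.linspace(2.0, 15.0, 30)
        fields = [
            total_field_photoproduct(tdm_from_intensity(i, y165o_anchors), y165o_anchors, cal)
            for i in intensities
        ]
        assert all(b < a for a, b in zip(fields, fields[1:]))


class TestFieldFromFrequency:
    @pytest.mark.parametrize(
        "nu, expected", [(2225.9, -32.09), (2226.9, -28.36), (2234.5, 0.0)]
    )
    def test_linear_stark_relation(self, cal, nu, expected):
        assert field_from_frequency(nu, cal) == pytest.approx(expected, abs=0.005)


class TestScaledTdm:
    def test_published_component_values(self, cal):
        record = make_record("Y165oCNF", "Pfr", [(2225.9, 1.11, False), (2230.4, 6.5, True)],
                             envelope=7.64)
        m = scaled_tdm_components(record, Y165O)
        assert m[0] == pytest.approx(2.960, abs=1e-3)
        record = make_record("F192pCNF", "Pfr", [(2230.5, 1.164, True)], envelope=1.164)
        assert scaled_tdm_components(record, F192P)[0] == pytest.approx(7.737, abs=1e-3)

    def test_reference_intensity_identity(self, cal, y165o_anchors):
        record = make_record("Y165oCNF", "Pfr", [(2230.4, 7.64, True)])
        assert scaled_tdm_components(record, y165o_anchors)[0] == pytest.approx(7.767, abs=1e-12)


def solve_y165o_pfr(cal):
    record = make_record("Y165oCNF", "Pfr", [(2225.9, 1.11, False), (2230.4, 6.5, True)],
                         envelope=7.64)
    # use the published scaled TDMs as inputs by rescaling intensities exactly
    for c, m in zip(record.components, (2.960, 7.181)):
        c.intensity_RT = Y165O.i_pfr_rt * (m / Y165O.mu_pfr) ** 2
        c.intensity_T = c.intensity_RT
    record.envelope_intensity_RT = sum(c.intensity_RT for c in record.components)
    return solve_substates(record, Y165O, cal, e_total=-53.41)


class TestSubstateSolver:
    def test_free_plus_hbonded_doublet(self, cal):
        sol = solve_y165o_pfr(cal)
        p1, p2 = sol.components
        assert p1.x == pytest.approx(0.2477, abs=5e-4)
        assert p2.e_field == pytest.approx(-81.68, rel=1e-3)
        assert p2.mu == pytest.approx(8.279, abs=2e-3)
        assert p1.x + p2.x == pytest.approx(1.0, abs=1e-12)

    def test_single_hbonded_component(self, cal):
        record = make_record("Y165pCNF", "Pfr", [(2237.4, 2.642, True)])
        sol = solve_substates(record, Y165P, cal, e_total=-73.84)
        (comp,) = sol.components
        assert comp.x == 1.0
        assert comp.e_field == pytest.approx(-53.70, abs=0.01)
        assert sol.deviation_pct == pytest.approx(27.27, abs=0.01)

    def test_single_free_component_uses_frequency(self, cal):
        record = make_record("F192oCNF", "Meta-F", [(2226.9, 9.130, False)])
        sol = solve_substates(record, F192O, cal, e_total=-20.17)
        (comp,) = sol.components
        assert comp.e_field == pytest.approx(-28.36, abs=0.005)
        assert comp.x == 1.0

    def test_two_hbonded_components_with_pin(self, cal):
        record = make_record("Y165pCNF", "Pr", [(2232.4, 2.094, True), (2241.6, 1.686, True)],
                             envelope=3.780)
        for c, m in zip(record.components, (8.515, 7.640)):
            c.intensity_RT = Y165P.i_pfr_rt * (m / Y165P.mu_pfr) ** 2
            c.intensity_T = c.intensity_RT
        record.envelope_intensity_RT = sum(c.intensity_RT for c in record.components)
        sol = solve_substates(record, Y165P, cal, e_total=-128.72, pinned_x={"P1": 0.36})
        p2, p3 = sol.components
        assert sol.pinned
        assert p2.e_field == pytest.approx(-152.16, rel=1e-3)
        assert p3.e_field == pytest.approx(-53.40, rel=1e-3)
        assert sol.solution_family is not None and len(sol.solution_family) > 100

    def test_two_hbonded_default_minimizes_consistency_gap(self, cal):
        record = make_record("Y165pCNF", "Pr", [(2232.4, 2.094, True), (2241.6, 1.686, True)],
                             envelope=3.780)
        sol = solve_substates(record, Y165P, cal, e_total=-128.72)
        gaps = [f["gap"] for f in sol.solution_family]
        assert abs(sol.e_sum - sol.e_total) == pytest.approx(min(gaps), rel=1e-6)

    def test_infeasible_mole_fraction_raises(self, cal):
        # free-component scaled TDM larger than its frequency-implied TDM -> x > 1
        record = make_record("Y165oCNF", "Pfr", [(2225.9, 7.0, False), (2230.4, 1.0, True)],
                             envelope=8.0)
        with pytest.raises(InfeasibleSolutionError):
            solve_substates(record, Y165O, cal, e_total=-53.41)

    def test_grid_search_oracle_matches_closed_form(self, cal):
        """Brute-force minimization over the (x1, E2) lattice agrees with the solver."""
        sol = solve_y165o_pfr(cal)
        m1, m2 = (c.scaled_tdm for c in sol.components)
        mu0, A = cal.mu0_oCNF, cal.tdm_slope
        e1 = field_from_frequency(2225.9, cal)
        mu1 = mu0 + A * e1
        x_grid = np.arange(1e-4, 1.0, 1e-4)
        e2_grid = np.arange(-120.0, -40.0, 1e-2)
        # residuals of the two scaled-TDM equations on the lattice
        r1 = (m1 - np.sqrt(x_grid) * mu1) ** 2
        best_x = x_grid[np.argmin(r1)]
        mu2 = mu0 + A * e2_grid
        r2 = (m2 - math.sqrt(1.0 - best_x) * mu2) ** 2
        best_e2 = e2_grid[np.argmin(r2)]
        assert best_x == pytest.approx(sol.components[0].x, abs=1e-4)
        assert best_e2 == pytest.approx(sol.components[1].e_field, abs=1e-2)

    def test_reconstruction_identity(self, cal):
        sol = solve_y165o_pfr(cal)
        mu0, A = cal.mu0_oCNF, cal.tdm_slope
        for comp in sol.components:
            assert math.sqrt(comp.x) * (mu0 + A * comp.e_field) == pytest.approx(
                comp.scaled_tdm, abs=1e-9
            )

    def test_scale_invariance(self, cal):
        """Multiplying all raw intensities by any c > 0 changes no field or fraction."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            c = float(rng.uniform(0.1, 10.0))
            base = make_record("Y165oCNF", "Pfr",
                               [(2225.9, 1.11, False), (2230.4, 6.5, True)], envelope=7.64)
            scaled = make_record("Y165oCNF", "Pfr",
                                 [(2225.9, 1.11 * c, False), (2230.4, 6.5 * c, True)],
                                 envelope=7.64 * c)
            anchors_scaled = VariantAnchors("Y165oCNF", "oCNF", -53.41, 7.767, 7.64 * c)
            sol_a = solve_substates(base, Y165O, cal, e_total=-53.41)
            sol_b = solve_substates(scaled, anchors_scaled, cal, e_total=-53.41)
            for a, b in zip(sol_a.components, sol_b.components):
                assert b.x == pytest.approx(a.x, rel=1e-12)
                assert b.e_field == pytest.approx(a.e_field, rel=1e-12)


class TestTdmFieldLine:
    def test_exact_two_point_line(self):
        mu0, A = fit_tdm_field_line([(-10.0, 4.91), (-50.0, 6.79)])
        assert mu0 == pytest.approx(4.44, abs=1e-12)
        assert A == pytest.approx(-0.047, abs=1e-12)

    def test_published_substate_pairs_recover_calibration(self):
        # (field, TDM) pairs read off the solved substates, per label type
        ortho = [(-32.09, 5.948), (-81.68, 8.279), (-66.8, 7.580), (-29.48, 5.826)]
        para = [(-35.82, 8.724), (-53.70, 9.564), (-152.16, 14.192), (-33.58, 8.618)]
        mu0_o, a_o = fit_tdm_field_line(ortho)
        mu0_p, a_p = fit_tdm_field_line(para)
        assert a_o == pytest.approx(-0.047, abs=5e-4)
        assert a_p == pytest.approx(-0.047, abs=5e-4)
        assert mu0_o == pytest.approx(4.44, abs=0.01)
        assert mu0_p == pytest.approx(7.04, abs=0.01)

    def test_noisy_line_recovers_slope(self):
        rng = np.random.default_rng(1)
        e = rng.uniform(-120, -10, 50)
        mu = 4.44 - 0.047 * e + rng.normal(0, 0.05, 50)
        mu0, A = fit_tdm_field_line(np.column_stack([e, mu]))
        assert A == pytest.approx(-0.047, rel=0.05)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            fit_tdm_field_line([(-10.0, 4.91), (-10.0, 5.0)])


class TestConsistencyProportionality:
    def test_single_component_states_share_identical_deviation(self, cal, fixture_bundle):
        """Both field estimates are affine in (mu - mu0), so single-H-bonded-component
        states of one variant have the same percentage gap in every state."""
        from vseprobe.pipeline import analyze_fixture

        result = analyze_fixture(source="tdm")
        devs = [
            result.state("Y165pCNF", s).solution.deviation_pct
            for s in ("Pfr", "Lumi-F", "Meta-F")
        ]
        assert devs[0] == pytest.approx(27.27, abs=0.05)
        assert max(devs) - min(devs) < 0.02
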