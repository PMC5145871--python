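"""Closed-form five-layer model: neutrality, potential, voltages, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import memvolt as mv
from memvolt.constants import COULOMB_NM
from memvolt.layered_model import (
    ClosurePolicy,
    NoCrossingError,
    neutrality_residual,
    potential_at,
)

from conftest import quadrature_potential, quadrature_voltages, random_neutral_stack


class TestNeutralityResidual:
    def test_zero_stack(self):
        assert neutrality_residual(mv.LayerStack()) == 0.0

    def test_forced_arithmetic(self):
        stack = mv.LayerStack(rho_m1=-1.0, rho_m2=-1.0, H_m=4.0, D=2.5)
        assert neutrality_residual(stack) == pytest.approx(-8.0, abs=1e-15)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("pops", [0.045, 0.15])
    def test_generator_enforces_neutrality(self, seed, pops):
        rng = np.random.default_rng(seed)
        stack = mv.build_stack_params(
            mv.standard_composition(pops), D=float(rng.uniform(1, 6))
        )
        assert abs(neutrality_residual(stack)) < 1e-9

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            mv.LayerStack(H_m=0.0)
        with pytest.raises(ValueError):
            mv.LayerStack(D=-1.0)
        with pytest.raises(ValueError):
            mv.LayerStack(eps_r=0.0)


class TestPotentialProfile:
    def test_zero_charge_stack_gives_zero_potential(self):
        prof = mv.potential_profile(mv.LayerStack(), n_points=20)
        assert np.allclose(prof.phi, 0.0, atol=1e-15)
        assert prof.value(prof.reference_z) == pytest.approx(0.0, abs=1e-12)

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError):
            mv.potential_profile(mv.LayerStack(), n_points=2)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        rho_m=st.floats(-0.4, -0.01),
        d=st.floats(0.5, 6.0),
        rho_outer=st.floats(0.0, 0.1),
    )
    def test_mirror_symmetric_stack_has_even_potential(self, rho_m, d, rho_outer):
        """phi(Z) = phi(-Z) whenever the stack is mirror symmetric."""
        h_l, h_m = 4.0, 4.0
        rho2 = -(2 * rho_outer * h_l + 2 * rho_m * h_m) / d
        stack = mv.LayerStack(
            rho1=rho_outer, rho2=rho2, rho3=rho_outer,
            rho_m1=rho_m, rho_m2=rho_m, D=d,
        )
        z = np.linspace(0.0, stack.edges[-1], 301)
        assert np.max(np.abs(potential_at(stack, z) - potential_at(stack, -z))) < 1e-12

    def test_matches_quadrature_oracle(self):
        """Closed form vs brute-force double integration at 1e-4 nm step."""
        rho_m = -0.3
        stack = mv.LayerStack(
            rho1=0.0, rho3=0.0, rho2=-2 * rho_m * 4.0 / 3.0,
            rho_m1=rho_m, rho_m2=rho_m, H_m=4.0, H_L=4.0, D=3.0, eps_r=3.0,
        )
        z, phi_num = quadrature_potential(stack, dz=1e-4)
        assert np.max(np.abs(potential_at(stack, z) - phi_num)) < 1e-4

    def test_continuity_of_value_and_slope_at_interfaces(self):
        rng = np.random.default_rng(5)
        stack = random_neutral_stack(rng)
        eps = 1e-7
        for edge in stack.edges[1:-1]:
            lo, mid, hi = (
                float(potential_at(stack, edge - eps)),
                float(potential_at(stack, edge)),
                float(potential_at(stack, edge + eps)),
            )
            # second-order symmetric check: continuous phi leaves only the
            # O(eps^2) curvature term
            assert abs(hi + lo - 2 * mid) < 1e-8
            s_lo = (mid - lo) / eps
            s_hi = (hi - mid) / eps
            assert abs(s_hi - s_lo) < 1e-4  # no surface charge sheets


class TestTransmembraneVoltages:
    def test_symmetric_stack_reduces_to_single_voltage(self, pops15_stack):
        dv1, dv2 = mv.transmembrane_voltages(pops15_stack)
        s = pops15_stack
        expected = -COULOMB_NM / (2 * s.eps_r) * (s.rho_m1 * s.H_m + s.rho2 * s.D) * s.H_m
        assert dv1 == pytest.approx(dv2, abs=1e-12)
        assert dv1 == pytest.approx(expected, rel=1e-12)

    def test_zero_condition(self):
        """rho2*D = -rho_m*H_m makes the voltage vanish exactly."""
        rho_m, h_m, d = -0.2, 4.0, 2.0
        rho2 = -rho_m * h_m / d
        rho_outer = -(rho2 * d + 2 * rho_m * h_m) / (2 * 4.0)
        stack = mv.LayerStack(
            rho1=rho_outer, rho2=rho2, rho3=rho_outer, rho_m1=rho_m, rho_m2=rho_m, D=d
        )
        dv1, dv2 = mv.transmembrane_voltages(stack)
        assert dv1 == pytest.approx(0.0, abs=1e-12)
        assert dv2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_quadrature_oracle(self):
        rho_m = -0.3
        stack = mv.LayerStack(
            rho1=0.0, rho3=0.0, rho2=-2 * rho_m * 4.0 / 3.0,
            rho_m1=rho_m, rho_m2=rho_m, H_m=4.0, H_L=4.0, D=3.0, eps_r=3.0,
        )
        num = quadrature_voltages(stack, dz=1e-4)
        ana = mv.transmembrane_voltages(stack)
        assert ana[0] == pytest.approx(num[0], abs=1e-4)
        assert ana[1] == pytest.approx(num[1], abs=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_consistent_with_profile_readoff(self, seed):
        """Closed forms equal the potential difference across each slab."""
        stack = random_neutral_stack(np.random.default_rng(seed))
        prof = mv.potential_profile(stack, n_points=50)
        f1, f2 = stack.membrane1_faces, stack.membrane2_faces
        dv1, dv2 = mv.transmembrane_voltages(stack)
        assert dv1 == pytest.approx(prof.value(f1[1]) - prof.value(f1[0]), abs=1e-9)
        assert dv2 == pytest.approx(prof.value(f2[0]) - prof.value(f2[1]), abs=1e-9)

    def test_non_neutral_stack_warns(self):
        with pytest.warns(UserWarning, match="not neutral"):
            mv.transmembrane_voltages(mv.LayerStack(rho_m1=-0.1))


class TestVoltageVsDistance:
    def test_paper_protocol_grid(self, pops15_stack):
        """6 nm down to 2 nm in 0.5 nm steps: 9 rows, monotone voltage."""
        d = np.arange(6.0, 1.9, -0.5)
        res = mv.voltage_vs_distance(pops15_stack, d, policy=ClosurePolicy.FIXED_RHO2)
        assert len(res.table) == 9
        assert res.metadata["policy"] == "fixed_rho2"
        dv = res.table["dV1_V"].to_numpy()
        assert np.all(np.diff(dv) != 0) and (np.all(np.diff(dv) > 0) or np.all(np.diff(dv) < 0))

    def test_affine_slope(self, pops15_stack):
        s = pops15_stack
        res = mv.voltage_vs_distance(s, [2.0, 6.0], policy=ClosurePolicy.FIXED_RHO2)
        dv = res.table["dV1_V"].to_numpy()
        slope = (dv[1] - dv[0]) / 4.0
        expected = -s.rho2 * s.H_m * COULOMB_NM / (2 * s.eps_r)
        assert slope == pytest.approx(expected, rel=1e-12)

    def test_zero_condition_row(self):
        rho_m, h_m = -0.2, 4.0
        d0 = 2.5
        rho2 = -rho_m * h_m / d0
        template = mv.LayerStack(rho2=rho2, rho_m1=rho_m, rho_m2=rho_m, D=d0)
        res = mv.voltage_vs_distance(template, [d0], policy=ClosurePolicy.FIXED_RHO2)
        assert res.table["dV1_V"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_rejects_bad_input(self, pops15_stack):
        with pytest.raises(ValueError):
            mv.voltage_vs_distance(pops15_stack, [])
        with pytest.raises(ValueError):
            mv.voltage_vs_distance(pops15_stack, [-1.0])


class TestCriticalDistance:
    @pytest.mark.parametrize("policy", list(ClosurePolicy))
    def test_round_trip_at_known_distance(self, pops15_stack, policy):
        target = abs(
            mv.transmembrane_voltages(mv.stack_at_distance(pops15_stack, 3.0, policy))[0]
        )
        d = mv.critical_distance(pops15_stack, target, policy=policy)
        assert d == pytest.approx(3.0, abs=1e-6)

    def test_higher_critical_voltage_needs_closer_contact(self, pops15_stack):
        d1 = mv.critical_distance(pops15_stack, 0.8)
        d2 = mv.critical_distance(pops15_stack, 1.2)
        assert d2 < d1

    @pytest.mark.parametrize("dv_crit", [0.7, 0.9, 1.2])
    def test_poration_voltage_range_gives_finite_distance(self, pops15_stack, dv_crit):
        """Critical voltages in the electroporation range (0.7-1.2 V)."""
        from scipy.optimize import brentq

        d = mv.critical_distance(pops15_stack, dv_crit)
        assert 0 < d < 10

        def gap(x):
            return (
                abs(mv.transmembrane_voltages(mv.stack_at_distance(pops15_stack, x))[0])
                - dv_crit
            )

        d_oracle = brentq(gap, 0.5, 10.0, xtol=1e-9)
        assert d == pytest.approx(d_oracle, abs=1e-8)

    def test_no_crossing_reported(self, pops15_stack):
        with pytest.raises(NoCrossingError):
            mv.critical_distance(pops15_stack, 100.0)

    def test_rejects_non_positive_voltage(self, pops15_stack):
        with pytest.raises(ValueError):
            mv.critical_distance(pops15_stack, 0.0)


class TestCompositionToMembraneCharge:
    def test_neutral_composition(self):
        comp = mv.standard_composition(0.0)
        assert mv.composition_to_membrane_charge(comp) == 0.0

    def test_pops_15_percent_hand_value(self):
        comp = mv.standard_composition(0.15)
        rho = mv.composition_to_membrane_charge(comp, area_per_lipid=0.65, H_m=4.0)
        assert rho == pytest.approx(2 * 0.15 * -1.0 / (0.65 * 4.0), rel=1e-12)

    def test_pip2_single_leaflet(self):
        comp = {"PIP2": 0.05, "DOPC": 0.95}
        rho = mv.composition_to_membrane_charge(comp, leaflets=1)
        assert rho == pytest.approx(0.05 * -5.0 / (0.65 * 4.0), rel=1e-12)

    def test_unknown_species_needs_charge(self):
        with pytest.raises(ValueError, match="unknown lipid species"):
            mv.composition_to_membrane_charge({"MYSTERY": 1.0})
        rho = mv.composition_to_membrane_charge({"MYSTERY": 1.0}, species_charges={"MYSTERY": -2.0})
        assert rho == pytest.approx(2 * -2.0 / (0.65 * 4.0), rel=1e-12)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            mv.composition_to_membrane_charge({"POPS": 0.5})

    def test_pops_ladder_monotone_charge(self):
        ladder = [0.045, 0.06, 0.09, 0.12, 0.15]
        rhos = [
            abs(mv.composition_to_membrane_charge(mv.standard_composition(f)))
            for f in ladder
        ]
        assert np.all(np.diff(rhos) > 0)
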