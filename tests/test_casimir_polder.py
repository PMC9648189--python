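"""Perturbation-theory oracles: sums over states, Casimir-Polder integrals,
London and Omega-shifted closed forms."""

import numpy as np
import pytest

import solvdisp as sd
from solvdisp.casimir_polder import (c6_exact_sum, c6_quadrature,
                                     gamma_factor_quadrature,
                                     load_transition_system,
                                     polarizability_real)


@pytest.fixture(scope="module")
def two_level():
    return load_transition_system("two-level")


@pytest.fixture(scope="module")
def three_level_excited():
    return load_transition_system("three-level-excited")


@pytest.fixture(scope="module")
def five_level():
    return load_transition_system("five-level")


class TestCpQuadrature:
    def test_symmetry(self):
        assert sd.cp_quadrature(0.3, 0.7) == pytest.approx(
            sd.cp_quadrature(0.7, 0.3), rel=1e-12)

    def test_symbolic_closed_form_unit_arguments(self):
        """(2/pi) Int uv/((u^2+w^2)(v^2+w^2)) dw at u=v=1, against sympy."""
        import sympy as sp
        w = sp.symbols("w", positive=True)
        exact = float(2 / sp.pi * sp.integrate(1 / (1 + w**2) ** 2,
                                               (w, 0, sp.oo)))
        assert exact == pytest.approx(0.5)  # the kernel is 1/(u+v)
        assert sd.cp_quadrature(1.0, 1.0) == pytest.approx(exact, rel=1e-10)

    @pytest.mark.parametrize("u,v", [(0.1, 0.1), (0.5, 2.0), (3.0, 0.02)])
    def test_kernel_identity(self, u, v):
        assert sd.cp_quadrature(u, v) == pytest.approx(1.0 / (u + v), rel=1e-10)

    def test_large_argument_limit(self):
        assert sd.cp_quadrature(1e6, 0.5) < 1e-5

    def test_positive_arguments_required(self):
        with pytest.raises(ValueError):
            sd.cp_quadrature(0.0, 1.0)


class TestDispersionSum:
    def test_zero_dipoles_give_zero(self, two_level):
        silent = sd.TransitionSystem(
            (sd.Level(0.0, np.zeros(3)), sd.Level(0.4, np.zeros(3))), 0)
        assert sd.dispersion_sum(two_level, silent, 10.0) == 0.0

    def test_two_level_closed_form(self, two_level):
        """Single-term sum evaluable by hand: -(2/3)|muA|^2|muB|^2/(u+v)/R^6."""
        other = sd.TransitionSystem(
            (sd.Level(0.0, np.zeros(3)), sd.Level(0.4, np.array([0, 0, 0.8]))), 0)
        R = 12.0
        expected = -(2.0 / 3.0) * 1.0**2 * 0.8**2 / (0.5 + 0.4) / R**6
        assert sd.dispersion_sum(two_level, other, R) == pytest.approx(
            expected, rel=1e-14)

    def test_r6_scaling_exact(self, two_level, five_level):
        """E(R) * R^6 is constant in the dipole limit."""
        vals = [sd.dispersion_sum(five_level, two_level, R) * R**6
                for R in (20.0, 40.0, 70.0, 100.0)]
        assert np.ptp(vals) / abs(vals[0]) < 1e-10

    def test_fixed_orientation_differs_but_same_sign(self, two_level):
        iso = sd.dispersion_sum(two_level, two_level, 15.0, orientation_averaged=True)
        fixed = sd.dispersion_sum(two_level, two_level, 15.0, orientation_averaged=False)
        assert iso < 0 and fixed < 0
        # z-aligned dipoles couple as -2/R^3: |m|^2 = 4, vs 2/3 averaged
        assert fixed / iso == pytest.approx(6.0, rel=1e-12)

    def test_resonance_detected(self):
        a = sd.TransitionSystem((sd.Level(0.0, np.array([0, 0, 1.0])),
                                 sd.Level(0.3, np.zeros(3))), 1)  # de-excitation -0.3
        b = sd.TransitionSystem((sd.Level(0.0, np.zeros(3)),
                                 sd.Level(0.3, np.array([0, 0, 1.0]))), 0)
        with pytest.raises(ValueError, match="resonance"):
            sd.dispersion_sum(a, b, 10.0)

    def test_large_r_matches_cp_quadrature_c6(self, five_level, two_level):
        """-E(R) R^6 equals the Casimir-Polder integral of the sum-over-states
        polarizabilities at R = 100 bohr."""
        R = 100.0
        e = sd.dispersion_sum(five_level, two_level, R)
        c6 = c6_quadrature(lambda w: sd.polarizability_iw(five_level, w),
                           lambda w: sd.polarizability_iw(two_level, w))
        assert -e * R**6 == pytest.approx(c6.value, rel=1e-6)


class TestPolarizabilities:
    def test_static_value(self, five_level):
        u = five_level.transition_energies
        s = five_level.dipole_strengths
        assert sd.polarizability_iw(five_level, 0.0) == pytest.approx(
            (2.0 / 3.0) * np.sum(s / u), rel=1e-14)

    def test_monotone_decrease_to_zero(self, five_level):
        w = np.linspace(0.0, 50.0, 40)
        a = np.array([sd.polarizability_iw(five_level, wi) for wi in w])
        assert np.all(np.diff(a) < 0)
        assert a[-1] < 1e-3 * a[0]

    def test_drude_one_pole(self):
        assert sd.drude_polarizability(4.5, 0.5, 0.0) == pytest.approx(4.5)
        assert sd.drude_polarizability(4.5, 0.5, 0.5) == pytest.approx(2.25)
        with pytest.raises(ValueError):
            sd.drude_polarizability(-1.0, 0.5, 0.0)


class TestLondon:
    def test_unit_inputs(self):
        # (3/2) * 1 * 1 * (1*1)/(1+1) = 3/4 with all factors explicit
        assert sd.london_c6(1.0, 1.0, 1.0, 1.0).value == pytest.approx(0.75)

    def test_swap_symmetry(self):
        a = sd.london_c6(4.5, 0.5, 2.0, 0.9).value
        b = sd.london_c6(2.0, 0.9, 4.5, 0.5).value
        assert a == pytest.approx(b, rel=1e-14)

    def test_matches_cp_quadrature_of_drude_models(self):
        """London's formula is the exact CP integral of two one-pole models."""
        c6q = c6_quadrature(lambda w: sd.drude_polarizability(4.5, 0.5, w),
                            lambda w: sd.drude_polarizability(4.5, 0.5, w))
        assert c6q.value == pytest.approx(sd.london_c6(4.5, 0.5, 4.5, 0.5).value,
                                          rel=1e-10)

    def test_unsold_vs_exact_sum_same_magnitude(self, five_level):
        """The average-energy closure is an approximation: London C6 from
        the static polarizability and the dominant transition energy stays
        within 35% of the exact sum on the hydrogen-like fixture."""
        exact = c6_exact_sum(five_level, five_level).value
        alpha = five_level.static_polarizability()
        london = sd.london_c6(alpha, 0.375, alpha, 0.375).value
        assert abs(london - exact) / exact < 0.35


class TestModifiedC6:
    B_MODEL = (1.2, 0.30)  # (abar_B(0), W_B) in a.u.

    def test_reduces_to_london_at_zero_omega(self):
        a = sd.modified_c6((4.5, 0.5), (2.0, 0.45), 0.0)
        assert a.value == pytest.approx(sd.london_c6(4.5, 0.5, 2.0, 0.45).value,
                                        rel=1e-14)
        assert a.method == "modified-omega"

    def test_exact_reference_matches_quadrature(self, three_level_excited):
        """Closed form vs numerical CP integral of the Omega-shifted
        sum-over-states polarizability (excited reference with one
        de-excitation channel)."""
        omega = 0.22  # > |de-excitation| = 0.18
        abar, wb = self.B_MODEL
        closed = sd.modified_c6(three_level_excited, self.B_MODEL, omega)
        quad = c6_quadrature(
            lambda w: sd.polarizability_iw(three_level_excited, w, shift=omega),
            lambda w: abar * wb**2 / (wb**2 + w**2))
        assert closed.value == pytest.approx(quad.value, rel=1e-6)

    def test_model_reference_matches_quadrature(self):
        abar_a, wa = 3.0, 0.62
        abar, wb = self.B_MODEL
        closed = sd.modified_c6((abar_a, wa), self.B_MODEL, 0.2)
        quad = c6_quadrature(lambda w: abar_a * wa**2 / (wa**2 + w**2),
                             lambda w: abar * wb**2 / (wb**2 + w**2))
        assert closed.value == pytest.approx(quad.value, rel=1e-10)

    def test_positive_over_valid_omega_interval(self, three_level_excited):
        for omega in np.linspace(0.19, 0.40, 8):
            assert sd.modified_c6(three_level_excited, self.B_MODEL,
                                  omega).value > 0

    def test_omega_constraint_enforced(self, three_level_excited):
        with pytest.raises(ValueError, match="de-excitation"):
            sd.modified_c6(three_level_excited, self.B_MODEL, 0.1)
        with pytest.raises(ValueError, match="W_B"):
            sd.modified_c6((4.5, 0.5), (1.2, -0.1), 0.2)


class TestGammaFactor:
    def test_matches_closed_form(self):
        assert gamma_factor_quadrature(0.61, 0.23) == pytest.approx(
            0.23 / (0.61 + 0.23), rel=1e-10)


class TestTransitionSystemValidation:
    def test_distinct_energies_required(self):
        with pytest.raises(ValueError):
            sd.TransitionSystem((sd.Level(0.1, np.zeros(3)),
                                 sd.Level(0.1, np.zeros(3))), 0)

    def test_reference_sign_structure(self, three_level_excited, five_level):
        assert not three_level_excited.is_ground_reference
        assert five_level.is_ground_reference
        assert np.min(three_level_excited.transition_energies) == pytest.approx(-0.18)

    def test_real_frequency_polarizability_below_resonance(self, five_level):
        a0 = polarizability_real(five_level, 0.0)
        a_w = polarizability_real(five_level, 0.2)
        assert a_w > a0 > 0
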