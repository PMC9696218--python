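"""Dielectric model, screening lengths, and the two axial force laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnabuckle.errors import DomainError
from dnabuckle.media_forces import (
    CONSTANTS,
    DnaGeometry,
    Medium,
    bjerrum_length,
    condensation_parameter,
    debye_length,
    electrostatic_force,
    relative_permittivity,
    thermal_force,
)


class TestRelativePermittivity:
    @pytest.mark.parametrize(
        "T, expected",
        [(293.0, 87.74), (298.0, 85.74), (278.0, 93.74), (313.0, 79.74)],
    )
    def test_linear_law(self, T, expected):
        assert relative_permittivity(T) == pytest.approx(expected, abs=1e-12)

    def test_warns_outside_validity_window(self):
        with pytest.warns(UserWarning, match="validity window"):
            relative_permittivity(350.0)

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(DomainError):
            relative_permittivity(0.0)


class TestBjerrumLength:
    def test_golden_value_at_298K(self):
        # Term-by-term hand evaluation of q^2/(4 pi eps0 eps_r kB T) with the
        # model constants: 2.56e-38 / 3.92132e-29 m.
        assert bjerrum_length(298.0, 85.74) == pytest.approx(6.52842e-10, rel=1e-5)

    def test_order_of_magnitude(self):
        lB = bjerrum_length(298.0, 85.74)
        assert 0.6e-9 < lB < 0.7e-9

    @settings(max_examples=50, derandomize=True)
    @given(
        T=st.floats(200.0, 400.0),
        eps=st.floats(20.0, 120.0),
    )
    def test_scaling_laws(self, T, eps):
        lB = bjerrum_length(T, eps)
        # Doubling the permittivity halves lB; (2T, eps/2) leaves lB fixed.
        assert bjerrum_length(T, 2 * eps) == pytest.approx(lB / 2, rel=1e-12)
        assert bjerrum_length(2 * T, eps / 2) == pytest.approx(lB, rel=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(DomainError):
            bjerrum_length(-1.0, 80.0)
        with pytest.raises(DomainError):
            bjerrum_length(298.0, 0.0)


class TestDebyeLength:
    def test_golden_value(self, medium_0p1M):
        # sqrt(eps0*85.74*kB*298 / (0.1*1000*NA*q^2)) by hand: 1.42272 nm.
        assert debye_length(medium_0p1M) == pytest.approx(1.42272e-9, rel=1e-5)

    def test_concentration_scaling(self):
        lam1 = debye_length(Medium(c=0.05))
        lam4 = debye_length(Medium(c=0.2))
        assert lam4 == pytest.approx(lam1 / 2, rel=1e-12)

    def test_valence_scaling(self):
        lam1 = debye_length(Medium(c=0.1, Z=1))
        lam2 = debye_length(Medium(c=0.1, Z=2))
        assert lam2 == pytest.approx(lam1 / 2, rel=1e-12)

    def test_rejects_nonpositive_concentration(self):
        with pytest.raises(DomainError):
            Medium(c=0.0)


class TestElectrostaticForce:
    def test_golden_value(self, medium_0p1M, geom):
        # Bracket by hand: kb = 0.11949, xi = 3.8403, bracket = 7.4727;
        # prefactor kB*T/lB = 6.2996e-12 N -> 47.07 pN.
        F = electrostatic_force(medium_0p1M, geom)
        assert F == pytest.approx(4.70741e-11, rel=1e-4)

    def test_tens_of_piconewtons_scale(self, medium_0p1M, geom):
        assert 1e-11 < electrostatic_force(medium_0p1M, geom) < 1e-10

    def test_high_salt_limit(self, geom):
        # Bracket -> -1, so F_ele -> -kB T / (Z^2 lB).
        med = Medium(c=5e4, Z=1, T=298.0)
        lB = bjerrum_length(298.0, med.permittivity)
        expected = -CONSTANTS.kB * 298.0 / lB
        assert electrostatic_force(med, geom) == pytest.approx(expected, rel=1e-3)

    def test_monotone_decreasing_in_concentration(self, geom, salt_scan):
        forces = [electrostatic_force(Medium(c=float(c)), geom) for c in salt_scan]
        assert all(a > b for a, b in zip(forces, forces[1:]))

    def test_diverges_logarithmically_at_low_salt(self, geom):
        # The -ln(1 - e^{-kb}) term gives F ~ (kBT/lB) * (1/2) ln(c_ref/c) as
        # c -> 0 (kb scales as sqrt(c)); check the increment over 5 decades.
        med_ref = Medium(c=1e-3)
        f_low = electrostatic_force(Medium(c=1e-8), geom)
        f_ref = electrostatic_force(med_ref, geom)
        lB = bjerrum_length(298.0, med_ref.permittivity)
        expected_increment = CONSTANTS.kB * 298.0 / lB * 0.5 * math.log(1e5)
        assert f_low > f_ref
        assert f_low - f_ref == pytest.approx(expected_increment, rel=0.05)

    def test_condensation_parameter_value(self, medium_0p1M, geom):
        # xi = lB/b ~ 3.84 for B-DNA charge spacing 0.17 nm at 298 K.
        assert condensation_parameter(medium_0p1M, geom) == pytest.approx(3.84, rel=1e-2)


class TestThermalForce:
    def test_golden_value(self, geom):
        # (2 kB T / R) sqrt(50/6) = 8.2248e-12 * 2.88675 N.
        F = thermal_force(50e-9, 6e-9, geom, 298.0)
        assert F == pytest.approx(2.374295e-11, rel=1e-5)

    def test_zero_stiffness_gives_zero_force(self, geom):
        assert thermal_force(0.0, 6e-9, geom, 298.0) == 0.0

    @pytest.mark.parametrize("factor", [2.0, 4.0, 9.0])
    def test_sqrt_scaling_in_lp_over_lcb(self, geom, factor):
        base = thermal_force(50e-9, 6e-9, geom, 298.0)
        assert thermal_force(factor * 50e-9, 6e-9, geom, 298.0) == pytest.approx(
            base * math.sqrt(factor), rel=1e-12
        )
        assert thermal_force(50e-9, factor * 6e-9, geom, 298.0) == pytest.approx(
            base / math.sqrt(factor), rel=1e-12
        )

    def test_rejects_nonpositive_lengths(self, geom):
        with pytest.raises(DomainError):
            thermal_force(50e-9, 0.0, geom, 298.0)
        with pytest.raises(DomainError):
            thermal_force(-1e-9, 6e-9, geom, 298.0)


class TestGeometry:
    def test_derived_section_properties(self, geom):
        assert geom.area == pytest.approx(math.pi * 1e-18, rel=1e-12)
        assert geom.inertia == pytest.approx(math.pi * 1e-36 / 4, rel=1e-12)

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(DomainError):
            DnaGeometry(R=0.0)

    def test_permittivity_override(self):
        med = Medium(c=0.1, eps_r=78.5)
        assert med.permittivity == 78.5
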