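"""The lp <-> lcb map, its degenerate limits, and the three-term decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnabuckle import (
    BucklingModel,
    EndConstraint,
    Medium,
    buckling_from_persistence,
    decompose,
    persistence_from_buckling,
    predict_curve,
)
from dnabuckle.errors import DomainError
from dnabuckle.media_forces import DnaGeometry, reduced_electrostatic_force
from dnabuckle.persistence_map import (
    characteristic_residual,
    lcb_from_lp,
    lp_from_lcb,
)

PI2, PI4 = math.pi**2, math.pi**4
R = 1e-9


def quadratic_root_oracle(mu, lcb, f, R):
    """Independent solve: numpy eigenvalue roots of the quadratic in lp."""
    a = PI4 / mu**4
    b = 4 * lcb**3 / R**2 + 2 * PI2 * f * lcb**2 / mu**2
    c = f**2 * lcb**4
    roots = np.roots([a, -b, c])
    return float(np.max(roots.real))


class TestForwardMap:
    def test_golden_suspended_class(self, suspended_model, medium_0p1M):
        # Class means (mu = 1.021, lcb = 5.95 nm) at 0.1 M, 298 K land inside
        # the experimental 40-80 nm band.
        lp = persistence_from_buckling(suspended_model, medium_0p1M)
        assert lp == pytest.approx(6.81042e-8, rel=1e-5)

    def test_golden_fixbead_class(self, fixbead_model, medium_0p1M):
        lp = persistence_from_buckling(fixbead_model, medium_0p1M)
        assert lp == pytest.approx(6.27443e-8, rel=1e-5)

    def test_matches_polynomial_root_oracle(self, medium_0p1M, geom):
        f = reduced_electrostatic_force(medium_0p1M, geom)
        for mu in (0.5, 0.718, 1.021, 1.25):
            for lcb in (4e-9, 5.95e-9, 8.43e-9, 16e-9):
                assert lp_from_lcb(mu, lcb, f, geom.R) == pytest.approx(
                    quadratic_root_oracle(mu, lcb, f, geom.R), rel=1e-10
                )

    def test_null_isomer_limit(self):
        # F_ele = 0, mu = 1/2: lp* = lcb*^3 / (4 pi^4 R^2) exactly.
        for lcb in (4e-9, 6e-9, 12e-9):
            assert lp_from_lcb(0.5, lcb, 0.0, R) == pytest.approx(
                lcb**3 / (4 * PI4 * R**2), rel=1e-12
            )

    def test_electrostatic_only_limit(self, medium_0p1M, geom):
        # Dropping the thermal reaction leaves lp = mu^2 lcb^2 f / pi^2, which
        # is exactly the strongly environment-dependent term of the split.
        f = reduced_electrostatic_force(medium_0p1M, geom)
        mu, lcb = 1.021, 5.95e-9
        expected = mu**2 * lcb**2 * f / PI2
        d = decompose(BucklingModel(EndConstraint(mu), lcb), medium_0p1M)
        assert d.tsde == pytest.approx(expected, rel=1e-12)

    def test_characteristic_polynomial_residual_vanishes(self, medium_0p1M, geom):
        f = reduced_electrostatic_force(medium_0p1M, geom)
        for mu in (0.6, 1.0):
            for lcb in (5e-9, 10e-9):
                lp = lp_from_lcb(mu, lcb, f, geom.R)
                res = characteristic_residual(mu, lcb, lp, f, geom.R)
                scale = PI4 * (lp / 1e-9) ** 2 / mu**4
                assert abs(res) < 1e-8 * scale

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(DomainError):
            lp_from_lcb(0.0, 6e-9, 1e10, R)
        with pytest.raises(DomainError):
            lp_from_lcb(1.0, -6e-9, 1e10, R)


class TestInverseMap:
    def test_round_trip_identity_grid(self, geom):
        for mu in (0.5, 0.75, 1.0, 1.25):
            for lcb in (4e-9, 8e-9, 16e-9):
                for c in (0.01, 0.1, 1.0):
                    f = reduced_electrostatic_force(Medium(c=c), geom)
                    lp = lp_from_lcb(mu, lcb, f, geom.R)
                    back = lcb_from_lp(mu, lp, f, geom.R)
                    assert back == pytest.approx(lcb, rel=1e-6)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        mu=st.floats(0.4, 2.0),
        lcb_nm=st.floats(2.0, 25.0),
        c=st.floats(0.001, 4.0),
    )
    def test_round_trip_property(self, mu, lcb_nm, c):
        geom = DnaGeometry()
        f = reduced_electrostatic_force(Medium(c=c), geom)
        lcb = lcb_nm * 1e-9
        lp = lp_from_lcb(mu, lcb, f, geom.R)
        assert lcb_from_lp(mu, lp, f, geom.R) == pytest.approx(lcb, rel=1e-6)

    def test_null_isomer_closed_form_inversion(self):
        lp = 5e-8
        lcb = lcb_from_lp(0.5, lp, 0.0, R)
        assert lcb == pytest.approx((4 * PI4 * R**2 * lp) ** (1 / 3), rel=1e-12)

    def test_golden_cyclization_inversion(self, medium_0p1M, geom):
        # Empirical cyclization lp at 298 K pushed through the clamp-clamp
        # inverse at 0.1 M; frozen from the quartic-root evaluation.
        lp = 4.757028e-8
        lcb = buckling_from_persistence(lp, EndConstraint(0.5), medium_0p1M, geom)
        assert lcb == pytest.approx(1.09677e-8, rel=1e-5)

    def test_object_api_round_trip(self, suspended_model, medium_0p1M):
        lp = persistence_from_buckling(suspended_model, medium_0p1M)
        lcb = buckling_from_persistence(
            lp, suspended_model.constraint, medium_0p1M, suspended_model.geom
        )
        assert lcb == pytest.approx(suspended_model.lcb, rel=1e-9)


class TestDecomposition:
    def test_additivity_everywhere(self, geom, salt_scan):
        model = BucklingModel(EndConstraint(1.021), 5.95e-9, geom)
        for c in salt_scan:
            med = Medium(c=float(c))
            d = decompose(model, med)
            total = persistence_from_buckling(model, med)
            assert d.total == pytest.approx(total, rel=1e-9)

    def test_constraint_term_independent_of_salt(self, geom, salt_scan):
        model = BucklingModel(EndConstraint(0.718), 8.43e-9, geom)
        todcs = {decompose(model, Medium(c=float(c))).todc for c in salt_scan}
        assert max(todcs) == pytest.approx(min(todcs), rel=1e-14)

    def test_strong_term_monotone_decreasing_in_salt(self, geom, salt_scan):
        model = BucklingModel(EndConstraint(1.021), 5.95e-9, geom)
        tsdes = [decompose(model, Medium(c=float(c))).tsde for c in salt_scan]
        assert all(a > b for a, b in zip(tsdes, tsdes[1:]))

    def test_no_electrostatics_collapses_to_constraint_terms(self, geom):
        # With f = 0 the linear term vanishes and the square-root term
        # collapses onto the constraint-only value, so the total is twice the
        # first term -- the null-isomer result.
        from dnabuckle.persistence_map import decompose_terms

        mu, lcb = 0.5, 6e-9
        todc, twde, tsde = decompose_terms(mu, lcb, 0.0, R)
        assert tsde == 0.0
        assert twde == pytest.approx(todc, rel=1e-12)
        assert todc + twde == pytest.approx(lcb**3 / (4 * PI4 * R**2), rel=1e-12)


class TestPredictCurve:
    def test_degenerate_band_at_zero_sigma(self, suspended_model, medium_0p1M):
        [(lp, lo, hi)] = predict_curve(suspended_model, [medium_0p1M], sigma_mu=0.0)
        assert lo == lp == hi

    def test_band_brackets_central_value(self, suspended_model, salt_scan):
        media = [Medium(c=float(c)) for c in salt_scan[::6]]
        for lp, lo, hi in predict_curve(suspended_model, media, sigma_mu=0.250):
            assert lo <= lp <= hi

    def test_lp_monotone_in_mu(self, medium_0p1M, geom):
        f = reduced_electrostatic_force(medium_0p1M, geom)
        lps = [lp_from_lcb(mu, 6e-9, f, geom.R) for mu in np.linspace(0.4, 2.0, 30)]
        assert all(a < b for a, b in zip(lps, lps[1:]))

    def test_curve_decreasing_in_salt(self, suspended_model, salt_scan):
        media = [Medium(c=float(c)) for c in salt_scan]
        lps = [lp for lp, _, _ in predict_curve(suspended_model, media)]
        assert all(a > b for a, b in zip(lps, lps[1:]))

    def test_fixbead_below_suspended_everywhere(
        self, suspended_model, fixbead_model, salt_scan
    ):
        for c in salt_scan:
            med = Medium(c=float(c))
            assert persistence_from_buckling(
                fixbead_model, med
            ) < persistence_from_buckling(suspended_model, med)

    def test_rejects_nonpositive_band_edge(self, suspended_model, medium_0p1M):
        with pytest.raises(DomainError):
            predict_curve(suspended_model, [medium_0p1M], sigma_mu=1.5)
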