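import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aunpcount.nanoparticle_model import (
    DEFAULT_CONSTANTS,
    NPEstimate,
    StrippingConstants,
    area_from_oxide_charge,
    count_from_area,
    coverage,
    enzyme_packing,
    estimate_np,
    geometric_area_cm2,
    hemisphere_area,
    oxide_charge_forward,
    radius_from_charges,
    stripping_charge_forward,
)

C = DEFAULT_CONSTANTS


class TestConstants:
    def test_defaults(self):
        assert C.k_ox == pytest.approx(489e-6)
        assert C.n_eff == 1.9
        assert C.x == 2.0
        assert C.rho_au == 19.3
        assert C.m_au == 196.97

    @pytest.mark.parametrize("name,expected", [
        ("finot", 489e-6), ("habrioux", 543e-6), ("trasatti", 400e-6), ("tan", 450e-6),
        ("489", 489e-6), ("543", 543e-6),
    ])
    def test_k_ox_selection(self, name, expected):
        assert C.with_k_ox(name).k_ox == pytest.approx(expected)

    def test_custom_k_ox_warns(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            c = StrippingConstants(k_ox=300e-6)
        assert c.k_ox == 300e-6
        assert any("k_ox" in r.message for r in caplog.records)

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(ValueError):
            StrippingConstants(n_eff=0.0)


class TestAreaFromOxideCharge:
    def test_zero(self):
        assert area_from_oxide_charge(0.0) == 0.0

    def test_definitional(self):
        assert area_from_oxide_charge(489e-6) == pytest.approx(1.0)

    def test_table_scale(self):
        # q_ox constructed as k_ox * 5.2e-2 cm^2: same order as a typical
        # few-1e-2 cm^2 electrode coating
        assert area_from_oxide_charge(2.54e-5) == pytest.approx(5.2e-2, rel=1e-2)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            area_from_oxide_charge(-1e-6)


class TestRadiusFromCharges:
    def test_linear_in_charge_ratio(self):
        r1 = radius_from_charges(1e-4, 5e-2)
        r2 = radius_from_charges(2e-4, 5e-2)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_unit_radius_by_construction(self):
        ratio = (C.n_eff * C.e * C.rho_au * C.n_a) / (3.0 * C.m_au) * 1e-7  # C/cm^2 for r=1 nm
        assert radius_from_charges(ratio, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_closed_form_round_trip_single(self):
        r0, n0 = 8.5, 1e10
        q = stripping_charge_forward(r0, n0)
        s = oxide_charge_forward(r0, n0) / C.k_ox
        assert radius_from_charges(q, s) == pytest.approx(r0, rel=1e-10)
        assert count_from_area(s, radius_from_charges(q, s)) == pytest.approx(n0, rel=1e-10)

    @pytest.mark.parametrize("bad", [(0.0, 1.0), (1e-4, 0.0), (-1e-4, 1.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            radius_from_charges(*bad)

    def test_independent_of_shape_factor(self):
        assert radius_from_charges(1e-4, 5e-2, StrippingConstants(x=3.0)) == pytest.approx(
            radius_from_charges(1e-4, 5e-2), rel=1e-14
        )


class TestCountFromArea:
    def test_one_particle(self):
        s = C.x * math.pi * (1e-6) ** 2  # one particle of r = 10 nm = 1e-6 cm
        assert count_from_area(s, 10.0) == pytest.approx(1.0, rel=1e-12)

    def test_table_scale(self):
        # s = 5.2e-2 cm^2, d = 19 nm, x = 2 -> ~9.2e9 particles
        n = count_from_area(5.2e-2, 9.5)
        assert n == pytest.approx(9.2e9, rel=0.01)

    def test_r_inverse_square_scaling(self):
        assert count_from_area(1e-2, 5.0) == pytest.approx(
            4 * count_from_area(1e-2, 10.0), rel=1e-12
        )

    def test_scales_as_inverse_x(self):
        n2 = count_from_area(1e-2, 10.0, StrippingConstants(x=2.0))
        n3 = count_from_area(1e-2, 10.0, StrippingConstants(x=3.0))
        assert n3 == pytest.approx(n2 * 2.0 / 3.0, rel=1e-12)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            count_from_area(1e-2, 0.0)


class TestForwardModel:
    def test_zero_cases(self):
        assert stripping_charge_forward(0.0, 1e10) == 0.0
        assert stripping_charge_forward(9.5, 0.0) == 0.0

    def test_hand_evaluated_charge(self):
        # independent arithmetic with explicit constants (hemisphere, r in cm)
        r_cm = 9.5e-7
        atoms = (2.0 / 3.0) * math.pi * r_cm**3 * 19.3 / 196.97 * 6.02214076e23
        expected = 1.9 * 1.602176634e-19 * atoms * 1e10
        got = stripping_charge_forward(9.5, 1e10)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(3.2e-4, rel=0.01)

    def test_cubic_scaling(self):
        assert stripping_charge_forward(20.0, 1e9) == pytest.approx(
            8 * stripping_charge_forward(10.0, 1e9), rel=1e-12
        )


class TestCoverage:
    def test_zero_particles(self):
        assert coverage(10.0, 0.0, 3.0) == 0.0

    def test_half_disc_by_construction(self):
        r_nm = 10.0
        a_geom = geometric_area_cm2(3.0)
        n = 0.5 * a_geom / (math.pi * (r_nm * 1e-7) ** 2)
        assert coverage(r_nm, n, 3.0) == pytest.approx(50.0, rel=1e-12)

    def test_table_scale(self):
        # d = 19 nm, 9.2e9 particles on a 3-mm disc -> about 37%
        assert coverage(9.5, 9.2e9, 3.0) == pytest.approx(37.0, abs=1.0)

    def test_over_100_percent_flagged_not_raised(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            cov = coverage(50.0, 1e12, 3.0)
        assert cov > 100.0
        assert any("100" in r.message for r in caplog.records)


class TestHemisphereArea:
    def test_worked_14nm(self):
        a = hemisphere_area(14.0)
        assert a == pytest.approx(2 * math.pi * 49.0, rel=1e-14)
        assert a == pytest.approx(307.9, abs=0.05)

    def test_zero(self):
        assert hemisphere_area(0.0) == 0.0

    def test_2nm(self):
        assert hemisphere_area(2.0) == pytest.approx(2 * math.pi, rel=1e-14)


class TestEnzymePacking:
    def test_short_side_round(self):
        assert enzyme_packing(hemisphere_area(14.0), 21.0, "round") == 15

    def test_long_side_floor(self):
        assert enzyme_packing(hemisphere_area(14.0), 67.0, "floor") == 4

    def test_zero_area(self):
        assert enzyme_packing(0.0, 21.0, "round") == 0

    def test_bad_footprint(self):
        with pytest.raises(ValueError):
            enzyme_packing(100.0, 0.0)

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            enzyme_packing(100.0, 21.0, "ceil")


class TestEstimateNP:
    def test_internal_consistency_invariant(self):
        est = estimate_np(3.2e-4, 2.5e-5)
        r_cm = est.r * 1e-7
        assert est.s_total == pytest.approx(est.x * math.pi * r_cm**2 * est.n_np, rel=1e-10)
        assert est.d == 2 * est.r

    def test_inconsistent_estimate_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            NPEstimate(r=10.0, n_np=1e9, s_total=1.0, coverage=10.0,
                       a_geom=0.07, q_strip=1e-4, q_ox=1e-5)

    def test_coverage_invariant_under_r_n_tradeoff(self):
        # r -> r/sqrt(k), n -> k*n keeps projected area fixed
        k = 4.0
        c1 = coverage(10.0, 1e10, 3.0)
        c2 = coverage(10.0 / math.sqrt(k), k * 1e10, 3.0)
        assert c2 == pytest.approx(c1, rel=1e-12)


@settings(max_examples=200, deadline=None)
@given(
    r=st.floats(min_value=1.0, max_value=100.0),
    n=st.floats(min_value=1e6, max_value=1e12),
    x=st.sampled_from([2.0, 3.0]),
)
def test_forward_inverse_identity_property(r, n, x):
    c = StrippingConstants(x=x)
    q = stripping_charge_forward(r, n, c)
    s = oxide_charge_forward(r, n, c) / c.k_ox
    r_hat = radius_from_charges(q, s, c)
    n_hat = count_from_area(s, r_hat, c)
    assert r_hat == pytest.approx(r, rel=1e-10)
    assert n_hat == pytest.approx(n, rel=1e-10)


@settings(max_examples=100, deadline=None)
@given(r=st.floats(min_value=1.0, max_value=100.0), n=st.floats(min_value=1e6, max_value=1e12))
def test_charge_ratio_is_r_linear_and_count_free(r, n):
    q = stripping_charge_forward(r, n)
    s = oxide_charge_forward(r, n) / C.k_ox
    ratio = q / s
    q2 = stripping_charge_forward(r, 7.3 * n)
    s2 = oxide_charge_forward(r, 7.3 * n) / C.k_ox
    assert q2 / s2 == pytest.approx(ratio, rel=1e-10)


def test_unit_audit_definitional_chain():
    """With defaults: q in C, s in cm^2, r in nm — checked on exact anchors."""
    s = area_from_oxide_charge(489e-6)  # 489 uC -> exactly 1 cm^2
    assert s == pytest.approx(1.0)
    ratio = (C.n_eff * C.e * C.rho_au * C.n_a) / (3.0 * C.m_au) * 1e-7
    assert radius_from_charges(ratio * s, s) == pytest.approx(1.0, rel=1e-12)  # 1 nm
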