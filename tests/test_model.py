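"""Feedback functions, calibration, and right-hand sides of all variants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpaxis import (
    DomainError,
    HPAState,
    IDENTITY,
    InterventionVector,
    ModelParams,
    TumorParams,
    calibrate_baseline,
    gr_response,
    mr_response,
    rhs_adrenal_adenoma,
    rhs_fixed_gland,
    rhs_intact,
    rhs_pituitary_adenoma,
)

ONES = np.ones(5)


class TestFeedbackFunctions:
    @pytest.mark.parametrize(
        "y, expected",
        [
            (4.0, 0.5),  # half-activation at y = KGR
            (1.0, 64 / 65),
            (1e-9, 1.0),
        ],
    )
    def test_gr_values(self, y, expected):
        assert gr_response(y, KGR=4.0, n=3) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("y, expected", [(1.0, 1.0), (2.0, 0.5), (0.25, 4.0)])
    def test_mr_values(self, y, expected):
        assert mr_response(y) == expected

    @pytest.mark.parametrize("fn", [gr_response, mr_response])
    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_signal_rejected(self, fn, bad):
        with pytest.raises(DomainError):
            fn(bad)

    @given(st.floats(min_value=0.01, max_value=100.0), st.floats(min_value=0.011, max_value=101.0))
    @settings(max_examples=50, derandomize=True)
    def test_gr_strictly_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        if lo < hi:
            assert gr_response(hi) < gr_response(lo)


class TestCalibration:
    def test_production_rates(self, params):
        # b3 = a3; b1 = a1/GR(1) with GR(1) = 64/65; gland gains equal removals
        assert params.b3 == pytest.approx(12.384)
        assert params.b1 == pytest.approx(244.8 * 65 / 64)
        assert params.b2 == pytest.approx(50.4 * 65 / 64)
        assert params.bP == params.aP
        assert params.bA == params.aA

    def test_day_unit_conversion(self, params):
        assert params.a1 == pytest.approx(244.8)
        assert params.a2 == pytest.approx(50.4)
        assert params.a3 == pytest.approx(12.384)

    def test_all_ones_is_exact_fixed_point(self, params):
        d = rhs_intact(0.0, ONES, params)
        assert np.max(np.abs(d)) < 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(b1=-1.0, b2=1.0, b3=1.0)
        with pytest.raises(ValueError):
            calibrate_baseline(KGR=-4.0)


class TestIntactRhs:
    def test_doubled_input_drives_only_crh(self, params):
        d = rhs_intact(0.0, ONES, params, IDENTITY, u=2.0)
        # production doubles while removal is at baseline: net +a1
        assert d[0] == pytest.approx(params.a1)
        assert d[1:] == pytest.approx(np.zeros(4), abs=1e-12)

    def test_gr_antagonist_relieves_feedback(self, params):
        iv = InterventionVector(C3=0.5)
        d = rhs_intact(0.0, ONES, params, iv, u=1.0)
        assert d[0] > 0  # GR(0.5)*MR(0.5) > GR(1)*MR(1)

    def test_intervention_placement(self, params):
        # C1 scales x1 in the ACTH and corticotroph-growth equations only
        d = rhs_intact(0.0, ONES, params, InterventionVector(C1=0.5))
        assert d[0] == pytest.approx(0.0, abs=1e-12)
        assert d[1] < 0 and d[3] < 0
        assert d[2] == pytest.approx(0.0, abs=1e-12) and d[4] == pytest.approx(0.0, abs=1e-12)
        # C2 scales x2 in the cortisol and adrenal-growth equations only
        d = rhs_intact(0.0, ONES, params, InterventionVector(C2=0.5))
        assert d[2] < 0 and d[4] < 0
        assert d[0] == pytest.approx(0.0, abs=1e-12) and d[1] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_cortisol_rejected(self, params):
        y = ONES.copy()
        y[2] = 0.0
        with pytest.raises(DomainError):
            rhs_intact(0.0, y, params)


class TestFixedGlandRhs:
    def test_fixed_point_shared(self, params):
        assert np.max(np.abs(rhs_fixed_gland(0.0, ONES, params))) < 1e-12

    def test_gland_derivatives_always_zero(self, params):
        y = np.array([2.0, 0.5, 3.0, 4.0, 0.2])
        d = rhs_fixed_gland(0.0, y, params)
        assert d[3] == 0.0 and d[4] == 0.0

    def test_cortisol_inhibitor_direct_effect(self, params):
        d = rhs_fixed_gland(0.0, ONES, params, InterventionVector(I3=0.5))
        assert d[2] == pytest.approx(-params.a3 / 2)


class TestTumorVariants:
    def test_null_pituitary_tumor_matches_intact(self, params):
        tum = TumorParams("pituitary", T_max=0.0, K_A=1e12)
        y = np.array([1.3, 0.8, 2.1, 0.9, 1.4])
        np.testing.assert_allclose(
            rhs_pituitary_adenoma(0.0, y, params, tumor=tum),
            rhs_intact(0.0, y, params),
            rtol=1e-9,
        )

    def test_null_adrenal_tumor_matches_intact(self, params):
        tum = TumorParams("adrenal", T_max=0.0)
        y = np.array([1.3, 0.8, 2.1, 0.9, 1.4])
        np.testing.assert_allclose(
            rhs_adrenal_adenoma(0.0, y, params, tumor=tum),
            rhs_intact(0.0, y, params),
            rtol=1e-12,
        )

    def test_pituitary_tumor_adds_acth_secretion(self, params):
        tum = TumorParams("pituitary", T_max=0.1 * params.a2, r=1.0, t0=-1e4, K_A=1e12)
        d = rhs_pituitary_adenoma(0.0, ONES, params, tumor=tum)
        assert d[1] == pytest.approx(0.1 * params.a2, rel=1e-6)

    def test_adrenal_capacity_saturation(self, params):
        KA = 10.0
        tum = TumorParams("pituitary", T_max=0.0, K_A=KA)
        y = np.array([1.0, 1.0, 1.0, 1.0, KA])
        d = rhs_pituitary_adenoma(0.0, y, params, tumor=tum)
        assert d[4] == pytest.approx(-params.aA * KA)

    def test_adrenal_tumor_adds_cortisol_secretion(self, params):
        tum = TumorParams("adrenal", T_max=0.5 * params.a3, r=1.0, t0=-1e4)
        d = rhs_adrenal_adenoma(0.0, ONES, params, tumor=tum)
        assert d[2] == pytest.approx(0.5 * params.a3, rel=1e-6)

    def test_synthesis_inhibitor_scales_tumor_too(self, params):
        tum = TumorParams("adrenal", T_max=0.5 * params.a3, r=1.0, t0=-1e4)
        iv = InterventionVector(I3=0.5)
        d = rhs_adrenal_adenoma(0.0, ONES, params, iv, 1.0, tum)
        # gland term: 0.5*a3 - a3; tumor term: 0.5*0.5*a3
        assert d[2] == pytest.approx(-0.5 * params.a3 + 0.25 * params.a3, rel=1e-6)

    def test_wrong_site_rejected(self, params):
        tum = TumorParams("adrenal", T_max=1.0)
        with pytest.raises(ValueError):
            rhs_pituitary_adenoma(0.0, ONES, params, tumor=tum)
        with pytest.raises(ValueError):
            rhs_adrenal_adenoma(0.0, ONES, params, tumor=TumorParams("pituitary", T_max=1.0))


class TestTypes:
    def test_state_invariants(self):
        with pytest.raises(ValueError):
            HPAState(x3=0.0)
        with pytest.raises(ValueError):
            HPAState(P=-0.1)
        HPAState(P=0.0, A=0.0)  # gland masses may vanish

    def test_intervention_identity_and_composition(self):
        a = InterventionVector(I1=0.5)
        b = InterventionVector(A1=2.0)
        ab = a.compose(b)
        assert ab.I1 == 0.5 and ab.A1 == 2.0
        assert IDENTITY.is_identity()
        with pytest.raises(ValueError):
            InterventionVector(C3=0.0)

    def test_tumor_validation(self):
        with pytest.raises(ValueError):
            TumorParams("liver", T_max=1.0)
        with pytest.raises(ValueError):
            TumorParams("adrenal", T_max=1.0, r=0.0)
        with pytest.raises(ValueError):
            TumorParams("adrenal", T_max=1.0, K_A=0.5)
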