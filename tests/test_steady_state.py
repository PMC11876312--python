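"""Closed forms, the full-Hill solver, tumor branches and thresholds.

Frozen expected values were computed with an independent scalar
implementation of the steady-state balances (bisection on the cortisol
equation), not with the module under test.
"""

import numpy as np
import pytest

from hpaxis import (
    IDENTITY,
    InterventionVector,
    TumorParams,
    adrenal_states,
    adrenal_threshold,
    classify_regime,
    closed_form_fixed_gland,
    closed_form_linear,
    closed_form_saturated,
    pituitary_states,
    pituitary_threshold,
    solve_fixed_gland_steady_state,
    solve_full_steady_state,
)
from conftest import random_intervention

# independent-oracle values: root of x3*(1+(x3/4)^3) = u*(65/64) etc.
X3_U2 = 1.8487289392
P_U2 = 1.0818243592
X3_FIXED_U2 = 1.3796932200


class TestFullSolver:
    def test_baseline_is_all_ones(self, params):
        s = solve_full_steady_state(params)
        np.testing.assert_allclose(s.as_array(), np.ones(5), atol=1e-12)
        assert s.residual < 1e-10

    def test_chronic_stress_u2(self, params):
        s = solve_full_steady_state(params, IDENTITY, u=2.0)
        assert s.x1 == pytest.approx(1.0)
        assert s.x2 == pytest.approx(1.0)
        assert s.x3 == pytest.approx(X3_U2, rel=1e-8)
        assert s.P == pytest.approx(P_U2, rel=1e-8)
        assert s.A == pytest.approx(X3_U2, rel=1e-8)
        assert s.residual < 1e-10

    def test_gr_antagonist_change_of_variables(self, params):
        # C3 = 0.5: measured cortisol doubles, net signal and P unchanged,
        # adrenal mass doubles to produce the extra cortisol
        s = solve_full_steady_state(params, InterventionVector(C3=0.5), u=1.0)
        assert s.x3 == pytest.approx(2.0, rel=1e-10)
        assert s.net_gr_signal == pytest.approx(1.0, rel=1e-10)
        assert s.P == pytest.approx(1.0, rel=1e-10)
        assert s.A == pytest.approx(2.0, rel=1e-10)

    def test_robustness_of_net_signal(self, params):
        """Net GR signal is invariant to every ACTH/cortisol-side parameter."""
        ref = solve_full_steady_state(params, IDENTITY, u=2.0).net_gr_signal
        perturbations = [
            InterventionVector(I2=0.3),
            InterventionVector(I3=3.0),
            InterventionVector(A2=5.0),
            InterventionVector(A3=0.4),
            InterventionVector(C2=0.2),
            InterventionVector(C3=4.0),
            InterventionVector(I2=0.5, A3=2.0, C3=0.25),
        ]
        for iv in perturbations:
            s = solve_full_steady_state(params, iv, u=2.0)
            assert s.net_gr_signal == pytest.approx(ref, rel=1e-10)
        # downstream rates b2, b3, a2, a3 do not enter either
        p2 = type(params)(**{**params.to_dict(), "b2": params.b2 * 3, "a3": params.a3 * 0.2})
        s = solve_full_steady_state(p2, IDENTITY, u=2.0)
        assert s.net_gr_signal == pytest.approx(ref, rel=1e-10)

    def test_exact_adaptation_of_upstream_hormones(self, params):
        for u in (0.5, 1.0, 3.0, 20.0):
            s = solve_full_steady_state(params, IDENTITY, u)
            assert s.x1 == pytest.approx(1.0, rel=1e-12)
            assert s.x2 == pytest.approx(1.0, rel=1e-12)

    def test_random_draw_residuals(self, params):
        rng = np.random.default_rng(7)
        for _ in range(25):
            iv = random_intervention(rng)
            u = float(rng.uniform(0.5, 5.0))
            s = solve_full_steady_state(params, iv, u)
            assert s.residual < 1e-8
            assert np.all(s.as_array() > 0)


class TestClosedForms:
    def test_saturated_fourth_root_scaling(self, params):
        a = closed_form_saturated(params, IDENTITY, u=100.0)
        b = closed_form_saturated(params, IDENTITY, u=200.0)
        assert b.x3 / a.x3 == pytest.approx(2 ** 0.25, rel=1e-12)
        assert b.P / a.P == pytest.approx(2 ** 0.75, rel=1e-12)

    def test_saturated_independent_of_downstream(self, params):
        ref = closed_form_saturated(params, IDENTITY, u=100.0).x3
        iv = InterventionVector(I2=0.3, I3=2.0, A2=4.0, A3=0.5, C2=0.1)
        assert closed_form_saturated(params, iv, u=100.0).x3 == pytest.approx(ref, rel=1e-12)

    def test_saturated_matches_full_solver_when_valid(self, params):
        # <5% agreement once cortisol is well past the GR knee (x3 >= 4*KGR)
        for u in (2e4, 2e5):
            full = solve_full_steady_state(params, IDENTITY, u)
            approx = closed_form_saturated(params, IDENTITY, u)
            assert full.x3 >= 4 * params.KGR
            assert approx.valid
            assert approx.x3 == pytest.approx(full.x3, rel=0.05)

    @pytest.mark.parametrize(
        "iv, expected_x3",
        [
            (InterventionVector(I1=0.5), 1.0),   # halved synthesis cancels doubled input
            (InterventionVector(A1=2.0), 1.0),   # doubled removal cancels doubled input
        ],
    )
    def test_linear_normalizing_interventions(self, params, iv, expected_x3):
        s = closed_form_linear(params, iv, u=2.0)
        assert s.x3 * 64 / 65 == pytest.approx(expected_x3, rel=1e-12)

    def test_linear_crh_antagonist_raises_crh(self, params):
        s = closed_form_linear(params, InterventionVector(C1=0.5), u=1.0)
        assert s.x1 == pytest.approx(2.0, rel=1e-12)

    def test_linear_matches_full_solver_when_valid(self, params):
        # <2% agreement deep in the linear regime (x3 <= KGR/4)
        for u in (0.3, 0.8):
            full = solve_full_steady_state(params, IDENTITY, u)
            approx = closed_form_linear(params, IDENTITY, u)
            assert full.x3 <= params.KGR / 4
            assert approx.x3 == pytest.approx(full.x3, rel=0.02)


class TestFixedGland:
    def test_numeric_solver_u2(self, params):
        s = solve_fixed_gland_steady_state(params, IDENTITY, u=2.0)
        assert s.x3 == pytest.approx(X3_FIXED_U2, rel=1e-8)
        assert s.x3 < X3_U2  # weaker response than the adaptive-gland model
        assert s.x2 > 1.0    # ACTH stays elevated without adrenal growth
        assert s.residual < 1e-10

    def test_eighth_root_scaling(self, params):
        a = closed_form_fixed_gland(params, IDENTITY, u=1e6)
        b = closed_form_fixed_gland(params, IDENTITY, u=2e6)
        assert b.x3 / a.x3 == pytest.approx(2 ** 0.125, rel=1e-12)

    def test_cortisol_inhibitor_has_an_effect(self, params):
        a = closed_form_fixed_gland(params, IDENTITY, u=1e6)
        b = closed_form_fixed_gland(params, InterventionVector(I3=0.5), u=1e6)
        assert b.x3 / a.x3 == pytest.approx(0.5 ** 0.125, rel=1e-12)

    def test_every_intervention_moves_cortisol(self, params):
        """Without gland adaptation all nine drug parameters shift cortisol."""
        ref = closed_form_fixed_gland(params, IDENTITY, u=1e6).x3
        for name in ("I1", "I2", "I3", "A1", "A2", "A3", "C1", "C2", "C3"):
            iv = InterventionVector(**{name: 0.5})
            assert closed_form_fixed_gland(params, iv, u=1e6).x3 != pytest.approx(ref, rel=1e-6)

    def test_closed_form_matches_numeric_at_saturation(self, params):
        full = solve_fixed_gland_steady_state(params, IDENTITY, u=1e8)
        approx = closed_form_fixed_gland(params, IDENTITY, u=1e8)
        assert approx.x3 == pytest.approx(full.x3, rel=0.05)


class TestThresholds:
    def test_pituitary_threshold_baseline(self, params):
        assert pituitary_threshold(params) == pytest.approx(params.a2)

    def test_acth_drugs_raise_pituitary_threshold(self, params):
        base = pituitary_threshold(params)
        assert pituitary_threshold(params, InterventionVector(I2=0.5)) == pytest.approx(2 * base)
        assert pituitary_threshold(params, InterventionVector(A2=2.0)) == pytest.approx(2 * base)
        assert pituitary_threshold(params, InterventionVector(C2=0.5)) == pytest.approx(2 * base)

    def test_adrenal_threshold_baseline(self, params):
        assert adrenal_threshold(params) == pytest.approx(params.a3 * 65 / 64)

    def test_cortisol_drugs_raise_adrenal_threshold(self, params):
        base = adrenal_threshold(params)
        assert adrenal_threshold(params, InterventionVector(I3=0.5)) == pytest.approx(2 * base)
        assert adrenal_threshold(params, InterventionVector(A3=2.0)) == pytest.approx(2 * base)
        assert adrenal_threshold(params, InterventionVector(C3=0.5)) == pytest.approx(2 * base)


class TestPituitaryBranches:
    def test_null_tumor_recovers_intact_state(self, params):
        tum = TumorParams("pituitary", T_max=0.0)
        sub, clin = pituitary_states(params, u=1.0, tumor=tum)
        np.testing.assert_allclose(sub.as_array(), closed_form_linear(params).as_array(), rtol=1e-12)
        assert sub.valid and not clin.valid

    def test_corticotroph_mass_shrinks_linearly(self, params):
        thr = pituitary_threshold(params)
        tum = TumorParams("pituitary", T_max=0.5 * thr)
        sub, _ = pituitary_states(params, u=1.0, tumor=tum)
        sub0, _ = pituitary_states(params, u=1.0, tumor=TumorParams("pituitary", T_max=1e-30))
        assert sub.P == pytest.approx(0.5 * sub0.P, rel=1e-9)
        assert sub.x3 == pytest.approx(sub0.x3, rel=1e-12)

    def test_branches_meet_at_threshold(self, params):
        thr = pituitary_threshold(params)
        tum = TumorParams("pituitary", T_max=thr)
        sub, clin = pituitary_states(params, u=1.0, tumor=tum)
        assert sub.P == pytest.approx(0.0, abs=1e-9)
        assert clin.x3 == pytest.approx(0.0, abs=1e-9)

    def test_clinical_values_at_twice_threshold(self, params):
        thr = pituitary_threshold(params)
        KA = 10.0
        tum = TumorParams("pituitary", T_max=2 * thr, K_A=KA)
        _, clin = pituitary_states(params, u=1.0, tumor=tum)
        assert clin.valid
        assert clin.x2 == pytest.approx(2.0, rel=1e-12)
        assert clin.x3 == pytest.approx(KA, rel=1e-12)
        assert clin.A == pytest.approx(KA / 2, rel=1e-12)
        assert clin.P == 0.0


class TestAdrenalBranches:
    def test_null_tumor(self, params):
        tum = TumorParams("adrenal", T_max=0.0)
        b1, b2, thr = adrenal_states(params, u=1.0, tumor=tum)
        assert b1.valid and not b2.valid
        assert thr == pytest.approx(adrenal_threshold(params))

    def test_clinical_cortisol_scales_with_inhibitor(self, params):
        thr = adrenal_threshold(params)
        tum = TumorParams("adrenal", T_max=4 * thr)
        _, c_ref, _ = adrenal_states(params, u=1.0, tumor=tum)
        _, c_inh, _ = adrenal_states(params, InterventionVector(I3=0.5), u=1.0, tumor=tum)
        assert c_ref.valid
        assert c_inh.x3 == pytest.approx(0.5 * c_ref.x3, rel=1e-12)

    def test_branch_stability_flips_at_threshold(self, params):
        thr = adrenal_threshold(params)
        below = TumorParams("adrenal", T_max=0.9 * thr)
        above = TumorParams("adrenal", T_max=1.1 * thr)
        b1, b2, _ = adrenal_states(params, u=1.0, tumor=below)
        assert b1.valid and not b2.valid
        b1, b2, _ = adrenal_states(params, u=1.0, tumor=above)
        assert not b1.valid and b2.valid

    def test_branch_stability_matches_jacobian(self, params):
        """Analytic stability labels agree with numerical Jacobian eigenvalues."""
        from hpaxis import rhs_adrenal_adenoma

        thr = adrenal_threshold(params)
        tum = TumorParams("adrenal", T_max=0.5 * thr)
        b1, _, _ = adrenal_states(params, u=1.0, tumor=tum)
        y0 = b1.as_array()

        def jac(y):
            eps = 1e-7
            J = np.zeros((5, 5))
            f0 = rhs_adrenal_adenoma(1e9, y, params, tumor=tum)
            for k in range(5):
                yp = y.copy()
                yp[k] += eps * max(abs(y[k]), 1e-3)
                J[:, k] = (rhs_adrenal_adenoma(1e9, yp, params, tumor=tum) - f0) / (
                    eps * max(abs(y[k]), 1e-3)
                )
            return J

        eig = np.linalg.eigvals(jac(y0))
        assert np.all(eig.real < 1e-6)  # compensated branch is stable below threshold


class TestRegimeClassifier:
    @pytest.mark.parametrize(
        "x3, expected", [(1.0, "linear"), (9.0, "saturated"), (4.0, "intermediate")]
    )
    def test_bands(self, x3, expected):
        assert classify_regime(x3, KGR=4.0) == expected
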