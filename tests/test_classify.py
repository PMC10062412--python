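"""Tests for thresholds, supports, and the regime decision tree."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from virodyn import (NondimParams, bifurcation_roots, boundary_exponents,
                     classify_regime, in_domain, infection_value,
                     lyapunov_parameters, stochastic_clearance_rates,
                     support_segment)

positive = st.floats(min_value=1e-2, max_value=30.0,
                     allow_nan=False, allow_infinity=False)


def params(**kw) -> NondimParams:
    base = dict(r=0.36, a=5.0, l1=0.48, l2=0.48, e1=10.0, e2=10.0,
                d1=0.4, d2=0.4, tau1=0.01, tau2=0.01)
    base.update(kw)
    return NondimParams(**base)


class TestThresholds:
    def test_infection_value_vanishes_at_unit_infectivity(self):
        assert infection_value(params(a=1.0)) == 0.0

    def test_infection_value_worked_example(self, baseline):
        assert infection_value(baseline) == pytest.approx(1.44 / 26.8,
                                                          rel=1e-14)

    @given(r=positive, a=positive)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_infection_value_below_one(self, r, a):
        assert infection_value(params(r=r, a=a)) < 1.0

    def test_clearance_rates(self, baseline):
        h1, h2 = stochastic_clearance_rates(baseline)
        assert h1 == pytest.approx(0.040005, rel=1e-12)
        assert round(h1, 2) == 0.04
        assert h2 == h1
        # noise-free limit and pure-noise term
        assert stochastic_clearance_rates(
            params(tau1=0.0, tau2=0.0))[0] == pytest.approx(0.04)
        h1, _ = stochastic_clearance_rates(
            params(d1=1e-300, e1=1.0, tau1=2.0))
        assert h1 == pytest.approx(2.0)

    def test_lyapunov_parameters(self, baseline):
        lam1, lam2, lam = lyapunov_parameters(baseline)
        assert lam is not None
        assert round(lam, 4) == 0.0137
        assert lam1 == pytest.approx(baseline.e1 * lam, rel=1e-12)
        # asymmetric h's: no combined lambda
        _, _, lam = lyapunov_parameters(params(d2=0.5))
        assert lam is None
        # threshold case lambda1 = 0: pick d1 so h1 = theta
        theta = infection_value(baseline)
        p = params(d1=10 * theta - 0.01 ** 2 / 2)
        lam1, _, _ = lyapunov_parameters(p)
        assert lam1 == pytest.approx(0.0, abs=1e-15)


class TestBifurcationRoots:
    def test_worked_example_printed_values(self, baseline):
        roots = bifurcation_roots(baseline)
        assert roots.exists
        assert round(roots.a1, 4) == 1.2116
        assert round(roots.a2, 4) == 7.4273
        assert round(roots.discriminant_margin, 4) == 0.1864
        assert 1.0 < roots.a1 < roots.a2

    def test_residuals_and_numeric_root_oracle(self, baseline):
        roots = bifurcation_roots(baseline)
        assert abs(roots.m(roots.a1)) < 1e-9
        assert abs(roots.m(roots.a2)) < 1e-9
        h, r = roots.h, baseline.r
        numeric = np.sort(np.roots([1.0, r * (1 - 1 / h), r / h]))
        assert roots.a1 == pytest.approx(numeric[0], abs=1e-10)
        assert roots.a2 == pytest.approx(numeric[1], abs=1e-10)

    def test_no_window_cases(self):
        # h >= 1: no roots, no error
        assert not bifurcation_roots(params(d1=20.0, d2=20.0, e1=10.0,
                                            e2=10.0)).exists
        # h < 1 but discriminant condition fails
        p = params(r=0.01, d1=0.4, d2=0.4)
        roots = bifurcation_roots(p)
        assert not roots.exists and roots.discriminant_margin < 0

    def test_asymmetric_clearance_refused(self):
        with pytest.raises(ValueError, match="h1 == h2"):
            bifurcation_roots(params(d2=0.6))

    def test_lambda_sign_characterization(self, baseline):
        # lambda(a) > 0 exactly on (a1, a2), over a dense grid
        roots = bifurcation_roots(baseline)
        h = roots.h
        for a in np.linspace(0.5, 10.0, 400):
            lam = infection_value(params(a=a)) - h
            inside = roots.a1 < a < roots.a2
            if abs(a - roots.a1) > 1e-6 and abs(a - roots.a2) > 1e-6:
                assert (lam > 0) == inside


class TestSupports:
    def test_s1_endpoint_algebra(self, baseline):
        s1 = support_segment(baseline, "S1")
        a, l1 = baseline.a, baseline.l1
        y1 = infection_value(baseline)
        assert s1.hi == pytest.approx((a - 1) / l1)
        lo_pt = s1.param_map(0.0)
        assert lo_pt == pytest.approx([1 / a, y1, 0.0, 0.0])
        hi_pt = s1.param_map(s1.hi)
        assert hi_pt == pytest.approx([1.0, 0.0, (a - 1) / l1, 0.0])

    def test_sk_interval_and_linear_leaf(self, baseline):
        sk = support_segment(baseline, "Sk", k=2.0)
        assert (sk.lo, sk.hi) == (0.0, pytest.approx(4 / 0.48))
        assert sk.hi == pytest.approx(8.3333, abs=1e-4)
        # rho = 1 here, so z2 = k z1 exactly along the segment
        pts = sk.sample(64)
        assert pts[:, 3] == pytest.approx(2.0 * pts[:, 2], rel=1e-14)

    def test_sk_y_positivity_matches_closed_condition(self, baseline):
        # y > 0 along the segment iff l1 z1 + k a l2 z1^rho / r < a - 1
        a, r, l1, l2, rho = (baseline.a, baseline.r, baseline.l1,
                             baseline.l2, baseline.rho)
        for k in (0.1, 1.0, 5.0):
            sk = support_segment(baseline, "Sk", k=k)
            z1s = np.linspace(1e-6, sk.hi - 1e-6, 2000)
            ys = np.array([sk.param_map(z)[1] for z in z1s])
            cond = l1 * z1s + k * a * l2 * z1s ** rho / r < a - 1
            assert np.array_equal(ys > 0, cond)

    def test_canonical_y_forms_agree(self, baseline):
        # factored and expanded forms of the S(0)=S1 y-coordinate
        a, r, l1 = baseline.a, baseline.r, baseline.l1
        y1 = infection_value(baseline)
        s1 = support_segment(baseline, "S1")
        for z1 in np.linspace(0, s1.hi, 50):
            factored = r * (a - 1 - l1 * z1) / (a * (a + r))
            expanded = y1 - r * l1 * z1 / (a * (a + r))
            assert factored == pytest.approx(expanded, abs=1e-15)

    @pytest.mark.parametrize("which,k", [("S1", None), ("S2", None),
                                         ("Sk", 0.5), ("Sk", 3.0)])
    def test_sampled_supports_lie_in_domain(self, baseline, which, k):
        supp = support_segment(baseline, which, k=k)
        for pt in supp.sample(512):
            assert in_domain(pt, tol=1e-12)

    def test_subcritical_infectivity_refused(self):
        with pytest.raises(ValueError, match="a > 1"):
            support_segment(params(a=0.5), "S1")


class TestBoundaryExponents:
    def test_catalogue(self, baseline):
        exps = boundary_exponents(baseline)
        lam1, _, _ = lyapunov_parameters(baseline)
        # x-exponent at the origin measure is the tumor growth rate r
        assert exps["mu0"][0] == pytest.approx(baseline.r)
        # y-exponent at the tumor-only measure is a - 1
        assert exps["mu1"][1] == pytest.approx(baseline.a - 1)
        # z1-exponent at the immune-free measure is lambda1
        assert exps["mu2"][2] == pytest.approx(lam1, rel=1e-12)
        # the immune-free point is an equilibrium of the tumor equations
        assert exps["mu2"][0] == pytest.approx(0.0, abs=1e-15)
        assert exps["mu2"][1] == pytest.approx(0.0, abs=1e-15)
        # z-exponents at origin/tumor-only: pure decay -d - tau^2/2
        assert exps["mu0"][2] == pytest.approx(-0.4 - 0.5e-4)
        assert exps["mu1"][2] == pytest.approx(-0.4 - 0.5e-4)


class TestRegimeTree:
    def test_worked_example_is_hopf_without_parameters(self, baseline):
        rep = classify_regime(baseline, k=1.0)
        assert rep.case_label == "Case3"
        assert rep.sub_regime == "hopf-without-parameters"
        assert rep.attractor == "{pi(k)}"
        assert rep.support is not None and rep.support.k == 1.0
        assert round(rep.lam, 4) == 0.0137

    def test_complete_failure(self):
        rep = classify_regime(params(a=0.5, d2=0.6))
        assert rep.sub_regime == "complete-failure"
        assert rep.support.point == pytest.approx([1, 0, 0, 0])

    def test_case1_immune_free(self):
        # h1 = 0.2 > theta ~ 0.0537, h2 = 0.3: Case 1, lambda1 < 0
        p = params(d1=2.0 - 0.01 ** 2 / 2, d2=3.0 - 0.01 ** 2 / 2)
        rep = classify_regime(p)
        assert rep.case_label == "Case1"
        assert rep.h1 == pytest.approx(0.2) and rep.h2 == pytest.approx(0.3)
        assert rep.lambda1 < 0
        assert rep.sub_regime == "immune-free"
        theta = infection_value(p)
        assert rep.support.point == pytest.approx([0.2, theta, 0, 0])

    def test_case1_case2_persistence_supports(self):
        rep1 = classify_regime(params(d2=0.6))
        assert (rep1.case_label, rep1.sub_regime) == ("Case1",
                                                      "persistent-innate")
        assert rep1.support.label == "S1"
        rep2 = classify_regime(params(d1=0.6))
        assert (rep2.case_label, rep2.sub_regime) == ("Case2",
                                                      "persistent-adaptive")
        assert rep2.support.label == "S2"

    def test_case3_extinction_to_immune_free(self):
        rep = classify_regime(params(d1=0.7, d2=0.7))
        assert rep.case_label == "Case3"
        assert rep.sub_regime == "extinction-to-immune-free"
        assert rep.lam < 0

    def test_critical_outcomes_are_explicit(self, baseline):
        rep = classify_regime(params(a=1.0, d2=0.6))
        assert rep.sub_regime == "critical"
        assert "not classified" in rep.attractor
        # exponent exactly zero: h1 = theta (Case 1 via larger h2)
        theta = infection_value(baseline)
        p = params(d1=10 * theta - 0.01 ** 2 / 2, d2=1.0)
        rep = classify_regime(p)
        assert abs(rep.lambda1) < 1e-12
        assert rep.sub_regime == "critical"

    @given(r=positive, a=positive, l1=positive, l2=positive,
           d1=positive, d2=positive)
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_swap_symmetry(self, r, a, l1, l2, d1, d2):
        p = NondimParams(r=r, a=a, l1=l1, l2=l2, e1=3.0, e2=7.0,
                         d1=d1, d2=d2, tau1=0.1, tau2=0.3)
        rep = classify_regime(p)
        rep_sw = classify_regime(p.swapped())
        case_map = {"Case1": "Case2", "Case2": "Case1", "Case3": "Case3"}
        sub_map = {"persistent-innate": "persistent-adaptive",
                   "persistent-adaptive": "persistent-innate"}
        assert rep_sw.case_label == case_map[rep.case_label]
        assert rep_sw.sub_regime == sub_map.get(rep.sub_regime,
                                                rep.sub_regime)
        assert rep_sw.h1 == pytest.approx(rep.h2)
        assert rep_sw.lambda1 == pytest.approx(rep.lambda2)
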