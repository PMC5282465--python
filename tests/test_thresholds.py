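"""Threshold arithmetic, theorem conditions, and their structural properties."""

import numpy as np
import pytest

from stochsirs import (
    ModelParams,
    check_extinction_thm9,
    compute_R0_det,
    compute_Rbar0,
    compute_Rtilde0,
    compute_S0,
    compute_S1,
    compute_Sbar,
    compute_threshold_report,
    make_builtin_incidence,
    permanence_bound_thm14,
    permanence_bound_thm15,
    persistence_bound_thm12,
)

from conftest import random_incidence, random_valid_params


def _params(**over):
    kw = dict(Lambda=1.0, q=0.0, p=0.0, epsilon=0.0, gamma=0.0, beta=0.5,
              dS=0.3, dI=0.3, dR=0.3, sigma=np.zeros((4, 1)))
    kw.update(over)
    return ModelParams(**kw)


class TestClosedForms:
    def test_S0_example_values(self, examples):
        # hand arithmetic: 1.85*0.344/0.272 and 3*1.12/0.72
        assert compute_S0(examples["example1"].params) == pytest.approx(2.3397059, abs=1e-6)
        assert compute_S0(examples["example2"].params) == pytest.approx(4.6666667, abs=1e-6)

    def test_S0_no_vaccination_reduces_to_Lambda_over_dS(self):
        p = _params(Lambda=2.0, dS=0.4)
        assert compute_S0(p) == pytest.approx(5.0, abs=1e-12)

    def test_S1_example_value(self, examples):
        # (0.53*3.39 + 0.39*0.99)/1.0026
        assert compute_S1(examples["example4"].params) == pytest.approx(2.1771394, abs=1e-6)

    def test_S1_reductions(self):
        assert compute_S1(_params(dI=0.6, dS=0.3)) == pytest.approx(2.0, abs=1e-12)
        assert compute_S1(_params()) == pytest.approx(1.0, abs=1e-12)

    def test_Sbar_uses_min_removal_rate(self, examples):
        p = examples["example3"].params
        assert compute_Sbar(p) == pytest.approx(1.2 / 0.35, abs=1e-12)


class TestReproductionNumbers:
    def test_R0_published_values(self, examples):
        assert compute_R0_det(examples["example4"].params, examples["example4"].incidence) \
            == pytest.approx(2.5279, abs=5e-5)
        assert compute_R0_det(examples["example5"].params, examples["example5"].incidence) \
            == pytest.approx(1.6484, abs=5e-5)

    def test_R0_zero_transmission(self):
        assert compute_R0_det(_params(beta=0.0), make_builtin_incidence()) == 0.0

    def test_Rtilde0_published_values(self, examples):
        for name, want in (("example1", 0.8939), ("example2", 1.3554), ("example3", 1.2931)):
            fx = examples[name]
            assert compute_Rtilde0(fx.params, fx.incidence) == pytest.approx(want, abs=5e-5)

    def test_Rbar0_published_value(self, examples):
        fx = examples["example3"]
        assert compute_Rbar0(fx.params, fx.incidence) == pytest.approx(0.8687, abs=5e-5)

    def test_noise_free_thresholds_collapse_to_R0(self, rng):
        for _ in range(200):
            p = random_valid_params(rng, sigma_scale=0.0)
            inc = random_incidence(rng)
            R0 = compute_R0_det(p, inc)
            assert compute_Rtilde0(p, inc) == R0
            assert compute_Rbar0(p, inc) == R0

    def test_Rbar0_equals_Rtilde0_without_incidence_noise(self, rng):
        p = random_valid_params(rng).with_zero_rows([0])
        inc = random_incidence(rng)
        assert compute_Rbar0(p, inc) == pytest.approx(compute_Rtilde0(p, inc), abs=1e-14)

    def test_Rbar0_printed_form_specialization(self, examples):
        # with f(S)=S and removal noise off, the generalized form reduces to
        # (beta S0 - Sbar^2 sigma_0^2/2)/(dI+gamma)
        p = examples["example4"].params.with_zero_rows([1, 2, 3])
        inc = make_builtin_incidence(0.0, 4.0)
        S0, Sbar = compute_S0(p), compute_Sbar(p)
        want = (p.beta * S0 - 0.5 * Sbar**2 * p.sigma_i_sq(0)) / (p.dI + p.gamma)
        assert compute_Rbar0(p, inc) == pytest.approx(want, rel=1e-12)

    def test_ordering_Rbar_le_Rtilde(self, rng):
        for _ in range(1000):
            p = random_valid_params(rng)
            inc = random_incidence(rng)
            assert compute_Rbar0(p, inc) <= compute_Rtilde0(p, inc) + 1e-12

    def test_Rtilde0_monotone_in_noise_and_transmission(self, examples):
        fx = examples["example2"]
        inc = fx.incidence
        sig = fx.params.sigma.copy()
        base = compute_Rtilde0(fx.params, inc)
        sig2 = sig.copy()
        sig2[2] *= 1.1  # more removal noise on I lowers the threshold
        assert compute_Rtilde0(fx.params.with_sigma(sig2), inc) < base
        import dataclasses
        stronger = dataclasses.replace(fx.params, beta=fx.params.beta * 1.05)
        small = fx.params.with_sigma(sig * 0.1)
        stronger_small = stronger.with_sigma(sig * 0.1)
        assert compute_Rtilde0(stronger_small, inc) > compute_Rtilde0(small, inc)


class TestExtinctionConditions:
    def test_published_condition_values(self, examples):
        fx = examples["example1"]
        rep = check_extinction_thm9(fx.params, fx.incidence)
        assert rep.condA_gap == pytest.approx(0.3442, abs=5e-5)
        assert rep.condB_value == pytest.approx(0.005, abs=5e-4)
        # both sufficient conditions fail for this parameter set
        assert not rep.condA_holds and not rep.condB_holds and not rep.extinct_predicted
        assert rep.Rtilde0 < 1

    def test_deterministic_subthreshold_satisfies_condA(self):
        p = _params(beta=0.1, gamma=0.2)  # R0 = 0.1*(1/0.3)/0.5 < 1, no noise
        rep = check_extinction_thm9(p, make_builtin_incidence())
        assert rep.condA_holds and rep.extinct_predicted
        assert rep.condA_gap == pytest.approx(-p.beta, abs=1e-12)

    def test_condB_not_applicable_without_incidence_noise(self, examples):
        p = examples["example1"].params.with_zero_rows([0])
        rep = check_extinction_thm9(p, examples["example1"].incidence)
        assert rep.condB_value is None and not rep.condB_holds

    def test_limits_match_disease_free_state(self, examples):
        from stochsirs import disease_free_equilibrium
        fx = examples["example1"]
        rep = check_extinction_thm9(fx.params, fx.incidence)
        dfe = disease_free_equilibrium(fx.params, fx.incidence)
        assert rep.S_limit == pytest.approx(dfe.state[0], abs=1e-12)
        assert rep.R_limit == pytest.approx(dfe.state[2], abs=1e-12)

    def test_sufficient_conditions_imply_subthreshold(self, rng):
        # whenever (a) or (b) holds, the noise-corrected threshold is < 1
        hits = 0
        for _ in range(1000):
            p = random_valid_params(rng, sigma_scale=1.2)
            inc = random_incidence(rng)
            rep = check_extinction_thm9(p, inc)
            if rep.condA_holds or rep.condB_holds:
                hits += 1
                assert rep.Rtilde0 < 1
        assert hits > 20  # the draw actually exercises the implication


class TestMeanBounds:
    def test_thm12_linear_g_reduction(self):
        # g identity (omega=0): G' == 0, bound = (dI+gamma)(Rt-1)/(beta S1)
        p = _params(beta=2.0, gamma=0.2, dI=0.4, dS=0.3, dR=0.3)
        inc = make_builtin_incidence(0.0, 0.0)
        b = persistence_bound_thm12(p, inc, M0_bound=5.0)
        assert b.applicable
        rt = b.threshold
        assert b.value == pytest.approx((p.dI + p.gamma) * (rt - 1) / (p.beta * compute_S1(p)),
                                        rel=1e-12)

    def test_thm12_direct_evaluation(self, examples):
        # independent term-by-term evaluation with the closed forms of G
        p = examples["example2"].params.with_zero_rows([0])
        inc = make_builtin_incidence(0.0, 2.0)  # theorem case: f(S)=S
        M0 = compute_Sbar(p)
        b = persistence_bound_thm12(p, inc, M0_bound=M0)
        assert b.applicable and b.value > 0
        r = p.dI + p.gamma
        rt = (p.beta * compute_S0(p) - 0.5 * p.sigma_i_sq(2)) / r
        M, supGp = 1 + 2.0 * M0**2, 2 * 2.0 * M0
        want = r * (rt - 1) / ((p.beta * compute_S1(p) + (r + 0.5 * p.sigma_i_sq(2)) * (M + 1) * supGp))
        assert b.value == pytest.approx(want, rel=1e-6)

    def test_thm12_not_applicable_below_threshold(self, examples):
        import dataclasses
        p = dataclasses.replace(examples["example1"].params, beta=0.1).with_zero_rows([0])
        b = persistence_bound_thm12(p, examples["example1"].incidence, M0_bound=3.0)
        assert not b.applicable and b.value == 0.0

    def test_thm14_direct_evaluation(self, examples):
        p = examples["example4"].params.with_zero_rows([1, 2, 3])
        inc = make_builtin_incidence(0.0, 4.0)
        b = permanence_bound_thm14(p, inc)
        assert b.applicable and b.value > 0
        r = p.dI + p.gamma
        Sbar = compute_Sbar(p)
        want = r * (b.threshold - 1) / (p.beta * compute_S1(p) + r * 2 * 4.0 * Sbar)
        assert b.value == pytest.approx(want, rel=1e-6)

    def test_thm14_not_applicable(self, examples):
        fx = examples["example3"]
        b = permanence_bound_thm14(fx.params.with_zero_rows([1, 2, 3]), fx.incidence)
        assert (b.value > 0) == b.applicable

    def test_thm15_M0_trivial_case(self):
        p = _params(Lambda=2.0, dS=0.5, dI=0.5, dR=0.5)
        bound, M0 = permanence_bound_thm15(p, make_builtin_incidence(0.0, 1.0))
        assert M0 == pytest.approx(6 * 2.0 / 0.5, rel=1e-12)

    def test_thm15_M0_term_by_term(self):
        p = _params(Lambda=1.0, dS=0.3, dR=0.3, dI=0.4, gamma=0.2, epsilon=0.1, p=0.05)
        _, M0 = permanence_bound_thm15(p, make_builtin_incidence(0.0, 1.0))
        dS, e, pp, g, al = 0.3, 0.1, 0.05, 0.2, 0.1
        terms = [1.0, al**2 / dS**2, g**2 / (dS + e) ** 2, pp**2 / (dS + e + pp) ** 2,
                 pp * al**2 / (dS**2 * (dS + e + pp) ** 2),
                 pp * g**2 / ((dS + e) ** 2 * (dS + e + pp) ** 2)]
        assert M0 == pytest.approx(6 * sum(terms) * 1.0 / dS, rel=1e-12)

    def test_thm15_requires_equal_removal(self):
        p = _params(dS=0.3, dR=0.4, dI=0.5)
        bound, M0 = permanence_bound_thm15(p, make_builtin_incidence())
        assert not bound.applicable and np.isnan(M0)


def test_threshold_report_consistency(examples):
    fx = examples["example3"]
    rep = compute_threshold_report(fx.params, fx.incidence)
    assert rep.Sbar >= rep.S0
    assert rep.verdicts["Rtilde0_gt_1"] and not rep.verdicts["Rbar0_gt_1"]
    assert rep.as_dict()["Rtilde0"] == rep.Rtilde0


def test_Sbar_dominates_S0_on_random_draws(rng):
    for _ in range(300):
        p = random_valid_params(rng)
        assert compute_Sbar(p) >= compute_S0(p) - 1e-12
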