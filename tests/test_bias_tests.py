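import math

import numpy as np
import pytest

from oracles import (
    begg_permutation_pvalue,
    begg_standardized_deviates_oracle,
    wls_oracle,
)

from dtabias.bias_tests import (
    begg_test,
    deeks_test,
    egger_test,
    exact_kendall_pvalue,
    run_all_tests,
)
from dtabias.config import RunConfig
from dtabias.effects import StudyEffect, meta_effects
from dtabias.exceptions import InsufficientDataError
from dtabias.study_data import MetaAnalysis, StudyTable


def make_effect(ln_dor, var=None, se=None, ess_=100.0, study_id="s"):
    if var is None:
        var = se * se
    return StudyEffect(
        study_id=study_id, dor=math.exp(ln_dor), ln_dor=ln_dor,
        var_ln_dor=var, se_ln_dor=math.sqrt(var),
        ess=ess_, inv_sqrt_ess=1.0 / math.sqrt(ess_), n_total=int(2 * ess_),
    )


def make_effects(ln_dors, vars=None, esss=None):
    k = len(ln_dors)
    vars = vars if vars is not None else [1.0] * k
    esss = esss if esss is not None else [100.0 + 10 * i for i in range(k)]
    return [
        make_effect(t, var=v, ess_=e, study_id=f"s{i}")
        for i, (t, v, e) in enumerate(zip(ln_dors, vars, esss))
    ]


class TestBegg:
    def test_naive_perfect_negative_correlation(self):
        res = begg_test(make_effects([1, 2, 3], [3, 2, 1]), variant="naive")
        assert res.slope_or_tau == pytest.approx(-1.0)
        assert res.p_value == pytest.approx(1 / 3)

    def test_naive_perfect_positive_correlation(self):
        res = begg_test(make_effects([1, 2, 3], [1, 2, 3]), variant="naive")
        assert res.slope_or_tau == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 3)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            begg_test(make_effects([1, 2], [1, 2]))

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            begg_test(make_effects([1, 2, 3], [1, 2, 3]), variant="weighted")

    def test_all_tied_degenerate(self):
        res = begg_test(make_effects([1, 2, 3], [2, 2, 2]), variant="naive")
        assert res.p_value == 1.0
        assert not res.significant
        assert any("degenerate" in n for n in res.notes)

    @pytest.mark.parametrize("k", [4, 5, 6, 7, 8])
    def test_exact_p_matches_permutation_oracle(self, k, rng):
        ln_dors = rng.normal(0, 1, size=k)
        vars_ = rng.uniform(0.1, 2.0, size=k)
        effs = make_effects(list(ln_dors), list(vars_))
        res = begg_test(effs, variant="standardized")
        assert "p=exact" in res.notes
        dev = begg_standardized_deviates_oracle(ln_dors, vars_)
        p_oracle = begg_permutation_pvalue(dev, vars_)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_normal_approx_near_exact_for_k8(self, rng):
        # tie-free data: asymptotic and exact p within 0.02 at k = 8
        for _ in range(10):
            ln_dors = list(rng.normal(0, 1, size=8))
            vars_ = list(rng.uniform(0.1, 2.0, size=8))
            effs = make_effects(ln_dors, vars_)
            res_exact = begg_test(effs)
            res_approx = begg_test(effs, exact_max_k=0)
            assert "p=normal-approx" in res_approx.notes
            assert abs(res_exact.p_value - res_approx.p_value) < 0.02

    def test_order_invariance(self, rng):
        effs = make_effects(list(rng.normal(0, 1, 9)), list(rng.uniform(0.1, 2, 9)))
        res1 = begg_test(effs)
        res2 = begg_test(list(reversed(effs)))
        assert res1.p_value == pytest.approx(res2.p_value, abs=1e-12)
        assert res1.slope_or_tau == pytest.approx(res2.slope_or_tau, abs=1e-12)

    def test_exact_kendall_p_is_valid_probability(self):
        for n in range(3, 9):
            n0 = n * (n - 1) // 2
            assert exact_kendall_pvalue(n0, n) == pytest.approx(2 / math.factorial(n))
            assert exact_kendall_pvalue(0, n) == 1.0


class TestEgger:
    def test_exact_fit_degenerate(self):
        ses = [0.5, 0.4, 0.3, 0.2]
        effs = [make_effect(2 * s, se=s, study_id=f"s{i}") for i, s in enumerate(ses)]
        res = egger_test(effs)
        assert res.slope_or_tau == pytest.approx(2.0)
        assert math.isnan(res.p_value)
        assert any("zero residual" in n for n in res.notes)

    def test_against_wls_oracle(self):
        ln_dors = [1.0, 1.2, 0.8, 1.0]
        ses = [0.5, 0.4, 0.3, 0.2]
        effs = [make_effect(t, se=s, study_id=f"s{i}")
                for i, (t, s) in enumerate(zip(ln_dors, ses))]
        res = egger_test(effs)
        ref = wls_oracle(ln_dors, ses, [1 / s**2 for s in ses])
        assert res.slope_or_tau == pytest.approx(ref["slope"], abs=1e-10)
        assert res.statistic == pytest.approx(ref["t"], abs=1e-10)
        assert res.p_value == pytest.approx(ref["p"], abs=1e-10)
        assert res.df == ref["df"]

    def test_weighted_equals_classical_form(self, rng):
        # weighted slope == intercept of standardized-effect-on-precision OLS
        for _ in range(20):
            k = int(rng.integers(4, 15))
            y = rng.normal(1, 1, size=k)
            se = rng.uniform(0.1, 1.0, size=k)
            effs = [make_effect(float(t), se=float(s), study_id=f"s{i}")
                    for i, (t, s) in enumerate(zip(y, se))]
            res = egger_test(effs)
            classical = wls_oracle(y / se, 1.0 / se, np.ones(k))
            assert res.slope_or_tau == pytest.approx(classical["intercept"], abs=1e-10)
            assert res.statistic == pytest.approx(classical["t0"], abs=1e-10)
            assert res.p_value == pytest.approx(classical["p0"], abs=1e-10)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            egger_test(make_effects([1, 2], [1, 2]))

    def test_constant_se_degenerate(self):
        res = egger_test(make_effects([1.0, 2.0, 1.5, 0.5], [1.0, 1.0, 1.0, 1.0]))
        assert math.isnan(res.p_value)
        assert any("constant regressor" in n for n in res.notes)


class TestDeeks:
    def test_flat_funnel_degenerate(self):
        effs = make_effects([1.5, 1.5, 1.5, 1.5], esss=[50, 100, 200, 400])
        res = deeks_test(effs)
        assert res.slope_or_tau == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(res.p_value)
        assert any("zero residual" in n for n in res.notes)

    def test_against_wls_oracle(self, rng):
        for _ in range(20):
            k = int(rng.integers(4, 15))
            y = rng.normal(2, 1, size=k)
            esss = rng.uniform(30, 500, size=k)
            effs = make_effects(list(y), esss=list(esss))
            res = deeks_test(effs)
            ref = wls_oracle(y, 1 / np.sqrt(esss), esss)
            assert res.slope_or_tau == pytest.approx(ref["slope"], abs=1e-10)
            assert res.statistic == pytest.approx(ref["t"], abs=1e-10)
            assert res.p_value == pytest.approx(ref["p"], abs=1e-10)

    def test_ess_rescaling_leaves_t_and_p_unchanged(self, rng):
        y = list(rng.normal(2, 1, size=6))
        esss = list(rng.uniform(30, 500, size=6))
        res1 = deeks_test(make_effects(y, esss=esss))
        res2 = deeks_test(make_effects(y, esss=[4 * e for e in esss]))
        assert res2.statistic == pytest.approx(res1.statistic, abs=1e-9)
        assert res2.p_value == pytest.approx(res1.p_value, abs=1e-9)
        assert res2.slope_or_tau == pytest.approx(2 * res1.slope_or_tau, abs=1e-9)

    def test_order_invariance(self, effects_factory):
        effs = effects_factory(k=9)
        res1 = deeks_test(effs)
        res2 = deeks_test(list(reversed(effs)))
        assert res1.p_value == pytest.approx(res2.p_value, abs=1e-12)


class TestRunAllTests:
    def test_two_study_meta_all_flagged(self):
        meta = MetaAnalysis("m", (
            StudyTable("a", 5, 5, 5, 5), StudyTable("b", 9, 1, 1, 9),
        ))
        results = run_all_tests(meta)
        assert len(results) == 3
        assert all(not r.ok for r in results)
        assert all("insufficient-data" in r.notes for r in results)

    def test_results_have_valid_pvalues(self, meta_factory):
        meta = meta_factory(k=12, meta_id="m1")
        results = run_all_tests(meta)
        assert [r.test for r in results] == ["begg", "egger", "deeks"]
        for r in results:
            assert r.ok and 0.0 <= r.p_value <= 1.0
            assert r.meta_id == "m1"
            assert r.significant == (r.p_value < 0.05)

    def test_low_power_note(self, meta_factory):
        meta = meta_factory(k=5)
        results = run_all_tests(meta)
        for r in results:
            assert any("low-power" in n for n in r.notes)

    def test_degenerate_effect_flagged_not_raised(self):
        meta = MetaAnalysis("m", (
            StudyTable("a", 10, 0, 2, 8),
            StudyTable("b", 5, 5, 5, 5),
            StudyTable("c", 9, 1, 1, 9),
        ))
        results = run_all_tests(meta, RunConfig(continuity=0.0))
        assert all(not r.ok for r in results)
        assert all("degenerate-effect" in r.failure_reason for r in results)

    def test_alpha_configurable(self, meta_factory):
        meta = meta_factory(k=12)
        strict = run_all_tests(meta, RunConfig(alpha=0.001))
        loose = run_all_tests(meta, RunConfig(alpha=0.999))
        for rs, rl in zip(strict, loose):
            if rs.ok:
                assert rs.significant == (rs.p_value < 0.001)
                assert rl.significant == (rl.p_value < 0.999)
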