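import math

import numpy as np
import pytest

from dtabias.bias_tests import BiasTestResult
from dtabias.concordance import (
    all_pairs,
    build_call_matrix,
    kappa_statistic,
    pairwise_concordance,
    pvalue_scatter,
    scatter_annotation,
)
from dtabias.exceptions import InsufficientDataError, IntegrityError, RenderError


def result(meta_id, test, p, ok=True):
    return BiasTestResult(
        meta_id=meta_id, test=test, statistic=0.0, slope_or_tau=0.0,
        p_value=p if ok else float("nan"), significant=(ok and p < 0.05),
        k=10, notes=() if ok else ("insufficient-data",),
    )


def matrix_from_calls(calls_a, calls_b, test_a="begg", test_b="egger", alpha=0.05):
    results = []
    for i, (a, b) in enumerate(zip(calls_a, calls_b)):
        results.append(result(f"m{i}", test_a, 0.01 if a else 0.5))
        results.append(result(f"m{i}", test_b, 0.01 if b else 0.5))
    return build_call_matrix(results, alpha=alpha)


class TestBuildCallMatrix:
    def test_all_significant(self):
        results = [result(f"m{i}", t, 0.01) for i in range(3)
                   for t in ("begg", "egger", "deeks")]
        matrix = build_call_matrix(results)
        assert all(matrix.calls.values())
        assert len(matrix.meta_ids) == 3

    def test_p_exactly_alpha_not_significant(self):
        matrix = build_call_matrix([result("m1", "begg", 0.05)])
        assert matrix.calls[("m1", "begg")] is False

    def test_failed_results_excluded_with_reason(self):
        matrix = build_call_matrix([
            result("m1", "begg", 0.01),
            result("m2", "begg", 0.0, ok=False),
        ])
        assert ("m2", "begg") not in matrix.calls
        assert ("m2", "begg", "insufficient-data") in matrix.excluded

    def test_duplicates_rejected(self):
        with pytest.raises(IntegrityError):
            build_call_matrix([result("m1", "begg", 0.1), result("m1", "begg", 0.2)])


class TestKappa:
    def test_hand_computed_example(self):
        kappa, p_o, se = kappa_statistic((10, 10, 10, 70))
        assert kappa == pytest.approx(0.375)
        assert p_o == pytest.approx(0.80)

    def test_perfect_agreement(self):
        kappa, p_o, _ = kappa_statistic((30, 0, 0, 70))
        assert kappa == pytest.approx(1.0)
        assert p_o == pytest.approx(1.0)

    def test_se_matches_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import cohens_kappa

        for _ in range(25):
            table = tuple(int(v) for v in rng.integers(1, 60, size=4))
            kappa, _, se = kappa_statistic(table)
            ref = cohens_kappa(np.array(table, dtype=float).reshape(2, 2))
            assert kappa == pytest.approx(ref.kappa, abs=1e-10)
            assert se == pytest.approx(ref.std_kappa, abs=1e-10)

    def test_undefined_when_chance_agreement_is_one(self):
        kappa, p_o, se = kappa_statistic((0, 0, 0, 50))
        assert math.isnan(kappa)
        assert p_o == 1.0


class TestPairwiseConcordance:
    def test_identical_calls(self):
        matrix = matrix_from_calls([1, 0, 1, 0, 1], [1, 0, 1, 0, 1])
        res = pairwise_concordance(matrix, "begg", "egger")
        assert res.kappa == pytest.approx(1.0)
        assert res.concordance_pct == pytest.approx(100.0)

    def test_agreement_table_counts(self):
        matrix = matrix_from_calls([1, 1, 0, 0], [1, 0, 1, 0])
        res = pairwise_concordance(matrix, "begg", "egger")
        assert res.agreement_table == (1, 1, 1, 1)
        assert res.concordance_pct == pytest.approx(50.0)
        assert res.n == 4

    def test_symmetry_under_test_swap(self):
        matrix = matrix_from_calls([1, 1, 0, 0, 1], [1, 0, 1, 0, 0])
        ab = pairwise_concordance(matrix, "begg", "egger")
        ba = pairwise_concordance(matrix, "egger", "begg")
        both, a_only, b_only, neither = ab.agreement_table
        assert ba.agreement_table == (both, b_only, a_only, neither)
        assert ba.kappa == pytest.approx(ab.kappa)
        assert ba.concordance_pct == pytest.approx(ab.concordance_pct)

    def test_kappa_one_iff_no_off_diagonal(self, rng):
        for _ in range(20):
            a = rng.integers(0, 2, size=30).astype(bool)
            flip = rng.integers(0, 2, size=30).astype(bool)
            b = a ^ flip
            if a.all() or (~a).all():
                continue
            matrix = matrix_from_calls(a.tolist(), b.tolist())
            res = pairwise_concordance(matrix, "begg", "egger")
            if not math.isnan(res.kappa):
                off_diag = res.agreement_table[1] + res.agreement_table[2]
                assert (res.kappa == pytest.approx(1.0)) == (off_diag == 0)
                assert res.kappa <= res.concordance_pct / 100 + 1e-12 <= 1 + 1e-12

    def test_independent_calls_give_near_zero_kappa(self):
        rng = np.random.default_rng(99)
        n = 4000
        a = rng.uniform(size=n) < 0.3
        b = rng.uniform(size=n) < 0.4
        matrix = matrix_from_calls(a.tolist(), b.tolist())
        res = pairwise_concordance(matrix, "begg", "egger")
        # MC error ~ 1/sqrt(n)
        assert abs(res.kappa) < 4 / math.sqrt(n)

    def test_degenerate_marginals_flagged(self):
        matrix = matrix_from_calls([0, 0, 0], [0, 0, 0])
        res = pairwise_concordance(matrix, "begg", "egger")
        assert math.isnan(res.kappa)
        assert any("undefined" in n for n in res.notes)

    def test_insufficient_overlap(self):
        matrix = build_call_matrix([result("m1", "begg", 0.1),
                                    result("m1", "egger", 0.1)])
        with pytest.raises(InsufficientDataError):
            pairwise_concordance(matrix, "begg", "egger")

    def test_bootstrap_ci_brackets_kappa(self):
        matrix = matrix_from_calls([1] * 12 + [0] * 18, [1] * 9 + [0] * 6 + [1] * 3 + [0] * 12)
        res = pairwise_concordance(
            matrix, "begg", "egger", ci_method="bootstrap",
            rng=np.random.default_rng(1), n_boot=500,
        )
        lo, hi = res.kappa_ci
        assert lo <= res.kappa <= hi

    def test_three_tests_three_pairs(self):
        results = [result(f"m{i}", t, 0.01 if i % 2 else 0.5)
                   for i in range(10) for t in ("begg", "egger", "deeks")]
        matrix = build_call_matrix(results)
        assert len(all_pairs(matrix)) == 3


class TestScatter:
    def test_smoke(self, tmp_path):
        matrix = matrix_from_calls([1, 0, 1, 0] * 5, [1, 1, 0, 0] * 5)
        path = tmp_path / "scatter.png"
        pvalue_scatter(matrix, "begg", "egger", str(path))
        assert path.exists() and path.stat().st_size > 0

    def test_single_point(self, tmp_path):
        matrix = build_call_matrix([result("m1", "begg", 0.3),
                                    result("m1", "egger", 0.7)])
        path = tmp_path / "one.png"
        pvalue_scatter(matrix, "begg", "egger", str(path))
        assert path.exists()

    def test_no_overlap_raises(self, tmp_path):
        matrix = build_call_matrix([result("m1", "begg", 0.3),
                                    result("m2", "egger", 0.7)])
        with pytest.raises(RenderError):
            pvalue_scatter(matrix, "begg", "egger", str(tmp_path / "x.png"))

    def test_annotation_contains_kappa_to_3_decimals(self):
        matrix = matrix_from_calls([1, 1, 0, 0, 1, 0], [1, 0, 0, 0, 1, 1])
        res = pairwise_concordance(matrix, "begg", "egger")
        assert f"{res.kappa:.3f}" in scatter_annotation(res)
        assert f"{res.concordance_pct:.0f}%" in scatter_annotation(res)
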