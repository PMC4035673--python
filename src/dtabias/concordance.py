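"""Pairwise agreement between tests' significance calls across a corpus.

Agreement is summarized by raw concordance (% of meta-analyses on which
two tests agree) and Cohen's kappa with an asymptotic 95% CI.  For two
categories weighted and unweighted kappa coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .bias_tests import BiasTestResult, TEST_NAMES
from .exceptions import InsufficientDataError, IntegrityError, RenderError

__all__ = [
    "CallMatrix",
    "ConcordanceResult",
    "build_call_matrix",
    "pairwise_concordance",
    "pvalue_scatter",
    "kappa_statistic",
]


@dataclass(frozen=True)
class CallMatrix:
    """Significance calls and p-values per (meta, test), with exclusions."""

    meta_ids: tuple[str, ...]
    tests: tuple[str, ...]
    calls: dict  # (meta_id, test) -> bool
    p_values: dict  # (meta_id, test) -> float
    excluded: tuple[tuple[str, str, str], ...]  # (meta_id, test, reason)
    alpha: float

    def complete_metas(self, test_a: str, test_b: str) -> list[str]:
        return [
            m
            for m in self.meta_ids
            if (m, test_a) in self.calls and (m, test_b) in self.calls
        ]


@dataclass(frozen=True)
class ConcordanceResult:
    """Pairwise agreement summary across a corpus.

    ``agreement_table`` holds (both significant, a only, b only,
    neither); ``concordance_pct`` is 100 * observed agreement.
    """

    test_a: str
    test_b: str
    agreement_table: tuple[int, int, int, int]
    concordance_pct: float
    kappa: float
    kappa_ci: tuple[float, float]
    n: int
    notes: tuple[str, ...] = ()


def build_call_matrix(
    results: Sequence[BiasTestResult], alpha: float = 0.05
) -> CallMatrix:
    """Collate per-(meta, test) significance calls.

    Significance is strict ``p < alpha``.  Tests that failed on a meta
    are excluded for that meta with their reason.
    """
    calls: dict = {}
    p_values: dict = {}
    excluded = []
    meta_ids: list[str] = []
    tests: list[str] = []
    seen = set()
    for res in results:
        key = (res.meta_id, res.test)
        if key in seen:
            raise IntegrityError(f"duplicate result for {key}")
        seen.add(key)
        if res.meta_id not in meta_ids:
            meta_ids.append(res.meta_id)
        if res.test not in tests:
            tests.append(res.test)
        if not res.ok:
            excluded.append((res.meta_id, res.test, res.failure_reason))
            continue
        calls[key] = bool(res.p_value < alpha)
        p_values[key] = float(res.p_value)
    return CallMatrix(
        meta_ids=tuple(meta_ids),
        tests=tuple(tests),
        calls=calls,
        p_values=p_values,
        excluded=tuple(excluded),
        alpha=alpha,
    )


def kappa_statistic(table: tuple[int, int, int, int]) -> tuple[float, float, float]:
    """Cohen's kappa, observed agreement p_o, and its asymptotic SE.

    ``table`` is (both, a_only, b_only, neither).  The SE is the
    Fleiss-Cohen-Everitt large-sample standard error of kappa-hat.
    Returns (kappa, p_o, se); kappa and se are nan when chance
    agreement p_e equals 1.
    """
    n = sum(table)
    if n < 2:
        raise InsufficientDataError(f"kappa requires >= 2 items, got {n}")
    both, a_only, b_only, neither = table
    p = np.array([[both, a_only], [b_only, neither]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = p[0, 0] + p[1, 1]
    p_e = float(row @ col)
    if 1.0 - p_e < 1e-12:
        return float("nan"), p_o, float("nan")
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss, Cohen & Everitt (1969) variance of kappa-hat
    a_term = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2 for i in range(2)
    )
    b_term = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    c_term = (kappa - p_e * (1.0 - kappa)) ** 2
    var = (a_term + b_term - c_term) / (n * (1.0 - p_e) ** 2)
    se = math.sqrt(max(var, 0.0))
    return kappa, p_o, se


def pairwise_concordance(
    matrix: CallMatrix,
    test_a: str,
    test_b: str,
    ci_method: str = "asymptotic",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> ConcordanceResult:
    """Agreement between two tests over the metas where both ran.

    ``ci_method`` is ``"asymptotic"`` (normal interval on the FCE
    standard error, default) or ``"bootstrap"`` (percentile over
    resampled metas; needs ``rng``).
    """
    metas = matrix.complete_metas(test_a, test_b)
    n = len(metas)
    if n < 2:
        raise InsufficientDataError(
            f"pair ({test_a}, {test_b}): need >= 2 metas with both calls, got {n}"
        )
    a = np.array([matrix.calls[(m, test_a)] for m in metas], dtype=bool)
    b = np.array([matrix.calls[(m, test_b)] for m in metas], dtype=bool)
    table = (
        int(np.sum(a & b)),
        int(np.sum(a & ~b)),
        int(np.sum(~a & b)),
        int(np.sum(~a & ~b)),
    )
    kappa, p_o, se = kappa_statistic(table)
    notes: list[str] = []
    if math.isnan(kappa):
        notes.append("kappa undefined: chance agreement is 1")
        ci = (float("nan"), float("nan"))
    elif ci_method == "bootstrap":
        if rng is None:
            rng = np.random.default_rng(0)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            ba, bb = a[idx], b[idx]
            t = (
                int(np.sum(ba & bb)),
                int(np.sum(ba & ~bb)),
                int(np.sum(~ba & bb)),
                int(np.sum(~ba & ~bb)),
            )
            kb, _, _ = kappa_statistic(t)
            if not math.isnan(kb):
                boots.append(kb)
        if boots:
            ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
        else:
            ci = (float("nan"), float("nan"))
            notes.append("bootstrap CI unavailable: all resamples degenerate")
        notes.append(f"ci=bootstrap({n_boot})")
    else:
        ci = (kappa - 1.96 * se, kappa + 1.96 * se)
    return ConcordanceResult(
        test_a=test_a,
        test_b=test_b,
        agreement_table=table,
        concordance_pct=100.0 * p_o,
        kappa=kappa,
        kappa_ci=ci,
        n=n,
        notes=tuple(notes),
    )


def all_pairs(matrix: CallMatrix, **kwargs) -> list[ConcordanceResult]:
    """Concordance for every unordered pair of tests in the matrix."""
    return [
        pairwise_concordance(matrix, a, b, **kwargs)
        for a, b in combinations(matrix.tests, 2)
    ]


def scatter_annotation(res: ConcordanceResult) -> str:
    """Caption-style annotation used on the p-value scatter plots."""
    return f"Concordance {res.concordance_pct:.0f}% (κ = {res.kappa:.3f})"


def pvalue_scatter(
    matrix: CallMatrix, test_x: str, test_y: str, path: str
) -> str:
    """Scatter of the two tests' p-values with dotted 0.05 gridlines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    metas = matrix.complete_metas(test_x, test_y)
    if not metas:
        raise RenderError(f"no metas with both {test_x} and {test_y} p-values")
    px = [matrix.p_values[(m, test_x)] for m in metas]
    py = [matrix.p_values[(m, test_y)] for m in metas]

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(px, py, s=26, facecolors="none", edgecolors="black")
    ax.axvline(matrix.alpha, linestyle=":", linewidth=1, color="black")
    ax.axhline(matrix.alpha, linestyle=":", linewidth=1, color="black")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel(f"p-value {test_x.capitalize()}")
    ax.set_ylabel(f"p-value {test_y.capitalize()}")
    if len(metas) >= 2:
        ax.set_title(scatter_annotation(pairwise_concordance(matrix, test_x, test_y)))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
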