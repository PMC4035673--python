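"""Funnel-asymmetry tests for DTA meta-analyses: Begg, Egger and Deeks.

All three operate on per-study log diagnostic odds ratios:

* Begg: Kendall rank correlation between effects (optionally
  variance-standardized deviates) and the lnDOR variances.  Exact
  permutation null for k <= 8 without ties, tie-corrected normal
  approximation otherwise.
* Egger: weighted least squares of lnDOR on SE(lnDOR) with weights
  1/Var(lnDOR); algebraically identical to the classical regression of
  the standardized effect on precision with an intercept test.
* Deeks: weighted least squares of lnDOR on 1/sqrt(ESS) with weights
  ESS.

Regression p-values use Student-t on k - 2 degrees of freedom.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

from scipy import stats

from .config import RunConfig
from .effects import StudyEffect, meta_effects
from .exceptions import DegenerateEffectError, InsufficientDataError
from .study_data import MetaAnalysis

__all__ = [
    "BiasTestResult",
    "begg_test",
    "egger_test",
    "deeks_test",
    "run_all_tests",
    "TEST_NAMES",
]

TEST_NAMES = ("begg", "egger", "deeks")

_NAN = float("nan")


@dataclass(frozen=True)
class BiasTestResult:
    """Outcome of one asymmetry test on one meta-analysis.

    ``statistic`` is the Kendall z (or exact-S, see notes) for Begg and
    the slope t-statistic for the regressions; ``slope_or_tau`` is the
    estimated regression slope or Kendall tau-b.  A failed or degenerate
    run carries ``p_value = nan`` and a reason in ``notes``.
    """

    meta_id: str
    test: str
    statistic: float
    slope_or_tau: float
    p_value: float
    significant: bool
    k: int
    df: int | None = None
    notes: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not math.isnan(self.p_value)

    @property
    def failure_reason(self) -> str:
        return self.notes[0] if self.notes else "failed"


# ---------------------------------------------------------------------------
# Kendall machinery


def _kendall_counts(x: Sequence[float], y: Sequence[float]):
    """Return (S, n_tied_pairs_x, n_tied_pairs_y, tie group sizes)."""
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = int(x[j] > x[i]) - int(x[j] < x[i])
            b = int(y[j] > y[i]) - int(y[j] < y[i])
            s += a * b
    tx = [c for c in Counter(x).values() if c > 1]
    ty = [c for c in Counter(y).values() if c > 1]
    return s, tx, ty


def _tau_b(s: int, n: int, tx: list[int], ty: list[int]) -> float:
    n0 = n * (n - 1) // 2
    n1 = sum(t * (t - 1) // 2 for t in tx)
    n2 = sum(t * (t - 1) // 2 for t in ty)
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        return _NAN
    return s / denom


def _var_s(n: int, tx: list[int], ty: list[int]) -> float:
    """Tie-corrected null variance of Kendall's S."""
    v0 = n * (n - 1) * (2 * n + 5)
    vt = sum(t * (t - 1) * (2 * t + 5) for t in tx)
    vu = sum(u * (u - 1) * (2 * u + 5) for u in ty)
    v1 = (
        sum(t * (t - 1) for t in tx)
        * sum(u * (u - 1) for u in ty)
        / (2.0 * n * (n - 1))
    )
    v2 = 0.0
    if n > 2:
        v2 = (
            sum(t * (t - 1) * (t - 2) for t in tx)
            * sum(u * (u - 1) * (u - 2) for u in ty)
            / (9.0 * n * (n - 1) * (n - 2))
        )
    return (v0 - vt - vu) / 18.0 + v1 + v2


def _inversion_counts(n: int) -> list[int]:
    """Mahonian numbers: permutations of n items by inversion count."""
    counts = [1]
    for m in range(2, n + 1):
        new = [0] * (len(counts) + m - 1)
        for d, c in enumerate(counts):
            for j in range(m):
                new[d + j] += c
        counts = new
    return counts


def exact_kendall_pvalue(s_obs: int, n: int) -> float:
    """Two-sided exact p-value for Kendall's S with no ties.

    P(|S| >= |s_obs|) under the uniform permutation null, computed from
    the inversion-count distribution (S = n0 - 2d for d discordant
    pairs).
    """
    counts = _inversion_counts(n)
    n0 = n * (n - 1) // 2
    total = math.factorial(n)
    hits = sum(c for d, c in enumerate(counts) if abs(n0 - 2 * d) >= abs(s_obs))
    return hits / total


def _begg_deviates(effects: Sequence[StudyEffect]) -> list[float]:
    """Begg-Mazumdar standardized deviates (t_i - tbar)/sqrt(v_i - vbar)."""
    v = [e.var_ln_dor for e in effects]
    t = [e.ln_dor for e in effects]
    w = [1.0 / vi for vi in v]
    sw = sum(w)
    tbar = sum(wi * ti for wi, ti in zip(w, t)) / sw
    vbar = 1.0 / sw  # variance of the weighted mean; < min(v_i) for k >= 2
    return [(ti - tbar) / math.sqrt(vi - vbar) for ti, vi in zip(t, v)]


def begg_test(
    effects: Sequence[StudyEffect],
    variant: str = "standardized",
    alpha: float = 0.05,
    meta_id: str = "",
    exact_max_k: int = 8,
    z_continuity: bool = True,
) -> BiasTestResult:
    """Begg's rank-correlation test between effects and their variances.

    ``z_continuity`` applies Kendall's classic continuity correction
    (|S| - 1 in the numerator of z) in the normal approximation, which
    keeps the approximate p within ~0.02 of the exact permutation p
    from k = 8 upward on tie-free data.
    """
    if variant not in ("standardized", "naive"):
        raise ValueError(f"unknown Begg variant {variant!r}")
    k = len(effects)
    if k < 3:
        raise InsufficientDataError(f"Begg test requires >= 3 studies, got {k}")
    v = [e.var_ln_dor for e in effects]
    x = _begg_deviates(effects) if variant == "standardized" else [e.ln_dor for e in effects]

    s, tx, ty = _kendall_counts(x, v)
    tau = _tau_b(s, k, tx, ty)
    if math.isnan(tau):
        return BiasTestResult(
            meta_id=meta_id, test="begg", statistic=_NAN, slope_or_tau=_NAN,
            p_value=1.0, significant=False, k=k,
            notes=("degenerate: all ranks tied", f"variant={variant}"),
        )
    notes = [f"variant={variant}"]
    sd_s = math.sqrt(_var_s(k, tx, ty))
    if z_continuity and abs(s) > 0:
        z = math.copysign(abs(s) - 1, s) / sd_s
    else:
        z = s / sd_s
    if k <= exact_max_k and not tx and not ty:
        p = exact_kendall_pvalue(s, k)
        notes.append("p=exact")
    else:
        p = 2.0 * stats.norm.sf(abs(z))
        notes.append("p=normal-approx")
    return BiasTestResult(
        meta_id=meta_id, test="begg", statistic=z, slope_or_tau=tau,
        p_value=p, significant=p < alpha, k=k, notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Weighted least squares


def _wls_slope(y, x, w):
    """Closed-form simple WLS: slope, se(slope), t, two-sided p, df.

    Returns an extra ``degenerate`` string that is non-empty when the
    fit has (numerically) zero residual variance or a constant
    regressor.
    """
    k = len(y)
    sw = sum(w)
    xbar = sum(wi * xi for wi, xi in zip(w, x)) / sw
    ybar = sum(wi * yi for wi, yi in zip(w, y)) / sw
    sxx = sum(wi * (xi - xbar) ** 2 for wi, xi in zip(w, x))
    if sxx <= 1e-12 * sum(wi * xi * xi for wi, xi in zip(w, x)):
        return _NAN, _NAN, _NAN, _NAN, k - 2, "constant regressor"
    sxy = sum(wi * (xi - xbar) * (yi - ybar) for wi, xi, yi in zip(w, x, y))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    rss = sum(wi * (yi - intercept - slope * xi) ** 2 for wi, xi, yi in zip(w, x, y))
    tss = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, y))
    df = k - 2
    if rss <= max(tss, 1.0) * 1e-12:
        return slope, 0.0, _NAN, _NAN, df, "zero residual variance"
    se = math.sqrt(rss / df / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return slope, se, t, p, df, ""


def _regression_test(
    effects: Sequence[StudyEffect],
    test: str,
    alpha: float,
    meta_id: str,
) -> BiasTestResult:
    k = len(effects)
    if k < 3:
        raise InsufficientDataError(f"{test} test requires >= 3 studies, got {k}")
    y = [e.ln_dor for e in effects]
    if test == "egger":
        x = [e.se_ln_dor for e in effects]
        w = [1.0 / e.var_ln_dor for e in effects]
    else:
        x = [e.inv_sqrt_ess for e in effects]
        w = [e.ess for e in effects]
    slope, se, t, p, df, degenerate = _wls_slope(y, x, w)
    notes: tuple[str, ...] = (f"degenerate: {degenerate}",) if degenerate else ()
    return BiasTestResult(
        meta_id=meta_id, test=test, statistic=t, slope_or_tau=slope,
        p_value=p, significant=(not math.isnan(p)) and p < alpha,
        k=k, df=df, notes=notes,
    )


def egger_test(
    effects: Sequence[StudyEffect], alpha: float = 0.05, meta_id: str = ""
) -> BiasTestResult:
    """Egger's regression test: lnDOR on SE(lnDOR), weights 1/Var(lnDOR)."""
    return _regression_test(effects, "egger", alpha, meta_id)


def deeks_test(
    effects: Sequence[StudyEffect], alpha: float = 0.05, meta_id: str = ""
) -> BiasTestResult:
    """Deeks' regression test: lnDOR on 1/sqrt(ESS), weights ESS."""
    return _regression_test(effects, "deeks", alpha, meta_id)


def _failed(meta_id: str, test: str, k: int, reason: str) -> BiasTestResult:
    return BiasTestResult(
        meta_id=meta_id, test=test, statistic=_NAN, slope_or_tau=_NAN,
        p_value=_NAN, significant=False, k=k, notes=(reason,),
    )


def run_all_tests(
    meta: MetaAnalysis, config: RunConfig | None = None
) -> list[BiasTestResult]:
    """Run every enabled test on one meta-analysis.

    Per-test errors are captured as flagged results (``p_value = nan``
    plus a reason) so that a corpus run never aborts on a single meta.
    """
    config = config or RunConfig()
    k = meta.k
    try:
        effects = meta_effects(meta.studies, continuity=config.continuity)
    except DegenerateEffectError as exc:
        return [_failed(meta.meta_id, t, k, f"degenerate-effect: {exc}") for t in TEST_NAMES]

    results = []
    for test in TEST_NAMES:
        if k < config.min_k:
            results.append(_failed(meta.meta_id, test, k, "insufficient-data"))
            continue
        try:
            if test == "begg":
                res = begg_test(effects, config.begg_variant, config.alpha, meta.meta_id)
            elif test == "egger":
                res = egger_test(effects, config.alpha, meta.meta_id)
            else:
                res = deeks_test(effects, config.alpha, meta.meta_id)
        except InsufficientDataError:
            results.append(_failed(meta.meta_id, test, k, "insufficient-data"))
            continue
        if k < config.low_power_k:
            res = replace(res, notes=res.notes + ("low-power: k < %d" % config.low_power_k,))
        results.append(res)
    return results
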