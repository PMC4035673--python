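"""Per-study and pooled accuracy-effect quantities.

Per study: the diagnostic odds ratio DOR = (tp*tn)/(fp*fn), its natural
log, the Woolf variance 1/tp + 1/fp + 1/fn + 1/tn, and the effective
sample size ESS = 4*n1*n2/(n1+n2) with n1 diseased and n2 non-diseased.
Pooled: inverse-variance fixed effect or DerSimonian-Laird random
effects on the log-DOR scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import DegenerateEffectError, InsufficientDataError
from .study_data import StudyTable

__all__ = ["StudyEffect", "PooledEffect", "ess", "study_effect", "pool_ln_dor"]


@dataclass(frozen=True)
class StudyEffect:
    """Derived per-study quantities used by every test and plot."""

    study_id: str
    dor: float
    ln_dor: float
    var_ln_dor: float
    se_ln_dor: float
    ess: float
    inv_sqrt_ess: float
    n_total: int
    corrected: bool = False


@dataclass(frozen=True)
class PooledEffect:
    """Pooled log-DOR with between-study variance estimate."""

    ln_dor_pooled: float
    dor_pooled: float
    tau2: float
    k: int
    method: str


def ess(n_diseased: int, n_nondiseased: int) -> float:
    """Effective sample size 4*n1*n2/(n1+n2).

    Equals the total sample size when the groups are balanced and is
    strictly smaller otherwise.
    """
    if n_diseased < 1 or n_nondiseased < 1:
        raise DegenerateEffectError(
            f"both group sizes must be >= 1, got ({n_diseased}, {n_nondiseased})"
        )
    return 4.0 * n_diseased * n_nondiseased / (n_diseased + n_nondiseased)


def study_effect(
    table: StudyTable,
    continuity: float = 0.5,
    always_correct: bool = False,
) -> StudyEffect:
    """Compute DOR, lnDOR, Woolf variance and ESS for one study.

    If any cell is zero (or ``always_correct`` is set), ``continuity``
    is added to all four cells before computing the odds ratio and its
    variance.  The ESS always uses the uncorrected group sizes: it is a
    design quantity, not an effect.
    """
    if continuity < 0:
        raise ValueError(f"continuity must be >= 0, got {continuity}")
    cells = (table.tp, table.fp, table.fn, table.tn)
    needs_correction = always_correct or any(c == 0 for c in cells)
    if needs_correction and continuity == 0 and any(c == 0 for c in cells):
        raise DegenerateEffectError(
            f"study {table.study_id!r} has a zero cell and continuity is 0"
        )
    corrected = needs_correction and continuity > 0
    a, b, c, d = (x + continuity if corrected else float(x) for x in cells)
    dor = (a * d) / (b * c)
    ln_dor = math.log(dor)
    var = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    ess_value = ess(table.n_diseased, table.n_nondiseased)
    return StudyEffect(
        study_id=table.study_id,
        dor=dor,
        ln_dor=ln_dor,
        var_ln_dor=var,
        se_ln_dor=math.sqrt(var),
        ess=ess_value,
        inv_sqrt_ess=1.0 / math.sqrt(ess_value),
        n_total=table.n_total,
        corrected=corrected,
    )


def meta_effects(
    studies: Iterable[StudyTable],
    continuity: float = 0.5,
    always_correct: bool = False,
) -> list[StudyEffect]:
    """Vector of :func:`study_effect` over a meta-analysis."""
    return [study_effect(s, continuity, always_correct) for s in studies]


def pool_ln_dor(
    effects: Sequence[StudyEffect],
    method: str = "dersimonian-laird",
) -> PooledEffect:
    """Pool log-DORs by fixed effect or DerSimonian-Laird random effects.

    Fixed effect: inverse-variance weighted mean, tau2 = 0.
    DerSimonian-Laird: tau2 = max(0, (Q - (k-1)) / (S1 - S2/S1)) with
    S_r the sums of the r-th powers of the fixed-effect weights, then
    weights 1/(v_i + tau2).
    """
    if method not in ("fixed", "dersimonian-laird"):
        raise ValueError(f"unknown pooling method {method!r}")
    k = len(effects)
    if k < 2:
        raise InsufficientDataError(f"pooling requires >= 2 studies, got {k}")
    y = [e.ln_dor for e in effects]
    v = [e.var_ln_dor for e in effects]
    w = [1.0 / vi for vi in v]
    sw = sum(w)
    mu_fixed = sum(wi * yi for wi, yi in zip(w, y)) / sw

    tau2 = 0.0
    if method == "dersimonian-laird":
        q = sum(wi * (yi - mu_fixed) ** 2 for wi, yi in zip(w, y))
        s1 = sw
        s2 = sum(wi * wi for wi in w)
        denom = s1 - s2 / s1
        if denom > 0:
            tau2 = max(0.0, (q - (k - 1)) / denom)

    w_star = [1.0 / (vi + tau2) for vi in v]
    mu = sum(wi * yi for wi, yi in zip(w_star, y)) / sum(w_star)
    return PooledEffect(
        ln_dor_pooled=mu,
        dor_pooled=math.exp(mu),
        tau2=tau2,
        k=k,
        method=method,
    )
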