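"""Logistic regression of pairwise test concordance on meta-analysis traits.

One univariable model per factor: high pooled DOR (>= 38 by default),
number of primary studies, number of included patients.  Fits use
Newton-Raphson on the log-likelihood; separation is detected and
flagged rather than penalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .concordance import CallMatrix
from .effects import PooledEffect
from .exceptions import (
    InsufficientDataError,
    IntegrityError,
    NonIdentifiableError,
)
from .study_data import Corpus

__all__ = [
    "ModeratorRecord",
    "ModeratorFit",
    "build_moderator_records",
    "fit_logistic",
    "FACTORS",
]

FACTORS = ("dor_gt_38", "n_studies", "n_participants")


@dataclass(frozen=True)
class ModeratorRecord:
    """One meta-analysis's predictors and pair-specific concordance."""

    meta_id: str
    concordant: bool
    n_participants: int
    n_studies: int
    dor_gt_38: bool


@dataclass(frozen=True)
class ModeratorFit:
    """Odds ratio for one factor and one test pair."""

    pair: str
    factor: str
    odds_ratio: float
    ci95: tuple[float, float]
    converged: bool
    n: int
    beta: float = float("nan")
    se: float = float("nan")
    notes: tuple[str, ...] = ()


def build_moderator_records(
    matrix: CallMatrix,
    corpus: Corpus,
    pooled: Mapping[str, PooledEffect],
    pair: tuple[str, str],
    dor_threshold: float = 38.0,
    inclusive: bool = True,
) -> list[ModeratorRecord]:
    """One record per meta with calls from both tests of the pair."""
    test_a, test_b = pair
    records = []
    for meta_id in matrix.complete_metas(test_a, test_b):
        if meta_id not in pooled:
            raise IntegrityError(f"no pooled effect for meta {meta_id!r}")
        meta = corpus.get(meta_id)
        dor = pooled[meta_id].dor_pooled
        high = dor >= dor_threshold if inclusive else dor > dor_threshold
        records.append(
            ModeratorRecord(
                meta_id=meta_id,
                concordant=matrix.calls[(meta_id, test_a)]
                == matrix.calls[(meta_id, test_b)],
                n_participants=sum(s.n_total for s in meta.studies),
                n_studies=meta.k,
                dor_gt_38=high,
            )
        )
    return records


def fit_logistic(
    records: Sequence[ModeratorRecord],
    factor: str,
    tol: float = 1e-8,
    max_iter: int = 100,
    beta_bound: float = 15.0,
) -> ModeratorFit:
    """Univariable logistic regression of concordance on one factor.

    Newton-Raphson to gradient max-norm < ``tol``.  Divergence
    (|beta| > ``beta_bound``) or non-convergence is flagged as a
    non-converged result with no odds ratio, the signature of complete
    or quasi-complete separation.
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; choose from {FACTORS}")
    n = len(records)
    if n < 10:
        raise InsufficientDataError(f"need >= 10 records, got {n}")
    y = np.array([r.concordant for r in records], dtype=float)
    x = np.array([float(getattr(r, factor)) for r in records], dtype=float)
    pair = ""  # filled by caller via dataclasses.replace if needed
    if y.min() == y.max():
        raise NonIdentifiableError("outcome is constant")
    if x.min() == x.max():
        raise NonIdentifiableError(f"predictor {factor!r} is constant")

    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = p * (1.0 - p)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(beta)) > beta_bound:
            break

    if not converged or np.max(np.abs(beta)) > beta_bound:
        return ModeratorFit(
            pair=pair, factor=factor, odds_ratio=float("nan"),
            ci95=(float("nan"), float("nan")), converged=False, n=n,
            notes=("separation or non-convergence detected",),
        )
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    b = float(beta[1])
    se = float(math.sqrt(cov[1, 1]))
    return ModeratorFit(
        pair=pair, factor=factor,
        odds_ratio=math.exp(b),
        ci95=(math.exp(b - 1.96 * se), math.exp(b + 1.96 * se)),
        converged=True, n=n, beta=b, se=se,
    )
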