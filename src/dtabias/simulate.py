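"""Synthetic DTA meta-analysis corpora with known truth.

Each simulated study draws a total size and disease prevalence, then a
study-level log-DOR (heterogeneity ``tau``) and a positivity-threshold
shift ``theta`` (SD ``sigma_theta``) placed on a symmetric
constant-DOR ROC curve::

    logit(sens_i)     = theta_i + lambda_i / 2
    logit(1 - spec_i) = theta_i - lambda_i / 2

so logit(sens) - logit(1 - spec) = lambda_i exactly.  Cell counts are
binomial.  An optional step selection rule suppresses "negative"
studies (one-sided Wald p >= threshold for lnDOR > 0) with probability
1 - retain_prob, and each meta-analysis is refilled until it holds k
published studies.

All randomness flows from one ``numpy.random.Generator`` seeded from
the scenario.  Per study the stream order is: total size, prevalence,
lambda, theta, tp, tn, then (only when the selection rule needs it) one
uniform publication draw.  This order is part of the stable interface.

Scenario distribution defaults are calibration choices (median ~13
studies per meta, IQR ~9-19, range 4-118; per-study size median ~100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .bias_tests import TEST_NAMES, run_all_tests
from .config import RunConfig
from .effects import study_effect
from .exceptions import ScenarioError
from .study_data import Corpus, MetaAnalysis, StudyTable

__all__ = [
    "LogNormalTrunc",
    "BetaTrunc",
    "Fixed",
    "SelectionRule",
    "SimulationScenario",
    "simulate_study",
    "apply_selection",
    "simulate_corpus",
    "estimate_operating_characteristics",
]

_MAX_REJECT = 10_000


@dataclass(frozen=True)
class LogNormalTrunc:
    """Lognormal by median and log-SD, rejection-truncated to [low, high]."""

    median: float
    sigma: float
    low: float
    high: float
    integer: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.median <= 0 or not self.low <= self.median <= self.high:
            raise ScenarioError(f"invalid LogNormalTrunc {self}")

    def sample(self, rng: np.random.Generator):
        mu = math.log(self.median)
        for _ in range(_MAX_REJECT):
            x = math.exp(rng.normal(mu, self.sigma))
            if self.integer:
                x = int(round(x))
            if self.low <= x <= self.high:
                return x
        raise ScenarioError(f"truncation rejected {_MAX_REJECT} draws: {self}")


@dataclass(frozen=True)
class BetaTrunc:
    """Beta(a, b) rejection-truncated to [low, high]."""

    a: float
    b: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or not 0 <= self.low < self.high <= 1:
            raise ScenarioError(f"invalid BetaTrunc {self}")

    def sample(self, rng: np.random.Generator) -> float:
        for _ in range(_MAX_REJECT):
            x = rng.beta(self.a, self.b)
            if self.low <= x <= self.high:
                return x
        raise ScenarioError(f"truncation rejected {_MAX_REJECT} draws: {self}")


@dataclass(frozen=True)
class Fixed:
    """Degenerate distribution; consumes no random draws."""

    value: float

    def sample(self, rng: np.random.Generator):
        return int(self.value) if float(self.value).is_integer() else self.value


@dataclass(frozen=True)
class SelectionRule:
    """Step selective-publication rule on the one-sided study p-value.

    ``mode="none"`` publishes everything.  ``mode="p_step"`` publishes
    studies with one-sided Wald p < ``p_threshold`` (for lnDOR > 0)
    with certainty and the rest with probability ``retain_prob``.
    """

    mode: str = "none"
    p_threshold: float = 0.05
    retain_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "p_step"):
            raise ScenarioError(f"unknown selection mode {self.mode!r}")
        if not 0.0 <= self.retain_prob <= 1.0:
            raise ScenarioError("retain_prob must be in [0, 1]")
        if not 0.0 < self.p_threshold < 1.0:
            raise ScenarioError("p_threshold must be in (0, 1)")


def default_k_distribution() -> LogNormalTrunc:
    return LogNormalTrunc(median=13.0, sigma=0.55, low=4, high=118, integer=True)


def default_n_distribution() -> LogNormalTrunc:
    return LogNormalTrunc(median=100.0, sigma=0.8, low=20, high=2000, integer=True)


def default_prevalence_distribution() -> BetaTrunc:
    return BetaTrunc(a=2.0, b=2.0, low=0.05, high=0.95)


@dataclass(frozen=True)
class SimulationScenario:
    """Generative model for a corpus of DTA meta-analyses."""

    n_metas: int = 92
    k_distribution: object = field(default_factory=default_k_distribution)
    n_distribution: object = field(default_factory=default_n_distribution)
    prevalence_distribution: object = field(default_factory=default_prevalence_distribution)
    ln_dor_true: float = 0.0
    tau: float = 0.0
    sigma_theta: float = 0.0
    suppression: SelectionRule = field(default_factory=SelectionRule)
    seed: int = 0
    max_attempts_per_study: int = 50

    def __post_init__(self) -> None:
        if self.n_metas < 1:
            raise ScenarioError("n_metas must be >= 1")
        if self.tau < 0 or self.sigma_theta < 0:
            raise ScenarioError("tau and sigma_theta must be >= 0")


def _expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def operating_point(ln_dor: float, theta: float) -> tuple[float, float]:
    """(sensitivity, specificity) on the symmetric constant-DOR ROC.

    Satisfies logit(sens) - logit(1 - spec) = ln_dor exactly for every
    threshold shift theta.
    """
    sens = _expit(theta + ln_dor / 2.0)
    spec = 1.0 - _expit(theta - ln_dor / 2.0)
    return sens, spec


def simulate_study(
    scenario: SimulationScenario, rng: np.random.Generator, study_id: str = "s"
) -> StudyTable:
    """Draw one primary study from the scenario's generative model."""
    n = int(scenario.n_distribution.sample(rng))
    prev = float(scenario.prevalence_distribution.sample(rng))
    n1 = max(1, min(n - 1, int(round(prev * n))))
    n2 = n - n1
    lam = rng.normal(scenario.ln_dor_true, scenario.tau)
    theta = rng.normal(0.0, scenario.sigma_theta)
    sens, spec = operating_point(lam, theta)
    tp = int(rng.binomial(n1, sens))
    tn = int(rng.binomial(n2, spec))
    return StudyTable(study_id=study_id, tp=tp, fn=n1 - tp, tn=tn, fp=n2 - tn)


def apply_selection(
    study: StudyTable, rule: SelectionRule, rng: np.random.Generator
) -> bool:
    """Decide publication.  Consumes one uniform draw only when the
    decision is genuinely random (p_step mode, non-significant study,
    0 < retain_prob < 1), so retain_prob = 1 is stream-identical to no
    selection."""
    if rule.mode == "none":
        return True
    effect = study_effect(study, continuity=0.5)
    z = effect.ln_dor / effect.se_ln_dor
    p_one_sided = float(stats.norm.sf(z))
    if p_one_sided < rule.p_threshold:
        return True
    if rule.retain_prob >= 1.0:
        return True
    if rule.retain_prob <= 0.0:
        return False
    return bool(rng.uniform() < rule.retain_prob)


def simulate_meta(
    scenario: SimulationScenario,
    rng: np.random.Generator,
    meta_id: str,
    k: int | None = None,
) -> MetaAnalysis:
    """Simulate one meta-analysis of k published studies."""
    if k is None:
        k = int(scenario.k_distribution.sample(rng))
    published: list[StudyTable] = []
    attempts = 0
    cap = scenario.max_attempts_per_study * k
    while len(published) < k:
        attempts += 1
        if attempts > cap:
            raise ScenarioError(
                f"meta {meta_id!r}: attempt cap {cap} exceeded "
                f"({len(published)}/{k} published); scenario infeasible"
            )
        study = simulate_study(scenario, rng, study_id=f"s{attempts:04d}")
        if apply_selection(study, scenario.suppression, rng):
            published.append(study)
    return MetaAnalysis(meta_id=meta_id, studies=tuple(published))


def simulate_corpus(scenario: SimulationScenario) -> tuple[Corpus, dict]:
    """Simulate a full corpus; returns (Corpus, per-meta truth record).

    Identical scenario (including seed) gives a bit-identical corpus.
    """
    rng = np.random.default_rng(scenario.seed)
    metas = []
    truth: dict = {
        "scenario": {
            "ln_dor_true": scenario.ln_dor_true,
            "tau": scenario.tau,
            "sigma_theta": scenario.sigma_theta,
            "suppression": scenario.suppression.mode != "none"
            and scenario.suppression.retain_prob < 1.0,
            "seed": scenario.seed,
        },
        "metas": {},
    }
    for i in range(scenario.n_metas):
        meta_id = f"m{i + 1:03d}"
        meta = simulate_meta(scenario, rng, meta_id)
        metas.append(meta)
        truth["metas"][meta_id] = {
            "ln_dor_true": scenario.ln_dor_true,
            "tau": scenario.tau,
            "sigma_theta": scenario.sigma_theta,
            "k": meta.k,
        }
    corpus = Corpus(metas=tuple(metas), provenance=f"simulated(seed={scenario.seed})")
    return corpus, truth


def estimate_operating_characteristics(
    scenario: SimulationScenario,
    n_replicates: int = 1000,
    tests: tuple[str, ...] = TEST_NAMES,
    config: RunConfig | None = None,
) -> dict:
    """Monte-Carlo rejection rates of each test under the scenario.

    Simulates ``n_replicates`` meta-analyses, runs each test, and
    returns per-test rejection proportions with exact (Clopper-Pearson)
    95% binomial CIs.  Failed test runs are counted separately.
    """
    if n_replicates < 100:
        raise ScenarioError("n_replicates must be >= 100")
    config = config or RunConfig()
    rng = np.random.default_rng(scenario.seed)
    rejections = {t: 0 for t in tests}
    successes = {t: 0 for t in tests}
    failures = {t: 0 for t in tests}
    for i in range(n_replicates):
        meta = simulate_meta(scenario, rng, meta_id=f"rep{i + 1:05d}")
        for res in run_all_tests(meta, config):
            if res.test not in rejections:
                continue
            if not res.ok:
                failures[res.test] += 1
                continue
            successes[res.test] += 1
            if res.significant:
                rejections[res.test] += 1
    out = {}
    for t in tests:
        n_ok = successes[t]
        rate = rejections[t] / n_ok if n_ok else float("nan")
        if n_ok:
            ci = stats.binomtest(rejections[t], n_ok).proportion_ci(
                confidence_level=0.95, method="exact"
            )
            ci_tuple = (float(ci.low), float(ci.high))
        else:
            ci_tuple = (float("nan"), float("nan"))
        out[t] = {
            "rejections": rejections[t],
            "n": n_ok,
            "rate": rate,
            "ci95": ci_tuple,
            "failures": failures[t],
            "alpha": config.alpha,
        }
    return out
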