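"""End-to-end corpus analysis: effects -> tests -> concordance -> moderators.

Produces a machine-readable report (``report.json``), CSV tables
(per-test significance summary, pairwise concordance, moderator odds
ratios, exclusion ledger) and figures (p-value scatters per test pair,
funnel plots for the first few metas).  Given the same corpus and
configuration the report JSON is byte-identical across reruns.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
import os
from itertools import combinations
from typing import Sequence

from . import __version__
from .bias_tests import BiasTestResult, TEST_NAMES, run_all_tests
from .concordance import build_call_matrix, pairwise_concordance, pvalue_scatter
from .config import RunConfig
from .effects import meta_effects, pool_ln_dor
from .exceptions import (
    DtaBiasError,
    InsufficientDataError,
    NonIdentifiableError,
)
from .funnel import FunnelSpec, funnel_coordinates, render_funnel
from .moderators import FACTORS, build_moderator_records, fit_logistic
from .study_data import Corpus, read_corpus

__all__ = ["run_pipeline", "summarize_significance"]

logger = logging.getLogger("dtabias")


def summarize_significance(results: Sequence[BiasTestResult]) -> dict:
    """Per-test identified / not-identified counts with percentages.

    Percentages are rounded to one decimal; ``formatted`` strings look
    like ``"1 (6.7)"``.
    """
    if not any(r.ok for r in results):
        raise InsufficientDataError("no successful test results to summarize")
    summary: dict = {}
    for test in TEST_NAMES:
        ok = [r for r in results if r.test == test and r.ok]
        if not ok:
            continue
        sig = sum(1 for r in ok if r.significant)
        total = len(ok)
        nonsig = total - sig
        pct_sig = round(100.0 * sig / total, 1)
        pct_non = round(100.0 * nonsig / total, 1)
        summary[test] = {
            "identified": sig,
            "identified_pct": pct_sig,
            "not_identified": nonsig,
            "not_identified_pct": pct_non,
            "total": total,
            "formatted": f"{sig} ({pct_sig}) / {nonsig} ({pct_non}) / {total}",
        }
    return summary


def _fmt_or(fit: dict) -> str:
    if not fit["converged"] or math.isnan(fit["odds_ratio"]):
        return "NE"
    lo, hi = fit["ci95"]
    return f"{fit['odds_ratio']:.3g} ({lo:.3g} to {hi:.3g})"


def _write_csv(path: str, header: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def run_pipeline(
    corpus: Corpus | str | os.PathLike,
    config: RunConfig | None = None,
    outdir: str | os.PathLike = "dtabias_out",
) -> dict:
    """Run the full analysis on a corpus (object or CSV path).

    Returns the report dictionary; also writes ``report.json``,
    ``table2.csv``, ``table3.csv``, ``concordance.csv``,
    ``exclusions.csv`` and figures under ``outdir``.
    """
    config = config or RunConfig()
    if not isinstance(corpus, Corpus):
        corpus = read_corpus(corpus)
    if len(corpus) == 0:
        raise InsufficientDataError("empty corpus")
    outdir = str(outdir)
    figdir = os.path.join(outdir, "figures")
    os.makedirs(figdir, exist_ok=True)

    # --- per-meta tests -----------------------------------------------------
    results: list[BiasTestResult] = []
    for meta in corpus:
        meta_results = run_all_tests(meta, config)
        for res in meta_results:
            if not res.ok:
                logger.info("excluded meta=%s test=%s reason=%s",
                            meta.meta_id, res.test, res.failure_reason)
        results.extend(meta_results)
    matrix = build_call_matrix(results, alpha=config.alpha)

    # --- significance summary (per-test counts) -----------------------------
    try:
        summary = summarize_significance(results)
    except InsufficientDataError:
        summary = {}

    # --- pairwise concordance + scatters ------------------------------------
    pairs = list(combinations(TEST_NAMES, 2))
    concordance_out = []
    figures: dict = {}
    for a, b in pairs:
        try:
            res = pairwise_concordance(matrix, a, b)
        except InsufficientDataError as exc:
            concordance_out.append(
                {"test_a": a, "test_b": b, "error": str(exc)}
            )
            continue
        entry = dataclasses.asdict(res)
        entry["kappa_ci"] = list(res.kappa_ci)
        entry["agreement_table"] = list(res.agreement_table)
        entry["notes"] = list(res.notes)
        concordance_out.append(entry)
        fig_path = os.path.join(figdir, f"pvalues_{a}_{b}.png")
        try:
            pvalue_scatter(matrix, a, b, fig_path)
            figures[f"pvalues_{a}_{b}"] = os.path.relpath(fig_path, outdir)
        except DtaBiasError as exc:
            logger.warning("scatter %s-%s not rendered: %s", a, b, exc)

    # --- pooled effects and moderators --------------------------------------
    pooled = {}
    for meta in corpus:
        if meta.k < 2:
            continue
        try:
            pooled[meta.meta_id] = pool_ln_dor(
                meta_effects(meta.studies, continuity=config.continuity),
                method=config.pooling,
            )
        except DtaBiasError as exc:
            logger.info("no pooled effect for %s: %s", meta.meta_id, exc)

    moderators_out: dict = {}
    for a, b in pairs:
        pair_label = f"{a}-{b}"
        usable = [m for m in matrix.complete_metas(a, b) if m in pooled]
        sub_calls = {k: v for k, v in matrix.calls.items() if k[0] in usable}
        sub_matrix = dataclasses.replace(
            matrix, meta_ids=tuple(m for m in matrix.meta_ids if m in usable),
            calls=sub_calls,
        )
        try:
            records = build_moderator_records(
                sub_matrix, corpus, pooled, (a, b),
                dor_threshold=config.dor_threshold,
                inclusive=config.dor_threshold_inclusive,
            )
        except DtaBiasError as exc:
            moderators_out[pair_label] = {"error": str(exc)}
            continue
        pair_fits: dict = {}
        for factor in FACTORS:
            try:
                fit = fit_logistic(records, factor)
                pair_fits[factor] = {
                    "odds_ratio": fit.odds_ratio,
                    "ci95": list(fit.ci95),
                    "converged": fit.converged,
                    "n": fit.n,
                    "notes": list(fit.notes),
                }
            except (InsufficientDataError, NonIdentifiableError) as exc:
                pair_fits[factor] = {
                    "odds_ratio": float("nan"),
                    "ci95": [float("nan"), float("nan")],
                    "converged": False,
                    "n": len(records),
                    "notes": [str(exc)],
                }
        moderators_out[pair_label] = pair_fits

    # --- funnel plots for the first few metas -------------------------------
    spec = FunnelSpec(x_axis="ln_dor", y_axis="inv_sqrt_ess")
    for meta in list(corpus)[: config.max_funnel_plots]:
        data = funnel_coordinates(meta, spec, continuity=config.continuity)
        if not data.points:
            continue
        pooled_x = (
            pooled[meta.meta_id].ln_dor_pooled if meta.meta_id in pooled else None
        )
        fig_path = os.path.join(figdir, f"funnel_{meta.meta_id}.png")
        render_funnel(data, fig_path, pooled_x=pooled_x)
        figures[f"funnel_{meta.meta_id}"] = os.path.relpath(fig_path, outdir)

    # --- report and CSV tables ----------------------------------------------
    report = {
        "version": __version__,
        "config": config.to_dict(),
        "provenance": corpus.provenance,
        "n_metas": len(corpus),
        "significance_summary": summary,
        "concordance": concordance_out,
        "moderators": moderators_out,
        "exclusions": [list(e) for e in matrix.excluded],
        "figures": figures,
    }
    with open(os.path.join(outdir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    _write_csv(
        os.path.join(outdir, "table2.csv"),
        ["test", "identified", "identified_pct", "not_identified",
         "not_identified_pct", "total"],
        [[t, s["identified"], s["identified_pct"], s["not_identified"],
          s["not_identified_pct"], s["total"]] for t, s in summary.items()],
    )
    _write_csv(
        os.path.join(outdir, "concordance.csv"),
        ["test_a", "test_b", "n", "both", "a_only", "b_only", "neither",
         "concordance_pct", "kappa", "kappa_lo", "kappa_hi"],
        [
            [c["test_a"], c["test_b"], c["n"], *c["agreement_table"],
             c["concordance_pct"], c["kappa"], *c["kappa_ci"]]
            for c in concordance_out if "error" not in c
        ],
    )
    _write_csv(
        os.path.join(outdir, "table3.csv"),
        ["factor"] + [f"{a}-{b}" for a, b in pairs],
        [
            [factor] + [
                _fmt_or(moderators_out[f"{a}-{b}"][factor])
                if factor in moderators_out.get(f"{a}-{b}", {}) else "NE"
                for a, b in pairs
            ]
            for factor in FACTORS
        ],
    )
    _write_csv(
        os.path.join(outdir, "exclusions.csv"),
        ["meta_id", "test", "reason"],
        [list(e) for e in matrix.excluded],
    )
    return report
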