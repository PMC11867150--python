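"""End-to-end inference pipeline.

Builds a history DAG from input maximum-parsimony histories, expands
ancestral ambiguity codes, completes the DAG, trims it to the minimal
parsimony score, collapses zero-mutation internal edges, optionally fits
branching-process parameters by maximizing the marginal likelihood over all
expressed histories, ranks the surviving histories (lexicographically or by
a linear combination of criteria) and emits the best history together with
a per-stage report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import io as pio
from .branching import BranchingParams, bp_criterion, fit_params
from .context import MutabilityModel, context_criterion
from .parsimony import parsimony_criterion
from .sdag import History, HistorySDAG
from .weights import (
    RankingCriterion,
    count_histories,
    linear_combination,
    lexicographic_trim,
    optimal_weight,
    trim,
)

logger = logging.getLogger("phylodag")

REPORT_SCHEMA_VERSION = 1

CRITERION_NAMES = ("bp_likelihood", "context_likelihood", "parsimony")


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`."""

    abundances: Mapping[str, int] = field(default_factory=dict)
    mutability_model: Optional[MutabilityModel] = None
    branching_params: Optional[BranchingParams] = None
    fit_branching: bool = False
    # default ranking: maximize branching process likelihood, then maximize
    # Poisson context likelihood
    criteria_order: Sequence[str] = ("bp_likelihood", "context_likelihood")
    linear_coefficients: Optional[Sequence[float]] = None
    expansion_cap: int = 100_000

    def validate(self) -> None:
        for name in self.criteria_order:
            if name not in CRITERION_NAMES:
                raise ValueError(f"unknown ranking criterion {name!r}")
        if self.linear_coefficients is not None and len(
            self.linear_coefficients
        ) != len(self.criteria_order):
            raise ValueError("need one coefficient per criterion")


@dataclass
class PipelineResult:
    best_history: History
    dag: HistorySDAG
    report: dict


def _stage(report: dict, name: str, dag: HistorySDAG) -> None:
    report["stages"].append({"stage": name, "n_histories": count_histories(dag)})
    logger.info("stage %-22s histories=%d", name, report["stages"][-1]["n_histories"])


def run_pipeline(histories: Sequence[History], config: PipelineConfig) -> PipelineResult:
    """Run the full DAG construction / trimming / ranking pipeline."""
    config.validate()
    t0 = time.perf_counter()
    report = {"schema_version": REPORT_SCHEMA_VERSION, "stages": []}
    report["n_input_histories"] = len(histories)

    dag = HistorySDAG.from_histories(histories)
    _stage(report, "graph_union", dag)

    dag = dag.expand_ambiguities(cap=config.expansion_cap)
    _stage(report, "expand_ambiguities", dag)

    dag = dag.complete()
    _stage(report, "complete", dag)

    pars = parsimony_criterion()
    dag = trim(dag, pars)
    report["parsimony_score"] = optimal_weight(dag, pars)
    _stage(report, "trim_parsimony", dag)

    dag = dag.collapse()
    _stage(report, "collapse", dag)

    params = config.branching_params
    if config.fit_branching:
        params = fit_params(dag, config.abundances)
        logger.info("fitted branching params p=%.4f q=%.4f", params.p, params.q)
    report["branching_params"] = (
        {"p": params.p, "q": params.q} if params is not None else None
    )

    criteria = []
    for name in config.criteria_order:
        if name == "bp_likelihood":
            if params is None:
                raise ValueError(
                    "bp_likelihood ranking requires branching params (or --fit)"
                )
            criteria.append(bp_criterion(params, config.abundances))
        elif name == "context_likelihood":
            if config.mutability_model is None:
                raise ValueError("context_likelihood ranking requires a model")
            criteria.append(context_criterion(config.mutability_model))
        elif name == "parsimony":
            criteria.append(parsimony_criterion())

    if criteria:
        report["optimal_weights"] = {
            c.name: optimal_weight(dag, c) for c in criteria
        }
        if config.linear_coefficients is not None:
            # maximize the linear combination; flip signs of minimized criteria
            signed = [
                a if c.direction == "max" else -a
                for a, c in zip(config.linear_coefficients, criteria)
            ]
            combined = RankingCriterion(
                edge_fn=linear_combination([c.edge_fn for c in criteria], signed),
                direction="max",
                name="linear_combination",
            )
            dag = trim(dag, combined)
        else:
            dag = lexicographic_trim(dag, criteria)
        _stage(report, "rank", dag)

    best = next(dag.enumerate_histories())
    report["elapsed_seconds"] = round(time.perf_counter() - t0, 3)
    return PipelineResult(best_history=best, dag=dag, report=report)
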