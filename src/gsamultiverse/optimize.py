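"""The analysis-choice space and the greedy stepwise results optimizer.

This module formalizes how a well-intentioned but result-driven analyst
tweaks a GSA pipeline: the uncertain analysis choices form an ordered list
of steps (:class:`ChoiceStep`), each with a default option and ordered
alternatives.  Optimization walks the steps in their fixed a-priori order;
at each step every alternative is evaluated with all other steps held at
their current (already optimized or default) choices, and the strictly best
improving alternative is adopted — equality is never an improvement, ties
go to the earlier-declared alternative, and a crashing option counts as
non-improving.  The result of one run is an audited
:class:`OptimizationTrajectory` from which the overoptimism relative to the
default configuration is computed.

Three optimization goals are supported: ``max_degs`` (maximize the number
of differentially enriched gene sets), ``min_adj_p`` (minimize a target
set's adjusted p-value) and ``min_rank`` (minimize its relative rank).

All option evaluations within one optimization run share a single
permutation seed, so the greedy comparison measures the options, not
Monte-Carlo noise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .datasets import GeneSetDatabase, IdConversionTable, LabelAssignment
from .errors import PipelineError
from .gsa import (
    MethodSpec,
    count_degs,
    gsea_preranked,
    gsea_sample_perm,
    ora_test,
    relative_rank,
    resolve_universe,
    weighted_fcs,
)
from .preprocessing import de_score, deduplicate, make_ranked_list, prefilter, transform_counts

logger = logging.getLogger(__name__)

__all__ = [
    "GOAL_KINDS",
    "Goal",
    "ChoiceStep",
    "PipelineContext",
    "build_choice_space",
    "evaluate",
    "is_improvement",
    "stepwise_optimize",
    "overoptimism",
    "StepEvaluation",
    "StepRecord",
    "OptimizationTrajectory",
    "OveroptimismRecord",
    "StepwiseOptimizer",
]

GOAL_KINDS = ("max_degs", "min_adj_p", "min_rank")

# Significance cutoff on BH-adjusted DE p-values used to form the ORA input
# gene list.  Fixed across option evaluations: it is part of the pipeline
# definition, not an exploited choice.
DE_ALPHA = 0.05


@dataclass(frozen=True)
class Goal:
    """One objective the hypothetical researcher optimizes toward."""

    kind: str
    target_set: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in GOAL_KINDS:
            raise ValueError(f"unknown goal kind {self.kind!r}")
        if self.kind in ("min_adj_p", "min_rank") and not self.target_set:
            raise ValueError(f"goal {self.kind!r} requires a target set name")


@dataclass(frozen=True)
class ChoiceStep:
    """One uncertain analysis choice: a default plus ordered alternatives.

    ``archetypes``/``goals`` restrict applicability (None = applies to
    all); e.g., the database choice is exploited only when maximizing the
    DEGS count, and the universe choice only exists for ORA.
    """

    name: str
    default: str
    alternatives: tuple[str, ...]
    archetypes: tuple[str, ...] | None = None
    goals: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.default in self.alternatives:
            raise ValueError(f"step {self.name!r}: default listed among alternatives")

    def applies(self, archetype: str, goal_kind: str) -> bool:
        if self.archetypes is not None and archetype not in self.archetypes:
            return False
        if self.goals is not None and goal_kind not in self.goals:
            return False
        return True


@dataclass(frozen=True)
class PipelineContext:
    """Everything one pipeline evaluation needs besides the choices."""

    counts: pd.DataFrame
    labels: LabelAssignment
    databases: Mapping[str, GeneSetDatabase]
    method: MethodSpec
    id_table: IdConversionTable | None = None
    seed: int = 0


_FCS_RANKED = ("gsea_sample_perm", "gsea_preranked")


def build_choice_space(
    database_names: Sequence[str], method: MethodSpec
) -> tuple[ChoiceStep, ...]:
    """The default step order and option sets for one GSA archetype.

    Order (fixed a priori, data preprocessing before parameters, with the
    DE method deliberately ahead of prefiltering because prefiltering
    conventions differ between DE methods): duplicate removal, DE method,
    prefilter, transformation, gene set database (DEGS-count goal only),
    ORA universe, gene-level ranking metric, p-value calculation, and the
    enrichment-score weight exponent.
    """
    database_names = list(database_names)
    if not database_names:
        raise ValueError("at least one database required")
    default_mode = method.resolved_pvalue_mode()
    other_mode = "gene_perm" if default_mode == "sample_perm" else "sample_perm"
    steps = [
        ChoiceStep("dedup", "keep_first", ("keep_highest_mean",)),
        ChoiceStep(
            "de_method",
            "welch_t",
            ("moderated_t", "wilcoxon_z"),
            archetypes=("ora",) + _FCS_RANKED,
        ),
        ChoiceStep("prefilter", "total_count:10", ("none", "cpm:1:2")),
        ChoiceStep("transform", "log2_cpm:0.5", ("median_ratio_log", "cpm")),
        ChoiceStep(
            "database",
            database_names[0],
            tuple(database_names[1:]),
            goals=("max_degs",),
        ),
        ChoiceStep(
            "universe", "all_measured", ("post_filter", "all_annotated"), archetypes=("ora",)
        ),
        ChoiceStep(
            "gene_metric", "statistic", ("log2fc", "signed_logp"), archetypes=_FCS_RANKED
        ),
        ChoiceStep("pvalue_mode", default_mode, (other_mode,), archetypes=_FCS_RANKED),
        ChoiceStep("weight", "1", ("0",), archetypes=_FCS_RANKED),
    ]
    return tuple(steps)


def default_config(space: Sequence[ChoiceStep]) -> dict[str, str]:
    return {step.name: step.default for step in space}


def evaluate(config: Mapping[str, str], goal: Goal, ctx: PipelineContext) -> float:
    """Run the full pipeline under one configuration; return the objective.

    Stages: duplicate-ID removal -> prefilter -> transform -> DE/ranking ->
    GSA archetype -> goal scalar.  Identical (config, context) pairs give
    identical values.  Failures surface as :class:`PipelineError` naming
    the stage.
    """
    method = ctx.method
    counts = ctx.counts
    if ctx.id_table is not None:
        try:
            counts = deduplicate(counts, ctx.id_table, config.get("dedup", "keep_first"))
        except PipelineError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError("dedup", str(exc)) from exc
    measured_genes = list(counts.index)
    try:
        filtered = prefilter(counts, config.get("prefilter", "none"))
        expr = transform_counts(filtered, config.get("transform", "log2_cpm:0.5"))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("preprocessing", str(exc)) from exc

    db_key = config.get("database") or next(iter(ctx.databases))
    if db_key not in ctx.databases:
        raise PipelineError("database", f"unknown database {db_key!r}")
    db = ctx.databases[db_key]

    de_option = config.get("de_method", "welch_t")
    metric_option = config.get("gene_metric", "statistic")
    spec = dataclasses.replace(method, p_w=int(config.get("weight", method.p_w)))

    try:
        if method.archetype == "ora":
            de = de_score(expr, ctx.labels, de_option)
            de_genes = set(de.index[de["adj_pval"] < DE_ALPHA])
            universe = resolve_universe(
                config.get("universe", method.universe), measured_genes, list(filtered.index), db
            )
            result = ora_test(
                de_genes,
                db,
                universe,
                min_set_size=spec.min_set_size,
                max_set_size=spec.max_set_size,
                threshold=spec.threshold,
                threshold_on=spec.threshold_on,
            )
        elif method.archetype in _FCS_RANKED:
            mode = config.get("pvalue_mode") or method.resolved_pvalue_mode()
            if mode == "sample_perm":
                result = gsea_sample_perm(
                    expr, ctx.labels, db, spec, ctx.seed,
                    de_option=de_option, metric_option=metric_option,
                )
            else:
                ranked = make_ranked_list(de_score(expr, ctx.labels, de_option), metric_option)
                result = gsea_preranked(ranked, db, spec, ctx.seed)
        elif method.archetype == "weighted_fcs":
            result = weighted_fcs(expr, ctx.labels, db, spec, ctx.seed)
        else:  # pragma: no cover - MethodSpec validates archetypes
            raise PipelineError("gsa", f"unknown archetype {method.archetype!r}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("gsa", str(exc)) from exc

    if goal.kind == "max_degs":
        return float(count_degs(result))
    # Targets filtered out of the results table take the worst-case value.
    if goal.target_set not in result.table.index:
        return 1.0
    if goal.kind == "min_adj_p":
        return float(result.table.loc[goal.target_set, "adj_pval"])
    return relative_rank(result, goal.target_set)


def is_improvement(goal: Goal, candidate: float, incumbent: float) -> bool:
    """Strict improvement in the goal's direction; equality never improves."""
    if goal.kind == "max_degs":
        return candidate > incumbent
    return candidate < incumbent


@dataclass(frozen=True)
class StepEvaluation:
    step: str
    option: str
    objective: float | None
    error: str | None = None


@dataclass(frozen=True)
class StepRecord:
    step: str
    evaluations: tuple[StepEvaluation, ...]
    chosen: str
    objective_before: float
    objective_after: float


@dataclass
class OptimizationTrajectory:
    """Full audit trail of one greedy optimization run."""

    goal: Goal
    seed: int
    default_config: dict[str, str]
    final_config: dict[str, str]
    default_objective: float
    optimized_objective: float
    records: list[StepRecord] = field(default_factory=list)

    def n_evaluations(self) -> int:
        return 1 + sum(len(r.evaluations) for r in self.records)

    def changed_steps(self) -> list[str]:
        return [
            r.step for r in self.records if r.chosen != self.default_config[r.step]
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [("default", "default", self.default_objective, None)]
        for r in self.records:
            for ev in r.evaluations:
                rows.append((ev.step, ev.option, ev.objective, ev.error))
        return pd.DataFrame(rows, columns=["step", "option", "objective", "error"])

    def to_dict(self) -> dict:
        return {
            "goal": {"kind": self.goal.kind, "target_set": self.goal.target_set},
            "seed": self.seed,
            "default_config": self.default_config,
            "final_config": self.final_config,
            "default_objective": self.default_objective,
            "optimized_objective": self.optimized_objective,
            "records": [
                {
                    "step": r.step,
                    "chosen": r.chosen,
                    "objective_before": r.objective_before,
                    "objective_after": r.objective_after,
                    "evaluations": [dataclasses.asdict(e) for e in r.evaluations],
                }
                for r in self.records
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass(frozen=True)
class OveroptimismRecord:
    """Default-vs-optimized objective values and which choices moved."""

    goal: Goal
    default_objective: float
    optimized_objective: float
    delta: float  # signed improvement: positive = results got "better"
    changed_steps: tuple[str, ...]


def stepwise_optimize(
    space: Sequence[ChoiceStep],
    goal: Goal,
    ctx: PipelineContext,
    evaluator: Callable[[Mapping[str, str], Goal, PipelineContext], float] = evaluate,
) -> OptimizationTrajectory:
    """Greedy stepwise exploitation of the choice space.

    Steps are processed in their declared order.  The running configuration
    starts at the defaults; each step evaluates its alternatives against
    the current incumbent objective and adopts the strictly best improving
    option (earliest declaration wins ties), so the objective is monotone
    in the goal's direction by construction.
    """
    applicable = [s for s in space if s.applies(ctx.method.archetype, goal.kind)]
    if not applicable:
        raise ValueError("no applicable choice steps for this archetype/goal")
    config = default_config(space)
    current = evaluator(config, goal, ctx)
    traj = OptimizationTrajectory(
        goal=goal,
        seed=ctx.seed,
        default_config=dict(config),
        final_config=dict(config),
        default_objective=current,
        optimized_objective=current,
    )
    for step in applicable:
        before = current
        evaluations: list[StepEvaluation] = []
        best_val = current
        best_opt: str | None = None
        for option in step.alternatives:
            candidate = {**config, step.name: option}
            try:
                val = evaluator(candidate, goal, ctx)
            except PipelineError as exc:
                logger.warning("option %s=%s failed (%s); treated as non-improving",
                               step.name, option, exc)
                evaluations.append(StepEvaluation(step.name, option, None, str(exc)))
                continue
            evaluations.append(StepEvaluation(step.name, option, val))
            if is_improvement(goal, val, best_val):
                best_val, best_opt = val, option
        if best_opt is not None:
            config[step.name] = best_opt
            current = best_val
        traj.records.append(
            StepRecord(
                step=step.name,
                evaluations=tuple(evaluations),
                chosen=config[step.name],
                objective_before=before,
                objective_after=current,
            )
        )
    traj.final_config = dict(config)
    traj.optimized_objective = current
    assert not is_improvement(goal, traj.default_objective, traj.optimized_objective), (
        "greedy optimization must never end worse than the default"
    )
    return traj


def overoptimism(trajectory: OptimizationTrajectory) -> OveroptimismRecord:
    """Improvement of the optimized over the default objective.

    ``delta`` is signed in the improvement direction: the DEGS-count gain
    for ``max_degs``, the decrease for the minimization goals (e.g., an
    adjusted p falling from 1 to 0.19 is a delta of +0.81).
    """
    d, o = trajectory.default_objective, trajectory.optimized_objective
    delta = (o - d) if trajectory.goal.kind == "max_degs" else (d - o)
    return OveroptimismRecord(
        goal=trajectory.goal,
        default_objective=d,
        optimized_objective=o,
        delta=delta,
        changed_steps=tuple(trajectory.changed_steps()),
    )


class StepwiseOptimizer(BaseEstimator):
    """sklearn-style meta-estimator running the greedy optimization.

    ``fit(X, y)`` takes the raw count matrix and a
    :class:`LabelAssignment`; the audit trail lands in ``trajectory_``,
    the tweaked configuration in ``best_config_``.
    """

    def __init__(
        self,
        method: MethodSpec = None,
        goal: str = "max_degs",
        target_set: str = None,
        databases: Mapping[str, GeneSetDatabase] = None,
        id_table: IdConversionTable = None,
        choice_space: Sequence[ChoiceStep] = None,
        seed: int = 0,
    ):
        self.method = method
        self.goal = goal
        self.target_set = target_set
        self.databases = databases
        self.id_table = id_table
        self.choice_space = choice_space
        self.seed = seed

    def fit(self, X: pd.DataFrame, y: LabelAssignment):
        if self.method is None or not self.databases:
            raise ValueError("a MethodSpec and at least one database are required")
        goal = Goal(kind=self.goal, target_set=self.target_set)
        space = (
            tuple(self.choice_space)
            if self.choice_space is not None
            else build_choice_space(list(self.databases), self.method)
        )
        ctx = PipelineContext(
            counts=X,
            labels=y,
            databases=dict(self.databases),
            method=self.method,
            id_table=self.id_table,
            seed=self.seed,
        )
        self.trajectory_ = stepwise_optimize(space, goal, ctx)
        self.best_config_ = dict(self.trajectory_.final_config)
        self.default_objective_ = self.trajectory_.default_objective
        self.optimized_objective_ = self.trajectory_.optimized_objective
        self.overoptimism_ = overoptimism(self.trajectory_)
        return self
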