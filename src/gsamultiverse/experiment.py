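"""Study grid: enumerate optimization settings, run them, summarize.

One *optimization setting* is a unique combination of (goal, data set,
label assignment, GSA method, and — for the target-set goals — one of two
target gene sets).  The reference grid mirrors the published study design:
three goals, two data sets, ten random label permutations plus the true
labels, seven methods of which three are "manual-only" web tools excluded
from the rank goal, and two target sets per method/data set for the
target-set goals — 638 settings in total.

Each setting runs one greedy stepwise optimization; the study runner is
resumable (settings already on disk are skipped byte-identically) and every
setting derives its own child seed from the master seed so any single
setting can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import (
    LabelAssignment,
    SimulationSpec,
    SyntheticStudy,
    child_seed,
    make_study_data,
    permute_labels,
)
from .gsa import MethodSpec
from .optimize import (
    Goal,
    PipelineContext,
    build_choice_space,
    overoptimism,
    stepwise_optimize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MethodEntry",
    "DatasetSpec",
    "StudyDesign",
    "Setting",
    "reference_study_design",
    "enumerate_settings",
    "run_study",
    "summarize",
]


@dataclass(frozen=True)
class MethodEntry:
    """One GSA method slot in the design.

    ``manual_only`` marks methods that would have to be driven by hand
    through a web interface; those are excluded from the rank goal.
    """

    name: str
    spec: MethodSpec
    manual_only: bool = False


@dataclass(frozen=True)
class DatasetSpec:
    """A named synthetic data source: a simulation spec plus database shape."""

    name: str
    sim: SimulationSpec
    n_sets: int = 50
    set_size_range: tuple[int, int] = (10, 60)
    overlap_fraction: float = 0.2
    duplicate_fraction: float = 0.1
    n_databases: int = 2
    block_aligned: bool = False


@dataclass(frozen=True)
class StudyDesign:
    goals: tuple[str, ...]
    datasets: tuple[DatasetSpec, ...]
    methods: tuple[MethodEntry, ...]
    n_label_permutations: int = 10
    include_true_labels: bool = True
    n_target_sets: int = 2
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_label_permutations < 0:
            raise ValueError("n_label_permutations must be >= 0")


@dataclass(frozen=True)
class Setting:
    """One enumerated optimization setting with its derived child seed."""

    setting_id: str
    goal: str
    dataset: str
    label_origin: str  # "true" or "permNN"
    method: str
    target_set: str | None
    seed: int


def reference_study_design(master_seed: int = 0, n_genes: int = 2000) -> StudyDesign:
    """The full-size grid: 3 goals x 2 data sets x 11 labelings x 7 methods.

    The seven method slots instantiate the four archetypes under the
    conventions of the popular tools they stand in for: three ORA variants
    (one web-based), a frequency-weighted FCS, a sample-permutation GSEA
    (R-package convention, BH 0.05), and the two web GSEA tools (q < 0.25),
    of which the preranked one uses the gene-permutation null.
    """
    sims = tuple(
        DatasetSpec(
            name=f"ds{i + 1}",
            sim=SimulationSpec(
                n_genes=n_genes,
                samples_per_group=(10, 10) if i == 0 else (11, 10),
                within_block_correlation=0.6,
                seed=child_seed(master_seed, 1000 + i),
            ),
            block_aligned=True,
        )
        for i in range(2)
    )
    methods = (
        MethodEntry("ora_r1", MethodSpec(archetype="ora")),
        MethodEntry("ora_r2", MethodSpec(archetype="ora")),
        MethodEntry("ora_web", MethodSpec(archetype="ora"), manual_only=True),
        MethodEntry("weighted_fcs", MethodSpec(archetype="weighted_fcs")),
        MethodEntry("gsea_r", MethodSpec(archetype="gsea_sample_perm")),
        MethodEntry(
            "gsea_web",
            MethodSpec(archetype="gsea_sample_perm", threshold=0.25, threshold_on="q"),
            manual_only=True,
        ),
        MethodEntry(
            "gsea_preranked_web",
            MethodSpec(archetype="gsea_preranked", threshold=0.25, threshold_on="q"),
            manual_only=True,
        ),
    )
    return StudyDesign(
        goals=("max_degs", "min_adj_p", "min_rank"),
        datasets=sims,
        methods=methods,
        n_label_permutations=10,
        include_true_labels=True,
        n_target_sets=2,
        master_seed=master_seed,
    )


def _setting_seed(master_seed: int, descriptor: str) -> int:
    digest = hashlib.sha256(f"{master_seed}|{descriptor}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _target_names(design: StudyDesign) -> list[str]:
    # Database set names are deterministic ("set0001", ...), so targets can
    # be enumerated without generating the data.
    return [f"set{i + 1:04d}" for i in range(design.n_target_sets)]


def enumerate_settings(design: StudyDesign) -> list[Setting]:
    """Cartesian product per goal, with the manual-only exclusion for ranks."""
    label_origins = (["true"] if design.include_true_labels else []) + [
        f"perm{i + 1:02d}" for i in range(design.n_label_permutations)
    ]
    settings: list[Setting] = []
    for goal in design.goals:
        methods = [
            m for m in design.methods if not (goal == "min_rank" and m.manual_only)
        ]
        targets = _target_names(design) if goal in ("min_adj_p", "min_rank") else [None]
        for ds in design.datasets:
            for origin in label_origins:
                for m in methods:
                    for tgt in targets:
                        descriptor = f"{goal}|{ds.name}|{origin}|{m.name}|{tgt or '-'}"
                        settings.append(
                            Setting(
                                setting_id=descriptor.replace("|", "__"),
                                goal=goal,
                                dataset=ds.name,
                                label_origin=origin,
                                method=m.name,
                                target_set=tgt,
                                seed=_setting_seed(design.master_seed, descriptor),
                            )
                        )
    return settings


def _build_dataset(design: StudyDesign, ds: DatasetSpec) -> tuple[SyntheticStudy, list[LabelAssignment]]:
    study = make_study_data(
        ds.sim,
        n_sets=ds.n_sets,
        set_size_range=ds.set_size_range,
        overlap_fraction=ds.overlap_fraction,
        duplicate_fraction=ds.duplicate_fraction,
        n_databases=ds.n_databases,
        block_aligned=ds.block_aligned,
    )
    perms = (
        permute_labels(study.labels, design.n_label_permutations, seed=ds.sim.seed)
        if design.n_label_permutations > 0
        else []
    )
    return study, perms


def run_study(
    design: StudyDesign,
    outdir: str | Path,
    settings: Sequence[Setting] | None = None,
) -> pd.DataFrame:
    """Run one stepwise optimization per setting; write records incrementally.

    Per-setting trajectory files live under ``<outdir>/trajectories``;
    settings whose trajectory file already exists are skipped, which makes
    an interrupted study resumable with identical results.  Per-setting
    failures are recorded with a status, never abort the study.
    """
    outdir = Path(outdir)
    traj_dir = outdir / "trajectories"
    traj_dir.mkdir(parents=True, exist_ok=True)
    all_settings = enumerate_settings(design)
    if settings is None:
        settings = all_settings
    by_name = {m.name: m for m in design.methods}
    ds_by_name = {d.name: d for d in design.datasets}

    pd.DataFrame([dataclasses.asdict(s) for s in all_settings]).to_csv(
        outdir / "settings.tsv", sep="\t", index=False
    )

    cache: dict[str, tuple[SyntheticStudy, list[LabelAssignment]]] = {}
    rows = []
    for setting in settings:
        record_path = traj_dir / f"{setting.setting_id}.json"
        if record_path.exists():
            rows.append(json.loads(record_path.read_text())["record"])
            continue
        if setting.dataset not in cache:
            cache[setting.dataset] = _build_dataset(design, ds_by_name[setting.dataset])
        study, perms = cache[setting.dataset]
        if setting.label_origin == "true":
            labels = study.labels
        else:
            labels = perms[int(setting.label_origin.removeprefix("perm")) - 1]
        entry = by_name[setting.method]
        goal = Goal(kind=setting.goal, target_set=setting.target_set)
        ctx = PipelineContext(
            counts=study.counts,
            labels=labels,
            databases=study.databases,
            method=entry.spec,
            id_table=study.id_table,
            seed=setting.seed,
        )
        space = build_choice_space(list(study.databases), entry.spec)
        record = {
            "setting_id": setting.setting_id,
            "goal": setting.goal,
            "dataset": setting.dataset,
            "label_origin": setting.label_origin,
            "method": setting.method,
            "target_set": setting.target_set,
        }
        try:
            traj = stepwise_optimize(space, goal, ctx)
            rec = overoptimism(traj)
            record.update(
                status="ok",
                default_objective=rec.default_objective,
                optimized_objective=rec.optimized_objective,
                delta=rec.delta,
                changed_steps=",".join(rec.changed_steps),
            )
            payload = {"record": record, "trajectory": traj.to_dict()}
        except Exception as exc:
            logger.warning("setting %s failed: %s", setting.setting_id, exc)
            record.update(
                status=f"failed: {exc}",
                default_objective=None,
                optimized_objective=None,
                delta=None,
                changed_steps="",
            )
            payload = {"record": record, "trajectory": None}
        record_path.write_text(json.dumps(payload, indent=1))
        rows.append(record)

    records = pd.DataFrame(rows)
    records.to_csv(outdir / "records.tsv", sep="\t", index=False)
    return records


def summarize(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Default-vs-optimized summaries per (goal, method, label-origin class).

    Returns the objective comparison table (the quantities plotted in the
    study's per-goal figures), the fraction of settings with any
    improvement, and per-step change frequencies showing which choices
    trigger improvements.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    df = records[records["status"] == "ok"].copy()
    df["origin_class"] = np.where(df["label_origin"] == "true", "true", "permuted")
    df["improved"] = df["delta"] > 0

    objectives = (
        df.groupby(["goal", "method", "origin_class"])
        .agg(
            n=("setting_id", "count"),
            mean_default=("default_objective", "mean"),
            mean_optimized=("optimized_objective", "mean"),
            mean_delta=("delta", "mean"),
            improvement_fraction=("improved", "mean"),
        )
        .reset_index()
    )

    changes = []
    for _, row in df.iterrows():
        for step in filter(None, str(row["changed_steps"]).split(",")):
            changes.append((row["goal"], row["method"], step))
    step_changes = (
        pd.DataFrame(changes, columns=["goal", "method", "step"])
        .value_counts()
        .rename("n_settings_changed")
        .reset_index()
        if changes
        else pd.DataFrame(columns=["goal", "method", "step", "n_settings_changed"])
    )
    return {"objectives": objectives, "step_changes": step_changes}
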