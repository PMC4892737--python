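"""Template-driven workflow engine.

A phenotyping run is fully parameterised by three JSON templates:

* **loading** — the crawler path template, plus (optionally) a metadata CSV
  and its key column;
* **processing** — one job list per image type.  Each job names a registered
  operation, its arguments, and the *slots* it reads and writes.  The
  reserved slot ``raw`` is the image as loaded from disk.  Dependencies are
  inferred from slot wiring, never from list order, so the declared order
  of jobs is documentation only;
* **configuration** — executor settings: concurrency, output root, seed.

The engine validates the templates (reporting *all* violations at once),
expands the per-type job lists into one task per (image, job), executes the
resulting DAG with a thread pool, writes each image's trait rows to its own
worker database, and finally aggregates the worker databases into a single
results database — results are bit-identical whatever the concurrency
level or completion order.  This is an in-process scheduler honouring the
same template contract a distributed grid executor would.
"""

from __future__ import annotations

import concurrent.futures
import graphlib
import json
import os
import shutil
import sqlite3
import threading
import time
import traceback
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import imops, traits
from .crawler import ImageRecord, PathTemplate, crawl, join_metadata, load_database
from .errors import PhenopipeError, SchemaError, TemplateError
from .imgio import read_image, write_image

__all__ = [
    "OPERATIONS",
    "Job",
    "WorkflowSpec",
    "ExecutionPlan",
    "validate_templates",
    "build_plan",
    "execute",
    "aggregate",
    "run",
]

# ---------------------------------------------------------------------------
# Operation registry
# ---------------------------------------------------------------------------

RAW_SLOT = "raw"


@dataclass(frozen=True)
class _OpSpec:
    func: Callable
    n_image_inputs: int = 1
    produces_image: bool = True


def _op_crop(image, *, roi):
    return imops.crop(image, roi)


def _op_color_filter(image, *, expr, roi=None):
    return imops.color_filter(image, expr, roi)


def _op_contour_chop(image, *, min_area):
    return imops.contour_chop(image, min_area)


def _op_morph_open(image, *, kernel=3, iterations=1):
    return imops.morphological_open(image, kernel, iterations)


def _op_contour_cut(image, *, min_area, padding=0):
    cropped, _roi = imops.contour_cut(image, min_area, padding)
    return cropped


#: Operation names usable in processing templates.  camelCase aliases match
#: the conventional workflow vocabulary of phenotyping pipelines.
OPERATIONS: dict[str, _OpSpec] = {
    "crop": _OpSpec(_op_crop),
    "colorFilter": _OpSpec(_op_color_filter),
    "contourChop": _OpSpec(_op_contour_chop),
    "morphologicalOpen": _OpSpec(_op_morph_open),
    "contourCut": _OpSpec(_op_contour_cut),
    "extract": _OpSpec(None, produces_image=False),  # handled specially
}

DEFAULT_METRICS = ("dimensions", "area", "moments", "hull", "histogram")


def extract_metrics(image: np.ndarray, metrics=DEFAULT_METRICS, bins: int = 8) -> dict[str, float]:
    """Compute the requested per-image metric groups on the binary support."""
    mask = imops.to_binary(image)
    out: dict[str, float] = {}
    for metric in metrics:
        if metric == "area":
            out["area"] = float(traits.pixel_area(mask))
        elif metric == "dimensions":
            if mask.any():
                h, w = traits.dimensions(mask)
                out["height"], out["width"] = float(h), float(w)
        elif metric == "moments":
            for name, v in traits.raw_moments(mask).as_dict().items():
                out[name] = float(v)
        elif metric == "hull":
            if mask.any():
                ch, den = traits.convex_hull_metrics(mask)
                out["hull_area"], out["density"] = float(ch), den
        elif metric == "histogram":
            hist = traits.color_histogram(image, mask, bins=bins)
            for c, chan in enumerate("rgb"):
                for b in range(hist.bins_per_channel):
                    out[f"hist_{chan}_{b}"] = float(hist.counts[c, b])
        else:
            raise PhenopipeError(f"unknown metric group {metric!r}")
    return out


# ---------------------------------------------------------------------------
# Template validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Job:
    name: str
    operation: str
    arguments: dict
    inputs: dict  # parameter -> slot name
    outputs: dict  # parameter -> slot name


@dataclass
class WorkflowSpec:
    workflows: dict[str, list[Job]]
    loading: PathTemplate
    metadata_csv: Optional[str]
    key_column: str
    max_concurrent: int
    output_root: str
    seed: int


def _validate_workflow(imtype: str, raw_jobs: list, violations: list[str]) -> list[Job]:
    jobs: list[Job] = []
    names: set[str] = set()
    producers: dict[str, str] = {}
    for k, rj in enumerate(raw_jobs):
        name = rj.get("name", f"job[{k}]")
        op = rj.get("operation")
        if name in names:
            violations.append(f"processing/{imtype}/{name}: duplicate job name")
        names.add(name)
        if op not in OPERATIONS:
            violations.append(f"processing/{imtype}/{name}: unknown operation {op!r}")
        inputs = dict(rj.get("inputs", {}))
        outputs = dict(rj.get("outputs", {}))
        if op in OPERATIONS and OPERATIONS[op].produces_image and not outputs:
            violations.append(f"processing/{imtype}/{name}: operation {op!r} declares no output slot")
        if not inputs:
            violations.append(f"processing/{imtype}/{name}: no input slot")
        for slot in outputs.values():
            if slot == RAW_SLOT:
                violations.append(f"processing/{imtype}/{name}: cannot write reserved slot 'raw'")
            elif slot in producers:
                violations.append(
                    f"processing/{imtype}/{name}: slot {slot!r} already produced by {producers[slot]}"
                )
            else:
                producers[slot] = name
        jobs.append(Job(name=name, operation=op, arguments=dict(rj.get("arguments", {})),
                        inputs=inputs, outputs=outputs))
    for job in jobs:
        for slot in job.inputs.values():
            if slot != RAW_SLOT and slot not in producers:
                violations.append(
                    f"processing/{imtype}/{job.name}: dangling input slot {slot!r}"
                )
    # cycle check on slot wiring
    graph = {
        job.name: {
            producers[slot]
            for slot in job.inputs.values()
            if slot in producers and producers[slot] != job.name
        }
        for job in jobs
    }
    try:
        graphlib.TopologicalSorter(graph).prepare()
    except graphlib.CycleError as exc:
        violations.append(f"processing/{imtype}: cycle among jobs {exc.args[1]}")
    return jobs


def validate_templates(loading: dict, processing: dict, config: dict) -> WorkflowSpec:
    """Validate the three templates together; raise :class:`TemplateError`
    with the complete violation list on any problem."""
    violations: list[str] = []
    template = None
    try:
        template = PathTemplate.from_dict(loading)
    except TemplateError as exc:
        violations.extend(exc.violations)

    raw_workflows = processing.get("workflows")
    workflows: dict[str, list[Job]] = {}
    if not isinstance(raw_workflows, dict) or not raw_workflows:
        violations.append("processing: missing or empty 'workflows' mapping")
    else:
        for imtype, raw_jobs in raw_workflows.items():
            if not isinstance(raw_jobs, list) or not raw_jobs:
                violations.append(f"processing/{imtype}: job list missing or empty")
                continue
            workflows[imtype] = _validate_workflow(imtype, raw_jobs, violations)

    max_concurrent = config.get("max_concurrent", 1)
    if not isinstance(max_concurrent, int) or max_concurrent < 1:
        violations.append("config/max_concurrent: must be an integer >= 1")
    output_root = config.get("output_root", ".")
    seed = config.get("seed", 0)
    if not isinstance(seed, int):
        violations.append("config/seed: must be an integer")

    if violations:
        raise TemplateError(violations)
    return WorkflowSpec(
        workflows=workflows,
        loading=template,
        metadata_csv=loading.get("metadata"),
        key_column=loading.get("key_column", "id"),
        max_concurrent=max_concurrent,
        output_root=output_root,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Plan construction
# ---------------------------------------------------------------------------


@dataclass
class Task:
    index: int
    record: ImageRecord
    record_index: int
    job: Job
    state: str = "pending"  # pending | running | done | failed | skipped
    message: str = ""


@dataclass
class ExecutionPlan:
    tasks: list[Task]
    edges: list[tuple[int, int]]  # (upstream task index, downstream task index)
    unknown_imtype: list[ImageRecord]

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    def successors(self) -> dict[int, list[int]]:
        succ: dict[int, list[int]] = {t.index: [] for t in self.tasks}
        for a, b in self.edges:
            succ[a].append(b)
        return succ

    def predecessors(self) -> dict[int, list[int]]:
        pred: dict[int, list[int]] = {t.index: [] for t in self.tasks}
        for a, b in self.edges:
            pred[b].append(a)
        return pred


def build_plan(spec: WorkflowSpec, records: list[ImageRecord]) -> ExecutionPlan:
    """One task per (record, job of its image type's workflow); edges follow
    slot wiring.  Records whose imtype has no workflow are excluded and
    reported on the plan, never silently dropped."""
    tasks: list[Task] = []
    edges: list[tuple[int, int]] = []
    unknown: list[ImageRecord] = []
    for rec_idx, rec in enumerate(records):
        jobs = spec.workflows.get(rec.imtype)
        if jobs is None:
            unknown.append(rec)
            continue
        producers: dict[str, int] = {}
        base = len(tasks)
        for j, job in enumerate(jobs):
            t = Task(index=base + j, record=rec, record_index=rec_idx, job=job)
            tasks.append(t)
            for slot in job.outputs.values():
                producers[slot] = t.index
        for j, job in enumerate(jobs):
            for slot in job.inputs.values():
                if slot in producers:
                    edges.append((producers[slot], base + j))
    return ExecutionPlan(tasks=tasks, edges=sorted(set(edges)), unknown_imtype=unknown)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

_WORKER_DDL = """
CREATE TABLE IF NOT EXISTS traits (
    path TEXT NOT NULL,
    id TEXT NOT NULL,
    imtype TEXT NOT NULL,
    angle TEXT,
    timestamp TEXT,
    trait TEXT NOT NULL,
    value REAL NOT NULL
);
CREATE TABLE IF NOT EXISTS tasks (
    path TEXT NOT NULL,
    job TEXT NOT NULL,
    status TEXT NOT NULL,
    message TEXT NOT NULL
);
"""


class _RecordContext:
    """Mutable per-image state shared by that image's tasks."""

    def __init__(self, record: ImageRecord, worker_db: Path):
        self.record = record
        self.worker_db = worker_db
        self.slots: dict[str, np.ndarray] = {}
        self.trait_rows: list[tuple] = []
        self.lock = threading.Lock()

    def get_slot(self, slot: str) -> np.ndarray:
        with self.lock:
            if slot == RAW_SLOT and RAW_SLOT not in self.slots:
                self.slots[RAW_SLOT] = read_image(self.record.path)
            return self.slots[slot]


def _run_task(task: Task, ctx: _RecordContext, image_dir: Optional[Path],
              consumed: set[str]) -> None:
    job = task.job
    inputs = {param: ctx.get_slot(slot) for param, slot in job.inputs.items()}
    if job.operation == "extract":
        (image,) = inputs.values()
        metrics = extract_metrics(
            image,
            metrics=job.arguments.get("metrics", DEFAULT_METRICS),
            bins=job.arguments.get("bins", 8),
        )
        rec = ctx.record
        with ctx.lock:
            for trait_name in sorted(metrics):
                ctx.trait_rows.append(
                    (rec.path, rec.id, rec.imtype, rec.angle, rec.timestamp,
                     trait_name, metrics[trait_name])
                )
        return
    spec = OPERATIONS[job.operation]
    kwargs = {k: v for k, v in job.arguments.items() if k != "save"}
    result = spec.func(*inputs.values(), **kwargs)
    out_slots = list(job.outputs.values())
    with ctx.lock:
        for slot in out_slots:
            ctx.slots[slot] = result
    if image_dir is not None:
        rec = ctx.record
        for slot in out_slots:
            if slot not in consumed or task.job.arguments.get("save"):
                stem = "_".join(
                    str(p) for p in (rec.id, rec.imtype, rec.angle, slot) if p is not None
                )
                write_image(image_dir / f"{stem}.png", result)


def execute(
    plan: ExecutionPlan,
    output_dir: str | os.PathLike,
    max_concurrent: int = 1,
) -> list[Path]:
    """Run every task of the plan; returns the list of worker database paths.

    A task failure marks only its descendants ``skipped``; everything else
    proceeds.  One worker database per image record mirrors the
    write-locally-then-aggregate pattern of distributed execution and keeps
    trait writes concurrency-safe.  Final (unconsumed) image slots are saved
    as PNG under ``output_dir/images``.
    """
    output_dir = Path(output_dir)
    worker_dir = output_dir / "workers"
    image_dir = output_dir / "images"
    worker_dir.mkdir(parents=True, exist_ok=True)
    image_dir.mkdir(parents=True, exist_ok=True)

    contexts: dict[int, _RecordContext] = {}
    for t in plan.tasks:
        if t.record_index not in contexts:
            contexts[t.record_index] = _RecordContext(
                t.record, worker_dir / f"worker_{t.record_index:05d}.db"
            )
    # a slot is "final" (worth saving as PNG) unless some image-producing
    # job consumes it further; extract-only consumers do not count
    consumed_by_rec: dict[int, set[str]] = {t.record_index: set() for t in plan.tasks}
    for t in plan.tasks:
        if t.job.operation != "extract":
            consumed_by_rec[t.record_index].update(t.job.inputs.values())

    pred = plan.predecessors()
    succ = plan.successors()
    remaining = {t.index: len(pred[t.index]) for t in plan.tasks}
    done_lock = threading.Lock()
    ready = [i for i, n in remaining.items() if n == 0]

    def mark_skipped(idx: int) -> None:
        for nxt in succ[idx]:
            t = plan.tasks[nxt]
            if t.state == "pending":
                t.state = "skipped"
                t.message = f"upstream task {plan.tasks[idx].job.name} failed"
                mark_skipped(nxt)

    with concurrent.futures.ThreadPoolExecutor(max_workers=max_concurrent) as pool:
        futures: dict[concurrent.futures.Future, int] = {}

        def submit(idx: int) -> None:
            t = plan.tasks[idx]
            t.state = "running"
            fut = pool.submit(
                _run_task, t, contexts[t.record_index], image_dir,
                consumed_by_rec[t.record_index],
            )
            futures[fut] = idx

        for idx in ready:
            submit(idx)
        while futures:
            done, _ = concurrent.futures.wait(
                futures, return_when=concurrent.futures.FIRST_COMPLETED
            )
            for fut in done:
                idx = futures.pop(fut)
                t = plan.tasks[idx]
                exc = fut.exception()
                with done_lock:
                    if exc is None:
                        t.state = "done"
                        for nxt in succ[idx]:
                            remaining[nxt] -= 1
                            if remaining[nxt] == 0 and plan.tasks[nxt].state == "pending":
                                submit(nxt)
                    else:
                        t.state = "failed"
                        t.message = "".join(
                            traceback.format_exception_only(type(exc), exc)
                        ).strip()
                        mark_skipped(idx)

    # persist per-record worker databases (traits + task statuses)
    worker_dbs: list[Path] = []
    tasks_by_rec: dict[int, list[Task]] = {}
    for t in plan.tasks:
        tasks_by_rec.setdefault(t.record_index, []).append(t)
    for rec_idx in sorted(contexts):
        ctx = contexts[rec_idx]
        con = sqlite3.connect(ctx.worker_db)
        try:
            con.executescript(_WORKER_DDL)
            con.executemany(
                "INSERT INTO traits VALUES (?, ?, ?, ?, ?, ?, ?)",
                sorted(ctx.trait_rows),
            )
            con.executemany(
                "INSERT INTO tasks VALUES (?, ?, ?, ?)",
                [
                    (t.record.path, t.job.name, t.state, t.message)
                    for t in tasks_by_rec[rec_idx]
                ],
            )
            con.commit()
        finally:
            con.close()
        worker_dbs.append(ctx.worker_db)
    return worker_dbs


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def _schema(con: sqlite3.Connection) -> dict[str, list[str]]:
    tables = [
        r[0]
        for r in con.execute(
            "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
        )
    ]
    return {
        t: [(c[1], c[2]) for c in con.execute(f"PRAGMA table_info({t})")]
        for t in tables
    }


def aggregate(
    worker_dbs: list[str | os.PathLike], final_db: str | os.PathLike
) -> dict[str, int]:
    """Combine all worker databases into one final database.

    All workers must share one schema (error names the divergent table or
    column otherwise).  No row is mutated; per-table final row counts — the
    sum over workers — are returned.  The result is independent of the
    order in which workers are given: tables are filled in sorted row order.
    """
    if not worker_dbs:
        return {}
    schemas = []
    for db in worker_dbs:
        con = sqlite3.connect(db)
        try:
            schemas.append(_schema(con))
        finally:
            con.close()
    ref = schemas[0]
    for db, sch in zip(worker_dbs[1:], schemas[1:]):
        if set(sch) != set(ref):
            raise SchemaError(
                f"worker {db}: tables {sorted(sch)} != expected {sorted(ref)}"
            )
        for t in ref:
            if sch[t] != ref[t]:
                raise SchemaError(
                    f"worker {db}: table {t!r} columns {sch[t]} != expected {ref[t]}"
                )

    rows: dict[str, list[tuple]] = {t: [] for t in ref}
    for db in worker_dbs:
        con = sqlite3.connect(db)
        try:
            for t in ref:
                rows[t].extend(con.execute(f"SELECT * FROM {t}"))
        finally:
            con.close()

    out = sqlite3.connect(final_db)
    try:
        for t, cols in ref.items():
            colspec = ", ".join(f"{name} {ctype}" for name, ctype in cols)
            out.execute(f"CREATE TABLE IF NOT EXISTS {t} ({colspec})")
            placeholders = ", ".join("?" for _ in cols)
            out.executemany(
                f"INSERT INTO {t} VALUES ({placeholders})",
                sorted(rows[t], key=lambda r: tuple(str(v) for v in r)),
            )
        out.commit()
    finally:
        out.close()
    return {t: len(rows[t]) for t in ref}


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------


def _timestamped_dir(root: Path) -> Path:
    stamp = time.strftime("%Y-%m-%d_%H-%M-%S")
    candidate = root / f"run_{stamp}"
    k = 1
    while candidate.exists():
        candidate = root / f"run_{stamp}_{k}"
        k += 1
    candidate.mkdir(parents=True)
    return candidate


def run(
    loading_path: str | os.PathLike,
    processing_path: str | os.PathLike,
    config_path: str | os.PathLike,
    image_root: Optional[str | os.PathLike] = None,
    max_concurrent: Optional[int] = None,
) -> Path:
    """Full pipeline: crawl → join → load → plan → execute → aggregate.

    Creates a date-and-time-stamped directory under the configured output
    root containing the final database (tables ``images``, ``traits``,
    ``tasks``), verbatim copies of the three templates, and the metadata
    CSV.  Returns the directory path.  Raises when the crawl finds no
    processable image.
    """
    with open(loading_path) as fh:
        loading = json.load(fh)
    with open(processing_path) as fh:
        processing = json.load(fh)
    with open(config_path) as fh:
        config = json.load(fh)
    if image_root is not None:
        loading = {**loading, "base_path": str(image_root)}
    spec = validate_templates(loading, processing, config)
    if max_concurrent is not None:
        spec.max_concurrent = max_concurrent

    result = crawl(spec.loading)
    records = result.records
    if spec.metadata_csv:
        csv_path = Path(spec.metadata_csv)
        if not csv_path.is_absolute():
            csv_path = Path(spec.loading.base_path) / csv_path
        table = pd.read_csv(csv_path, dtype=str)
        records, _unmatched = join_metadata(records, table, spec.key_column)
    else:
        csv_path = None

    out_dir = _timestamped_dir(Path(spec.output_root))
    for src in (loading_path, processing_path, config_path):
        shutil.copy(src, out_dir / Path(src).name)
    if csv_path is not None:
        shutil.copy(csv_path, out_dir / csv_path.name)

    final_db = out_dir / "results.db"
    load_database(records, final_db)

    if not records:
        raise PhenopipeError(
            f"no images found under {spec.loading.base_path} "
            f"({len(result.skipped)} files skipped); outputs in {out_dir}"
        )
    plan = build_plan(spec, records)
    worker_dbs = execute(plan, out_dir, max_concurrent=spec.max_concurrent)
    counts = aggregate(worker_dbs, final_db)
    (out_dir / "aggregate_counts.json").write_text(json.dumps(counts, indent=2))
    return out_dir
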