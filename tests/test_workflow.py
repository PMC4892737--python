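"""Workflow engine: template validation, DAG expansion, execution, aggregation."""

import json
import sqlite3

import pandas as pd
import pytest

from phenopipe.crawler import ImageRecord
from phenopipe.errors import PhenopipeError, SchemaError, TemplateError
from phenopipe.workflow import (
    aggregate,
    build_plan,
    execute,
    run,
    validate_templates,
)

from conftest import STANDARD_WORKFLOW, write_templates

LOADING = {"base_path": ".", "pattern": ["{id}_{date}", "{imtype}", "{angle}.png"]}
CONFIG = {"max_concurrent": 1, "output_root": ".", "seed": 0}


def processing(jobs, imtypes=("rgbsv",)):
    return {"workflows": {t: jobs for t in imtypes}}


def trait_frame(db):
    con = sqlite3.connect(db)
    try:
        return pd.read_sql_query(
            "SELECT path, trait, value FROM traits ORDER BY path, trait", con
        )
    finally:
        con.close()


class TestValidation:
    def test_linear_pipeline_valid(self):
        spec = validate_templates(LOADING, processing(STANDARD_WORKFLOW), CONFIG)
        assert list(spec.workflows) == ["rgbsv"]
        assert [j.name for j in spec.workflows["rgbsv"]] == [
            "filter", "chop", "cut", "extract",
        ]

    def test_dangling_input_reported(self):
        jobs = [
            {"name": "cut", "operation": "contourCut", "arguments": {"min_area": 0},
             "inputs": {"image": "nonexistent"}, "outputs": {"image": "final"}},
        ]
        with pytest.raises(TemplateError, match="dangling input"):
            validate_templates(LOADING, processing(jobs), CONFIG)

    def test_cycle_reported(self):
        jobs = [
            {"name": "a", "operation": "contourChop", "arguments": {"min_area": 0},
             "inputs": {"image": "y"}, "outputs": {"image": "x"}},
            {"name": "b", "operation": "contourChop", "arguments": {"min_area": 0},
             "inputs": {"image": "x"}, "outputs": {"image": "y"}},
        ]
        with pytest.raises(TemplateError, match="cycle"):
            validate_templates(LOADING, processing(jobs), CONFIG)

    def test_all_violations_collected(self):
        jobs = [
            {"name": "a", "operation": "noSuchOp",
             "inputs": {"image": "missing"}, "outputs": {"image": "x"}},
            {"name": "a", "operation": "contourChop", "arguments": {"min_area": 0},
             "inputs": {"image": "raw"}, "outputs": {"image": "x"}},
        ]
        with pytest.raises(TemplateError) as exc:
            validate_templates(LOADING, processing(jobs), {"max_concurrent": 0})
        text = str(exc.value)
        for fragment in ("unknown operation", "duplicate job name",
                         "already produced", "max_concurrent"):
            assert fragment in text


def _records(n, imtype="rgbsv"):
    return [
        ImageRecord(id=f"p{i:03d}", imtype=imtype, path=f"/img/{i}.png", angle="0")
        for i in range(n)
    ]


class TestPlan:
    def test_task_and_edge_counts(self):
        spec = validate_templates(LOADING, processing(STANDARD_WORKFLOW), CONFIG)
        plan = build_plan(spec, _records(10))
        assert plan.n_tasks == 40
        assert len(plan.edges) == 30  # 3 data dependencies per image

    def test_reversed_job_list_same_dag(self):
        spec_fwd = validate_templates(LOADING, processing(STANDARD_WORKFLOW), CONFIG)
        spec_rev = validate_templates(
            LOADING, processing(list(reversed(STANDARD_WORKFLOW))), CONFIG
        )
        recs = _records(3)
        plan_fwd = build_plan(spec_fwd, recs)
        plan_rev = build_plan(spec_rev, recs)

        def canonical(plan):
            names = {t.index: (t.record.path, t.job.name) for t in plan.tasks}
            return sorted((names[a], names[b]) for a, b in plan.edges)

        assert canonical(plan_fwd) == canonical(plan_rev)

    def test_zero_records_empty_plan(self):
        spec = validate_templates(LOADING, processing(STANDARD_WORKFLOW), CONFIG)
        plan = build_plan(spec, [])
        assert plan.n_tasks == 0 and plan.edges == []

    def test_unknown_imtype_excluded_and_reported(self):
        spec = validate_templates(LOADING, processing(STANDARD_WORKFLOW), CONFIG)
        recs = _records(2) + _records(1, imtype="fluosv")
        plan = build_plan(spec, recs)
        assert plan.n_tasks == 8
        assert [r.imtype for r in plan.unknown_imtype] == ["fluosv"]


class TestExecution:
    def test_failure_blocks_only_descendants(self, fixture_tree, tmp_path):
        """A bad filter expression fails that task; downstream tasks are
        skipped, the upstream crop-equivalent is preserved."""
        root, manifest = fixture_tree
        jobs = [
            {"name": "pre", "operation": "contourChop", "arguments": {"min_area": 0},
             "inputs": {"image": "raw"}, "outputs": {"image": "pre"}},
            {"name": "filter", "operation": "colorFilter",
             "arguments": {"expr": "q > b"},  # unknown operand -> parse error
             "inputs": {"image": "pre"}, "outputs": {"image": "filtered"}},
            {"name": "cut", "operation": "contourCut", "arguments": {"min_area": 0},
             "inputs": {"image": "filtered"}, "outputs": {"image": "final"}},
            {"name": "extract", "operation": "extract",
             "inputs": {"image": "final"}, "outputs": {}},
        ]
        loading = dict(manifest["template"])
        spec = validate_templates(
            loading, {"workflows": {"rgbsv": jobs, "rgbtv": jobs}}, CONFIG
        )
        from phenopipe.crawler import PathTemplate, crawl

        records = crawl(PathTemplate.from_dict(loading)).records[:2]
        plan = build_plan(spec, records)
        execute(plan, tmp_path / "out", max_concurrent=2)
        states = {(t.record.path, t.job.name): t.state for t in plan.tasks}
        for rec in records:
            assert states[(rec.path, "pre")] == "done"
            assert states[(rec.path, "filter")] == "failed"
            assert states[(rec.path, "cut")] == "skipped"
            assert states[(rec.path, "extract")] == "skipped"

    def test_empty_plan_succeeds(self, tmp_path):
        spec = validate_templates(LOADING, processing(STANDARD_WORKFLOW), CONFIG)
        plan = build_plan(spec, [])
        assert execute(plan, tmp_path / "out") == []


class TestRun:
    def test_output_directory_contract(self, fixture_tree, tmp_path):
        root, manifest = fixture_tree
        paths = write_templates(tmp_path, manifest["template"], output_root=tmp_path / "o")
        out_dir = run(*paths)
        names = {p.name for p in out_dir.iterdir()}
        assert {"loading.json", "processing.json", "config.json",
                "metadata.csv", "results.db"} <= names
        con = sqlite3.connect(out_dir / "results.db")
        tables = {r[0] for r in con.execute(
            "SELECT name FROM sqlite_master WHERE type='table'")}
        assert {"images", "traits", "tasks"} <= tables
        n_images = con.execute("SELECT COUNT(*) FROM images").fetchone()[0]
        assert n_images == 18
        n_traits = con.execute("SELECT COUNT(*) FROM traits").fetchone()[0]
        assert n_traits == 18 * 45  # 45 metrics per image with default groups
        con.close()

    def test_rerun_creates_new_directory(self, fixture_tree, tmp_path):
        root, manifest = fixture_tree
        paths = write_templates(tmp_path, manifest["template"], output_root=tmp_path / "o")
        first = run(*paths)
        marker = (first / "results.db").stat().st_mtime_ns
        second = run(*paths)
        assert first != second
        assert (first / "results.db").stat().st_mtime_ns == marker

    def test_no_images_is_an_error(self, tmp_path):
        empty = tmp_path / "empty"
        empty.mkdir()
        template = {"base_path": str(empty), "pattern": LOADING["pattern"]}
        paths = write_templates(tmp_path, template, output_root=tmp_path / "o")
        with pytest.raises(PhenopipeError, match="no images"):
            run(*paths)

    def test_schedule_invariance(self, fixture_tree, tmp_path):
        """Concurrency 1 vs 8 yields identical sorted trait tables."""
        root, manifest = fixture_tree
        paths = write_templates(tmp_path, manifest["template"], output_root=tmp_path / "o")
        out1 = run(*paths, max_concurrent=1)
        out8 = run(*paths, max_concurrent=8)
        t1, t8 = trait_frame(out1 / "results.db"), trait_frame(out8 / "results.db")
        pd.testing.assert_frame_equal(t1, t8)


class TestAggregate:
    def _worker(self, path, rows):
        con = sqlite3.connect(path)
        con.execute("CREATE TABLE traits (path TEXT, trait TEXT, value REAL)")
        con.executemany("INSERT INTO traits VALUES (?, ?, ?)", rows)
        con.commit()
        con.close()
        return path

    def test_row_conservation(self, tmp_path):
        dbs = [
            self._worker(tmp_path / f"w{i}.db",
                         [(f"img{i}", f"t{j}", float(j)) for j in range(n)])
            for i, n in enumerate([5, 7, 0])
        ]
        counts = aggregate(dbs, tmp_path / "final.db")
        assert counts == {"traits": 12}

    def test_order_independence(self, tmp_path):
        dbs = [
            self._worker(tmp_path / f"w{i}.db",
                         [(f"img{i}", f"t{j}", i * 10.0 + j) for j in range(4)])
            for i in range(3)
        ]
        aggregate(dbs, tmp_path / "a.db")
        aggregate(list(reversed(dbs)), tmp_path / "b.db")
        a, b = trait_frame(tmp_path / "a.db"), trait_frame(tmp_path / "b.db")
        pd.testing.assert_frame_equal(a, b)
        assert (tmp_path / "a.db").read_bytes() == (tmp_path / "b.db").read_bytes()

    def test_schema_mismatch_names_divergence(self, tmp_path):
        self._worker(tmp_path / "w0.db", [])
        con = sqlite3.connect(tmp_path / "w1.db")
        con.execute("CREATE TABLE traits (path TEXT, trait TEXT, value REAL, extra TEXT)")
        con.commit()
        con.close()
        with pytest.raises(SchemaError, match="traits"):
            aggregate([tmp_path / "w0.db", tmp_path / "w1.db"], tmp_path / "final.db")
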