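"""Metadata crawler: turn a structured image tree into queryable records.

Automated high-throughput imaging platforms encode the experimental
metadata — pot/plant id, imaging date, camera perspective and type, view
angle — in the directory hierarchy itself.  The crawler walks the tree with
a declarative *path template*, binds the named captures of every matching
file into an :class:`ImageRecord`, left-joins a user-supplied CSV metadata
table on the plant id, and loads everything into a single SQLite database.

Path templates are ordered lists of path components.  Each component is a
string mixing literal text with ``{name}`` captures (``{name:regex}`` to
constrain one); e.g.::

    ["{id}_{date}", "{imtype}", "{angle}.png"]

matches ``p001_2024-01-05/rgbsv/0.png`` and binds id=p001,
date=2024-01-05, imtype=rgbsv, angle=0.  A template must capture at least
``id`` and ``imtype``.  Files that do not match are counted and reported,
never silently dropped.
"""

from __future__ import annotations

import os
import re
import sqlite3
from dataclasses import dataclass, field as dc_field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import PhenopipeError, SchemaError, TemplateError

__all__ = ["PathTemplate", "ImageRecord", "CrawlResult", "crawl", "join_metadata", "load_database"]

_CAPTURE_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_]*)(?::((?:[^{}]|\{\d+(?:,\d*)?\})*))?\}")

_DATE_FORMATS = (
    "%Y-%m-%d %H:%M:%S",
    "%Y-%m-%d_%H-%M-%S",
    "%Y-%m-%dT%H:%M:%S",
    "%Y-%m-%d",
    "%Y%m%d",
)


@dataclass(frozen=True)
class PathTemplate:
    """Declarative description of where metadata lives in the tree."""

    base_path: str
    pattern: tuple[str, ...]

    def __post_init__(self):
        names: list[str] = []
        for comp in self.pattern:
            names.extend(m.group(1) for m in _CAPTURE_RE.finditer(comp))
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TemplateError([f"loading template: duplicate capture(s) {sorted(dupes)}"])
        for required in ("id", "imtype"):
            if required not in names:
                raise TemplateError(
                    [f"loading template: pattern must capture {required!r}"]
                )

    @classmethod
    def from_dict(cls, spec: dict) -> "PathTemplate":
        try:
            return cls(base_path=spec["base_path"], pattern=tuple(spec["pattern"]))
        except KeyError as exc:
            raise TemplateError([f"loading template: missing field {exc.args[0]!r}"])

    def component_regexes(self) -> list[re.Pattern]:
        out = []
        for comp in self.pattern:
            parts: list[str] = []
            last = 0
            for m in _CAPTURE_RE.finditer(comp):
                parts.append(re.escape(comp[last : m.start()]))
                constraint = m.group(2) or "[^/]+?"
                parts.append(f"(?P<{m.group(1)}>{constraint})")
                last = m.end()
            parts.append(re.escape(comp[last:]))
            out.append(re.compile("^" + "".join(parts) + "$"))
        return out


@dataclass
class ImageRecord:
    """One image's metadata as recovered from the tree (plus joined extras)."""

    id: str
    imtype: str
    path: str
    timestamp: Optional[str] = None  # ISO-8601, or verbatim if unparseable
    angle: Optional[str] = None
    extra: dict = dc_field(default_factory=dict)
    flags: list = dc_field(default_factory=list)


@dataclass
class CrawlResult:
    records: list[ImageRecord]
    skipped: list[str]  # relative paths of files that did not match

    def __iter__(self):
        return iter(self.records)


def _parse_timestamp(raw: str) -> tuple[Optional[str], bool]:
    """Return (ISO-8601 string, ok).  Unparseable input comes back verbatim."""
    for fmt in _DATE_FORMATS:
        try:
            dt = datetime.strptime(raw, fmt)
        except ValueError:
            continue
        return dt.isoformat(sep=" ") if "%H" in fmt else dt.date().isoformat(), True
    return raw, False


def crawl(template: PathTemplate) -> CrawlResult:
    """Walk the tree under ``template.base_path`` and bind every matching file.

    Every file at exactly the template's depth whose components all match
    yields one record; every other file is recorded in ``skipped`` so that
    len(records) + len(skipped) equals the number of files under the root.
    """
    root = Path(template.base_path)
    if not root.is_dir():
        raise PhenopipeError(f"base path {root} is not a readable directory")
    regexes = template.component_regexes()
    depth = len(regexes)
    records: list[ImageRecord] = []
    skipped: list[str] = []
    for dirpath, _dirnames, filenames in os.walk(root):
        for fname in sorted(filenames):
            rel = Path(dirpath, fname).relative_to(root)
            parts = rel.parts
            if len(parts) != depth:
                skipped.append(str(rel))
                continue
            captures: dict[str, str] = {}
            for comp, rx in zip(parts, regexes):
                m = rx.match(comp)
                if m is None:
                    captures = {}
                    break
                captures.update(m.groupdict())
            else:
                rec = ImageRecord(
                    id=captures.pop("id"),
                    imtype=captures.pop("imtype"),
                    path=str(root / rel),
                    angle=captures.pop("angle", None),
                )
                raw_date = captures.pop("date", None)
                if raw_date is not None:
                    ts, ok = _parse_timestamp(raw_date)
                    rec.timestamp = ts
                    if not ok:
                        rec.flags.append("unparsed-timestamp")
                rec.extra.update(captures)
                records.append(rec)
                continue
            skipped.append(str(rel))
    records.sort(key=lambda r: r.path)
    # flag distinct files that collide on the full metadata key
    seen: dict[tuple, ImageRecord] = {}
    for rec in records:
        key = (rec.id, rec.timestamp, rec.imtype, rec.angle)
        if key in seen:
            for r in (seen[key], rec):
                if "duplicate-key" not in r.flags:
                    r.flags.append("duplicate-key")
        else:
            seen[key] = rec
    return CrawlResult(records=records, skipped=skipped)


def join_metadata(
    records: Iterable[ImageRecord], table: pd.DataFrame, key_column: str = "id"
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Left-join a metadata table onto the records by plant id.

    Every record whose ``id`` matches a key row gains all that row's other
    columns in ``extra``.  Returns (records, unmatched); unmatched records
    keep empty extras and survive (left-join semantics).  Duplicate keys in
    the table are an error, naming the offending keys.
    """
    if key_column not in table.columns:
        raise SchemaError(
            f"metadata table has no key column {key_column!r} "
            f"(columns: {list(table.columns)})"
        )
    keys = table[key_column].astype(str)
    dup = sorted(keys[keys.duplicated()].unique())
    if dup:
        raise SchemaError(f"duplicate key(s) in metadata table: {dup}")
    lookup = {
        str(row[key_column]): {
            k: row[k] for k in table.columns if k != key_column
        }
        for row in table.to_dict("records")
    }
    records = list(records)
    unmatched = []
    for rec in records:
        extras = lookup.get(rec.id)
        if extras is None:
            unmatched.append(rec)
        else:
            rec.extra.update(extras)
    return records, unmatched


_IMAGES_DDL = """
CREATE TABLE IF NOT EXISTS images (
    path TEXT PRIMARY KEY,
    id TEXT NOT NULL,
    imtype TEXT NOT NULL,
    timestamp TEXT,
    angle TEXT,
    extra TEXT,
    flags TEXT
)
"""


def load_database(records: Iterable[ImageRecord], db_path: str | os.PathLike) -> int:
    """Write one row per record into the ``images`` table of a SQLite file.

    Keyed on path, so re-loading the same tree is idempotent.  Returns the
    number of records written.
    """
    import json

    records = list(records)
    con = sqlite3.connect(db_path)
    try:
        con.execute(_IMAGES_DDL)
        con.executemany(
            "INSERT OR REPLACE INTO images (path, id, imtype, timestamp, angle, extra, flags)"
            " VALUES (?, ?, ?, ?, ?, ?, ?)",
            [
                (
                    r.path,
                    r.id,
                    r.imtype,
                    r.timestamp,
                    r.angle,
                    json.dumps(r.extra, sort_keys=True, default=str),
                    json.dumps(r.flags),
                )
                for r in records
            ],
        )
        con.commit()
    finally:
        con.close()
    return len(records)


def read_database(db_path: str | os.PathLike) -> list[ImageRecord]:
    """Inverse of :func:`load_database`: reconstruct records from the table."""
    import json

    con = sqlite3.connect(db_path)
    try:
        rows = con.execute(
            "SELECT path, id, imtype, timestamp, angle, extra, flags"
            " FROM images ORDER BY path"
        ).fetchall()
    finally:
        con.close()
    return [
        ImageRecord(
            id=r[1],
            imtype=r[2],
            path=r[0],
            timestamp=r[3],
            angle=r[4],
            extra=json.loads(r[5]),
            flags=json.loads(r[6]),
        )
        for r in rows
    ]
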