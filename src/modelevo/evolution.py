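"""Aggregation of per-model version histories into the three data tables.

* ``filestats``   — one row per (model, version): the entity-count vector.
* ``diffstats``   — one row per consecutive version pair: line-diff counts
  and typed operation tallies (inserts, deletes, updates, moves, triggered).
* ``repo-evolution`` — for each grid date, per-repository model counts and
  accumulated entity-count vectors, plus the combined vector.

Identical consecutive versions yield a recorded all-zero diffstats row,
never a dropped row: a repository re-release without content changes is a
version transition.

Ingestion layout (local stand-in for a repository snapshot)::

    <root>/<repo>/<model_id>/manifest.json
    <root>/<repo>/<model_id>/<NNN>_<version_id>/model.xml

``manifest.json`` carries ``model_id``, ``repository``,
``curation_status`` and the ordered ``versions`` list with ISO-8601
timestamps.  Unparseable versions are skipped with an entry in the
exclusion report, not fatal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .diff_engine import Delta, diff
from .model_io import EntityCounts, ModelDocument, count_entities, parse_model

__all__ = [
    "VersionRecord",
    "ModelHistory",
    "load_corpus",
    "build_filestats",
    "build_diffstats",
    "build_repo_evolution",
    "summarize",
    "default_date_grid",
    "FILESTATS_COLUMNS",
    "DIFFSTATS_COLUMNS",
]

log = logging.getLogger(__name__)

FILESTATS_COLUMNS = list(EntityCounts.COUNT_FIELDS) + [
    "curation_status", "format", "model_id", "version_id", "file_url",
]

DIFFSTATS_COLUMNS = [
    "model_id", "version_from", "version_to",
    "line_inserts", "line_deletes",
    "bives_inserts", "bives_deletes", "bives_updates", "bives_moves",
    "triggered_count",
]


@dataclass
class VersionRecord:
    model_id: str
    version_id: str
    timestamp: datetime
    path: Path
    curation_status: str = "unknown"


@dataclass
class ModelHistory:
    """Ordered versions of one model; the aggregation unit."""

    model_id: str
    repository: str = "other"
    versions: list[VersionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.versions:
            ts = [v.timestamp for v in self.versions]
            if any(b < a for a, b in zip(ts, ts[1:])):
                raise ValueError(
                    f"timestamps not non-decreasing for model {self.model_id}"
                )
            vids = [v.version_id for v in self.versions]
            if len(set(vids)) != len(vids):
                raise ValueError(f"duplicate version ids for model {self.model_id}")


def load_corpus(root: str | Path) -> list[ModelHistory]:
    """Read the ingestion layout into histories (sorted, deterministic)."""
    root = Path(root)
    histories = []
    for manifest_path in sorted(root.glob("*/*/manifest.json")):
        with open(manifest_path, "r", encoding="utf-8") as fh:
            manifest = json.load(fh)
        mdir = manifest_path.parent
        repo = manifest.get("repository", mdir.parent.name)
        curation = manifest.get("curation_status", "unknown")
        versions = [
            VersionRecord(
                model_id=manifest["model_id"],
                version_id=v["version_id"],
                timestamp=datetime.fromisoformat(v["timestamp"]),
                path=mdir / v["dir"] / "model.xml",
                curation_status=curation,
            )
            for v in manifest["versions"]
        ]
        histories.append(
            ModelHistory(
                model_id=manifest["model_id"], repository=repo, versions=versions
            )
        )
    return histories


class _DocStore:
    """Parse-once cache shared by the table builders."""

    def __init__(self) -> None:
        self.docs: dict[tuple[str, str], ModelDocument] = {}
        self.failures: list[dict] = []

    def get(self, rec: VersionRecord) -> Optional[ModelDocument]:
        key = (rec.model_id, rec.version_id)
        if key in self.docs:
            return self.docs[key]
        try:
            doc = parse_model(
                rec.path.read_bytes(),
                model_id=rec.model_id,
                version_id=rec.version_id,
                timestamp=rec.timestamp,
                source_uri=str(rec.path),
            )
        except Exception as exc:
            log.warning("skipping %s %s: %s", rec.model_id, rec.version_id, exc)
            self.failures.append(
                {"model_id": rec.model_id, "version_id": rec.version_id,
                 "file": str(rec.path), "error": str(exc)}
            )
            self.docs[key] = None  # type: ignore[assignment]
            return None
        self.docs[key] = doc
        return doc


def build_filestats(
    histories: Iterable[ModelHistory], store: Optional[_DocStore] = None
) -> tuple[pd.DataFrame, list[dict]]:
    """One row per parseable (model, version); returns (table, exclusions)."""
    store = store or _DocStore()
    rows = []
    for h in histories:
        for rec in h.versions:
            doc = store.get(rec)
            if doc is None:
                continue
            counts = count_entities(
                doc, curation_status=rec.curation_status, file_url=str(rec.path)
            )
            rows.append(counts.as_dict())
    return pd.DataFrame(rows, columns=FILESTATS_COLUMNS), store.failures


def build_diffstats(
    histories: Iterable[ModelHistory],
    store: Optional[_DocStore] = None,
    keep_deltas: bool = False,
) -> tuple[pd.DataFrame, list[Delta]]:
    """One row per consecutive version pair (n versions -> n-1 rows)."""
    store = store or _DocStore()
    rows = []
    deltas: list[Delta] = []
    for h in histories:
        for prev, nxt in zip(h.versions, h.versions[1:]):
            a = store.get(prev)
            b = store.get(nxt)
            if a is None or b is None:
                continue
            d = diff(a, b)
            s = d.summary
            rows.append({
                "model_id": h.model_id,
                "version_from": prev.version_id,
                "version_to": nxt.version_id,
                "line_inserts": d.line_inserts,
                "line_deletes": d.line_deletes,
                "bives_inserts": s["insert"],
                "bives_deletes": s["delete"],
                "bives_updates": s["update"],
                "bives_moves": s["move"],
                "triggered_count": s["triggered"],
            })
            if keep_deltas:
                deltas.append(d)
    return pd.DataFrame(rows, columns=DIFFSTATS_COLUMNS), deltas


def default_date_grid(
    histories: Iterable[ModelHistory], step_days: int = 30
) -> list[datetime]:
    """Regular grid from the earliest to the latest version timestamp."""
    stamps = [v.timestamp for h in histories for v in h.versions]
    if not stamps:
        return []
    start, end = min(stamps), max(stamps)
    grid = []
    t = start
    while t <= end:
        grid.append(t)
        t = t + timedelta(days=step_days)
    if grid[-1] != end:
        grid.append(end)
    return grid


def build_repo_evolution(
    histories: Iterable[ModelHistory],
    date_grid: Iterable[datetime],
    store: Optional[_DocStore] = None,
) -> pd.DataFrame:
    """Accumulated per-repository feature vectors on a date grid.

    At each grid date a model contributes its latest version at or before
    that date.  A ``combined`` row is the elementwise sum over
    repositories.
    """
    histories = list(histories)
    grid = list(date_grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("date_grid must be sorted ascending")
    store = store or _DocStore()
    count_fields = list(EntityCounts.COUNT_FIELDS)
    repos = sorted({h.repository for h in histories})
    rows = []
    for date in grid:
        vectors = {r: {"models": 0, **{f: 0 for f in count_fields}} for r in repos}
        for h in histories:
            current = None
            for rec in h.versions:
                if rec.timestamp <= date:
                    current = rec
                else:
                    break
            if current is None:
                continue
            doc = store.get(current)
            if doc is None:
                continue
            counts = count_entities(doc)
            vec = vectors[h.repository]
            vec["models"] += 1
            for f in count_fields:
                vec[f] += getattr(counts, f)
        combined = {"models": 0, **{f: 0 for f in count_fields}}
        for r in repos:
            for k in combined:
                combined[k] += vectors[r][k]
        for r in repos:
            rows.append({"date": date.isoformat(), "repository": r, **vectors[r]})
        rows.append({"date": date.isoformat(), "repository": "combined", **combined})
    return pd.DataFrame(
        rows, columns=["date", "repository", "models"] + count_fields
    )


def summarize(
    diffstats: pd.DataFrame,
    filestats: pd.DataFrame,
    histories: Optional[Iterable[ModelHistory]] = None,
    window_years: float = 5.0,
    include_triggered: bool = True,
    include_zero_transitions: bool = True,
) -> dict:
    """Derived summary statistics; absent (not zero) on empty inputs.

    * ``mean_versions_per_model_window`` — mean number of versions within
      ``window_years`` of each model's first version (closed interval);
      needs ``histories``.
    * ``mean_ops_per_transition`` — mean total typed operations per
      version transition, with toggles for triggered ops and for
      all-zero transitions (both unstated in the original setting, hence
      explicit here).
    * ``mean_nodes_latest_by_format`` — mean node count of each model's
      last version, grouped by encoding format.
    * ``release_change_matrix`` — version_to x model_id -> op count.
    """
    out: dict = {}
    if histories is not None:
        histories = list(histories)
        if histories:
            per_model = []
            for h in histories:
                if not h.versions:
                    continue
                t0 = h.versions[0].timestamp
                horizon = t0 + timedelta(days=365.25 * window_years)
                per_model.append(sum(1 for v in h.versions if v.timestamp <= horizon))
            if per_model:
                out["mean_versions_per_model_window"] = sum(per_model) / len(per_model)

    if not diffstats.empty:
        ops = (
            diffstats["bives_inserts"] + diffstats["bives_deletes"]
            + diffstats["bives_updates"] + diffstats["bives_moves"]
        )
        if not include_triggered:
            ops = ops - diffstats["triggered_count"]
        if not include_zero_transitions:
            ops = ops[ops > 0]
        if len(ops):
            out["mean_ops_per_transition"] = float(ops.mean())
        matrix = diffstats.assign(total_ops=(
            diffstats["bives_inserts"] + diffstats["bives_deletes"]
            + diffstats["bives_updates"] + diffstats["bives_moves"]
        )).pivot_table(
            index="version_to", columns="model_id", values="total_ops",
            aggfunc="sum", fill_value=0,
        )
        out["release_change_matrix"] = matrix

    if not filestats.empty:
        latest = filestats.groupby("model_id").tail(1)
        out["mean_nodes_latest_by_format"] = {
            fmt: float(grp["nodes"].mean())
            for fmt, grp in latest.groupby("format")
        }
    return out
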