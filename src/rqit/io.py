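"""Readers and writers for the delimited-text interchange formats.

All tabular formats are comma-separated UTF-8 with a mandatory header row;
option positions and level indices are 1-based.  Utility tables and
instruments serialize to JSON at full stored precision so round-trips are
exact.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import RatingsMatrix
from .delphi import DelphiItem
from .design import ChoiceTask, DesignBlock
from .fit import BWResponse
from .instrument import UtilityTable, table_from_dict
from .validation import ArticleRecord

__all__ = [
    "read_responses",
    "write_responses",
    "read_design",
    "write_design",
    "read_utility_table",
    "write_utility_table",
    "read_ratings",
    "read_delphi_items",
    "read_articles",
    "write_provenance",
]

logger = logging.getLogger(__name__)

RESPONSE_COLUMNS = ["respondent_id", "task_id", "best_option", "worst_option"]


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    unknown = [c for c in df.columns if c not in expected]
    missing = [c for c in expected if c not in df.columns]
    if unknown or missing:
        raise SchemaError(
            f"{path}: expected columns {list(expected)}, "
            f"missing {missing}, unknown {unknown}"
        )


def read_responses(path: str | Path) -> list[BWResponse]:
    """Read best-worst responses; malformed rows are rejected and logged."""
    df = pd.read_csv(path, dtype={"respondent_id": str, "task_id": str})
    _check_columns(df, RESPONSE_COLUMNS, path)
    out: list[BWResponse] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        best = None if pd.isna(row.best_option) else int(row.best_option)
        worst = None if pd.isna(row.worst_option) else int(row.worst_option)
        try:
            out.append(BWResponse(str(row.respondent_id), str(row.task_id), best, worst))
        except ValueError as exc:
            logger.warning("%s line %d: row rejected (%s)", path, i, exc)
    return out


def write_responses(responses: Sequence[BWResponse], path: str | Path) -> None:
    rows = [
        {
            "respondent_id": r.respondent_id,
            "task_id": r.task_id,
            "best_option": "" if r.best is None else r.best,
            "worst_option": "" if r.worst is None else r.worst,
        }
        for r in responses
    ]
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS).to_csv(path, index=False)


def write_design(tasks: Sequence[ChoiceTask], path: str | Path,
                 blocks: Sequence[DesignBlock] | None = None) -> None:
    """Write tasks as task_id, dim_pair, opt1..opt3 ("A3+B1" option syntax)."""
    rows = []
    block_of: dict[str, list[int]] = {}
    if blocks:
        for b in blocks:
            for tid in b.task_ids:
                block_of.setdefault(tid, []).append(b.block_id)
    for t in tasks:
        row = {
            "task_id": t.task_id,
            "dim_pair": "".join(t.dimension_pair),
            "opt1": "+".join(t.options[0]),
            "opt2": "+".join(t.options[1]),
            "opt3": "+".join(t.options[2]),
        }
        if blocks:
            row["blocks"] = "|".join(str(i) for i in block_of.get(t.task_id, []))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_design(path: str | Path) -> list[ChoiceTask]:
    df = pd.read_csv(path, dtype=str)
    needed = ["task_id", "dim_pair", "opt1", "opt2", "opt3"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    tasks = []
    for row in df.itertuples(index=False):
        options = tuple(
            tuple(getattr(row, f"opt{i}").split("+")) for i in (1, 2, 3)
        )
        pair = (row.dim_pair[0], row.dim_pair[1])
        tasks.append(ChoiceTask(task_id=row.task_id, dimension_pair=pair, options=options))
    return tasks


def write_utility_table(table: UtilityTable, path: str | Path) -> None:
    """Serialize a utility table (instrument + utilities + correlations)."""
    codes = list(table.instrument.element_codes)
    doc = {
        "name": table.instrument.name,
        "version": table.instrument.version,
        "scale": list(table.scale),
        "dimensions": [
            {
                "code": d.code,
                "label": d.label,
                "levels": [
                    {
                        "code": c,
                        "descriptor": desc,
                        "utility": table.utility(c),
                        "se": table.se(c),
                    }
                    for c, desc in d.levels
                ],
            }
            for d in table.instrument.dimensions
        ],
        "correlations": {"codes": codes, "matrix": np.asarray(table.correlations).tolist()},
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_utility_table(path: str | Path) -> UtilityTable:
    """Read and validate a serialized utility table (exact round-trip)."""
    return table_from_dict(json.loads(Path(path).read_text()))


def read_ratings(path: str | Path, n_categories: int | None = None) -> RatingsMatrix:
    """Read a ratings grid, wide (subject_id + one column per rater) or long
    (subject_id, rater_id, category)."""
    df = pd.read_csv(path)
    if {"subject_id", "rater_id", "category"}.issubset(df.columns):
        wide = df.pivot(index="subject_id", columns="rater_id", values="category")
        return RatingsMatrix(wide.to_numpy(dtype=float), n_categories)
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path}: need subject_id plus rater columns, or long format")
    grid = df.drop(columns=["subject_id"]).to_numpy(dtype=float)
    return RatingsMatrix(grid, n_categories)


def read_delphi_items(path: str | Path) -> list[DelphiItem]:
    """Read long-format item ratings (item_id, theme, respondent_id, rating[, round])."""
    df = pd.read_csv(path)
    needed = {"item_id", "theme", "respondent_id", "rating"}
    if not needed.issubset(df.columns):
        raise SchemaError(f"{path}: need columns {sorted(needed)}")
    if "round" not in df.columns:
        df["round"] = 1
    items = []
    for (item_id, rnd), grp in df.groupby(["item_id", "round"], sort=True):
        items.append(
            DelphiItem(
                item_id=str(item_id),
                text=str(grp["text"].iloc[0]) if "text" in grp else "",
                theme=str(grp["theme"].iloc[0]),
                ratings=tuple(int(r) for r in grp["rating"]),
                round=int(rnd),
            )
        )
    return items


def read_articles(path: str | Path, level_columns: Sequence[str] | None = None) -> list[ArticleRecord]:
    """Read article records: article_id, level columns, journal_group, citations."""
    df = pd.read_csv(path, dtype={"article_id": str})
    if level_columns is None:
        level_columns = [
            c for c in df.columns
            if c not in ("article_id", "journal_group", "citations")
        ]
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ArticleRecord(
                article_id=str(row.article_id),
                levels=tuple(str(getattr(row, c)) for c in level_columns),
                journal_group=str(row.journal_group),
                citation_count=int(row.citations),
            )
        )
    return out


def write_provenance(path: str | Path, command: str, inputs: dict, options: dict, seed: int | None) -> None:
    """Machine-readable record sufficient to re-run a command identically."""
    from . import __version__

    doc = {
        "package": "rqit",
        "version": __version__,
        "command": command,
        "inputs": inputs,
        "options": options,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")
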