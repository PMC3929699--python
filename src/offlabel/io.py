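"""Reading and writing the pipeline's tab-separated interchange tables.

Every input and output of the pipeline is a UTF-8, tab-separated table
with a header row. Each table has a declared schema (column names, cell
types, closed enumerations); reading validates every row and either
raises with the offending line number or collects rejected rows, so no
row is ever silently dropped.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .containers import CONCEPT_TYPES


class SchemaError(ValueError):
    """Header does not match the declared schema."""


class RowError(ValueError):
    """A data row failed validation; carries the 1-based line number."""

    def __init__(self, line: int, message: str) -> None:
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass(frozen=True)
class Column:
    name: str
    kind: Literal["str", "int", "float", "date"] = "str"
    allowed: frozenset[str] | None = None

    def parse(self, raw: str):
        if self.allowed is not None and raw not in self.allowed:
            raise ValueError(
                f"column {self.name!r}: {raw!r} not in "
                f"{{{', '.join(sorted(self.allowed))}}}"
            )
        if self.kind == "str":
            return raw
        if self.kind == "int":
            return int(raw)
        if self.kind == "float":
            return float(raw)
        if self.kind == "date":
            return dt.date.fromisoformat(raw)
        raise AssertionError(self.kind)


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[Column, ...]

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)


MENTIONS = TableSchema(
    "mentions",
    (
        Column("patient_id"),
        Column("note_id"),
        Column("date", "date"),
        Column("concept_id"),
        Column("concept_type", allowed=CONCEPT_TYPES),
    ),
)
USAGE = TableSchema(
    "usage",
    (
        Column("drug"),
        Column("indication"),
        Column("status", allowed=frozenset({"approved", "known"})),
    ),
)
HIERARCHY = TableSchema("hierarchy", (Column("child"), Column("parent")))
INGREDIENTS = TableSchema("ingredients", (Column("product"), Column("ingredient")))
ATTRIBUTES = TableSchema(
    "attributes",
    (
        Column("drug"),
        Column("kind", allowed=frozenset({"targets", "pathways", "categories"})),
        Column("value"),
    ),
)
REPORTS = TableSchema(
    "reports", (Column("report_id"), Column("drug"), Column("indication"))
)
LITERATURE = TableSchema(
    "literature", (Column("article_id"), Column("drug"), Column("indication"))
)
SIDE_EFFECTS = TableSchema("side_effects", (Column("drug"), Column("event")))
ADVERSE_EVENTS = TableSchema(
    "adverse_events",
    (Column("drug"), Column("event"), Column("severity"), Column("frequency")),
)
COSTS = TableSchema("costs", (Column("drug"), Column("unit_cost", "float")))
LABELED_PAIRS = TableSchema(
    "labeled_pairs",
    (
        Column("drug"),
        Column("indication"),
        Column("label", allowed=frozenset({"positive", "negative"})),
        Column("origin", allowed=frozenset({"kb", "sampled"})),
    ),
)
PAIRS = TableSchema("pairs", (Column("drug"), Column("indication")))

_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r"}


def _escape(cell: str) -> str:
    for raw, esc in _ESCAPES.items():
        cell = cell.replace(raw, esc)
    return cell


def _unescape(cell: str) -> str:
    out = []
    it = iter(range(len(cell)))
    i = 0
    while i < len(cell):
        ch = cell[i]
        if ch == "\\" and i + 1 < len(cell):
            nxt = cell[i + 1]
            out.append({"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}.get(nxt, ch + nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def read_table(
    path: str | Path,
    schema: TableSchema,
    errors: Literal["raise", "collect"] = "raise",
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a TSV against ``schema``.

    With ``errors="raise"`` (default) the first invalid row aborts the
    read with a :class:`RowError` naming its line. With ``"collect"``
    the return value is ``(accepted, rejected)`` where ``rejected`` has
    the raw row text plus line number and reason; the line counts of the
    two frames always sum to the number of data lines in the file.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE, escapechar=None)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected header")
        for col in schema.columns:
            if col.name not in header:
                raise SchemaError(f"{path}: missing column {col.name!r}")
        idx = {c.name: header.index(c.name) for c in schema.columns}
        accepted: list[dict] = []
        rejected: list[dict] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                if len(row) != len(header):
                    raise ValueError(
                        f"expected {len(header)} fields, got {len(row)}"
                    )
                parsed = {
                    c.name: c.parse(_unescape(row[idx[c.name]]))
                    for c in schema.columns
                }
            except ValueError as exc:
                if errors == "raise":
                    raise RowError(lineno, str(exc)) from exc
                rejected.append(
                    {"line": lineno, "raw": "\t".join(row), "reason": str(exc)}
                )
                continue
            accepted.append(parsed)
    acc_df = pd.DataFrame(accepted, columns=list(schema.column_names))
    if errors == "collect":
        rej_df = pd.DataFrame(rejected, columns=["line", "raw", "reason"])
        return acc_df, rej_df
    return acc_df


def write_table(
    rows: pd.DataFrame | Iterable[dict],
    path: str | Path,
    schema: TableSchema,
    on_special: Literal["escape", "reject"] = "escape",
) -> None:
    """Write rows as a UTF-8 TSV with header, in schema column order.

    Tabs/newlines/backslashes inside string fields are backslash-escaped
    (the default, making write/read a round trip) or rejected.
    """
    if isinstance(rows, pd.DataFrame):
        records = rows.to_dict("records")
    else:
        records = list(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(schema.column_names) + "\n")
        for rec in records:
            cells = []
            for col in schema.columns:
                value = rec[col.name]
                if col.kind == "date" and isinstance(value, (dt.date, dt.datetime)):
                    cell = value.strftime("%Y-%m-%d")
                elif col.kind == "float":
                    cell = repr(float(value))
                else:
                    cell = str(value)
                if any(ch in cell for ch in "\t\n\r\\"):
                    if on_special == "reject":
                        raise ValueError(
                            f"field {col.name!r} contains a control character: "
                            f"{cell!r}"
                        )
                    cell = _escape(cell)
                cells.append(cell)
            fh.write("\t".join(cells) + "\n")


# -- container <-> frame converters ---------------------------------------

def usage_to_frame(usage) -> pd.DataFrame:
    return pd.DataFrame(usage.to_records(), columns=["drug", "indication", "status"])


def frame_to_usage(df: pd.DataFrame, drugs=None, indications=None):
    from .containers import UsageMatrix

    drugs = list(drugs) if drugs is not None else sorted(df["drug"].unique())
    indications = (
        list(indications)
        if indications is not None
        else sorted(df["indication"].unique())
    )
    pairs = {
        (r.drug, r.indication): r.status == "approved" for r in df.itertuples()
    }
    return UsageMatrix(drugs, indications, pairs)
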