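"""Reading and writing the two CSV dialects.

Aggregated dialect (one row per trial)::

    label,year,n1,e1,n0,e0,subgroup_prop

``year`` and ``subgroup_prop`` may be empty; ``subgroup_prop`` is a
fraction in [0, 1].  IPD dialect (one row per participant or weighted
cell)::

    trial,arm,subgroup,outcome,weight

``weight`` is optional and defaults to 1.  Both dialects are
comma-separated UTF-8 with a period decimal separator and a required
header; floats are written with 12 significant digits so that
write-then-read round trips are identity up to that formatting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .effects import TwoByTwoTable
from .errors import InvalidTableError, ParseError
from .ipd import IPDDataset

AGGREGATED_COLUMNS = ("label", "year", "n1", "e1", "n0", "e0", "subgroup_prop")


@dataclass
class RunConfig:
    """Options shared across CLI subcommands."""

    input_path: Path | None = None
    output_path: Path | None = None
    measure: str = "rr"
    level: float = 0.95
    plot_mode: str = "standard"
    subgroup_col: str = "subgroup_prop"
    seed: int | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("confidence level must be in (0, 1)")


def _fmt_num(v: float) -> str:
    return f"{v:.12g}"


def _parse_float(raw: str, row: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ParseError(f"cannot parse {raw!r} as a number", row=row, column=column)


def read_aggregated(
    path: str | Path, subgroup_col: str = "subgroup_prop"
) -> tuple[list[TwoByTwoTable], list[float | None]]:
    """Read trials from the aggregated dialect.

    Returns the tables and the per-trial subgroup proportions (``None``
    where the cell is empty).  Row numbers in error messages count data
    rows from 1.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file, header required")
        required = {"label", "n1", "e1", "n0", "e0"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: header lacks columns {sorted(missing)}")
        tables: list[TwoByTwoTable] = []
        props: list[float | None] = []
        for i, rec in enumerate(reader, start=1):
            year_raw = (rec.get("year") or "").strip()
            year = None
            if year_raw:
                try:
                    year = int(year_raw)
                except ValueError:
                    raise ParseError(
                        f"cannot parse {year_raw!r} as a year", row=i, column="year"
                    )
            nums = {c: _parse_float(rec[c], i, c) for c in ("n1", "e1", "n0", "e0")}
            try:
                tables.append(
                    TwoByTwoTable(
                        label=rec["label"],
                        a=nums["e1"],
                        n1=nums["n1"],
                        c=nums["e0"],
                        n0=nums["n0"],
                        year=year,
                    )
                )
            except InvalidTableError as exc:
                raise ParseError(f"invalid counts: {exc}", row=i) from exc
            prop_raw = (rec.get(subgroup_col) or "").strip()
            if prop_raw:
                p = _parse_float(prop_raw, i, subgroup_col)
                if not 0 <= p <= 1:
                    raise ParseError(
                        f"subgroup proportion {p} outside [0, 1]",
                        row=i,
                        column=subgroup_col,
                    )
                props.append(p)
            else:
                props.append(None)
    return tables, props


def write_aggregated(
    tables: list[TwoByTwoTable],
    subgroup_props: list[float | None] | None,
    path: str | Path,
) -> None:
    props = subgroup_props if subgroup_props is not None else [None] * len(tables)
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(AGGREGATED_COLUMNS)
        for t, p in zip(tables, props):
            writer.writerow(
                [
                    t.label,
                    "" if t.year is None else t.year,
                    _fmt_num(t.n1),
                    _fmt_num(t.a),
                    _fmt_num(t.n0),
                    _fmt_num(t.c),
                    "" if p is None else _fmt_num(p),
                ]
            )


def read_ipd(path: str | Path) -> IPDDataset:
    """Read participant-level records; a missing weight column means 1."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file, header required")
    required = {"trial", "arm", "subgroup", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: header lacks columns {sorted(missing)}")
    try:
        return IPDDataset(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_ipd(ipd: IPDDataset, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(("trial", "arm", "subgroup", "outcome", "weight"))
        for rec in ipd.data.itertuples(index=False):
            writer.writerow(
                [rec.trial, rec.arm, rec.subgroup, rec.outcome, _fmt_num(rec.weight)]
            )
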