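"""Readers, writers, packaged fixtures and report rendering.

One flat CSV dialect (UTF-8, comma-separated, header required) carries exam
records; contingency tables travel as plain-text matrices whose first
non-comment line lists the ordered category values.  The published summary
tables of the BIND-M evaluation study ship as packaged fixtures (see
``bindm/fixtures/*.csv``; each file carries a provenance comment noting any
known typographical discrepancy in the printed original).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np

from .rubric import ExamRecord, Rater, SubscoreAssessment, DomainError
from .agreement import ContingencyTable, KappaResult
from .diagnostics import PerformanceSweep, ThresholdPerformance
from .risk_factors import CategoricalExposureTable, OddsRatioResult

__all__ = [
    "ExamRecordError",
    "EXAM_COLUMNS",
    "read_exam_records",
    "write_exam_records",
    "read_contingency_table",
    "read_threshold_counts",
    "read_exposure_tables",
    "FixtureSet",
    "load_fixtures",
    "load_fixture_table",
    "check_fixtures",
    "render_report",
]

EXAM_COLUMNS = ("infant_id", "rater", "mental_status", "muscle_tone",
                "cry", "gaze", "abe_diagnosis")

_NA = {"", "na", "n/a", "nan", "none"}


class ExamRecordError(ValueError):
    """A malformed exam-record file; the message names line and field."""


def _parse_bool(raw: str, line_no: int) -> Optional[bool]:
    s = raw.strip().lower()
    if s in _NA:
        return None
    if s in {"0", "false"}:
        return False
    if s in {"1", "true"}:
        return True
    raise ExamRecordError(f"line {line_no}: abe_diagnosis must be 0, 1 or NA, got {raw!r}")


def read_exam_records(source: Union[str, TextIO]) -> list[ExamRecord]:
    """Read validated exam records from the flat CSV dialect.

    Malformed rows raise :class:`ExamRecordError` naming the offending line
    and field; an empty file returns an empty list with a warning.
    """
    close = False
    if isinstance(source, str):
        fh = open(source, newline="", encoding="utf-8")
        close = True
    else:
        fh = source
    try:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            warnings.warn("exam-record file is empty", stacklevel=2)
            return []
        header = [h.strip() for h in header]
        if header[:len(EXAM_COLUMNS)] != list(EXAM_COLUMNS):
            # extra covariate columns (cohort CSVs) are permitted after the
            # core exam columns and ignored here
            raise ExamRecordError(
                f"header must start with {','.join(EXAM_COLUMNS)}, "
                f"got {','.join(header)}")
        records: list[ExamRecord] = []
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ExamRecordError(
                    f"line {line_no}: expected {len(header)} fields, got {len(row)}")
            vals = dict(zip(EXAM_COLUMNS, (c.strip() for c in row)))
            try:
                rater = Rater(vals["rater"].lower())
            except ValueError:
                raise ExamRecordError(
                    f"line {line_no}: unknown rater {vals['rater']!r}") from None
            levels = {}
            for fname in ("mental_status", "muscle_tone", "cry", "gaze"):
                try:
                    levels[fname] = int(vals[fname])
                except ValueError:
                    raise ExamRecordError(
                        f"line {line_no}: field {fname!r} must be an integer, "
                        f"got {vals[fname]!r}") from None
            try:
                assessment = SubscoreAssessment(**levels)
                record = ExamRecord(
                    infant_id=vals["infant_id"], rater=rater,
                    assessment=assessment,
                    abe_diagnosis=_parse_bool(vals["abe_diagnosis"], line_no),
                )
            except DomainError as exc:
                raise ExamRecordError(f"line {line_no}: {exc}") from None
            records.append(record)
        if not records:
            warnings.warn("exam-record file has no data rows", stacklevel=2)
        return records
    finally:
        if close:
            fh.close()


def write_exam_records(records: Iterable[ExamRecord], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EXAM_COLUMNS)
        for r in records:
            a = r.assessment
            writer.writerow([
                r.infant_id, r.rater.value, a.mental_status, a.muscle_tone,
                a.cry, a.gaze,
                "" if r.abe_diagnosis is None else int(r.abe_diagnosis),
            ])


def _data_lines(text: str) -> list[str]:
    return [ln for ln in text.splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")]


def read_contingency_table(source: Union[str, TextIO]) -> ContingencyTable:
    """Plain-text square count matrix; first non-comment line = categories."""
    text = source if not hasattr(source, "read") else source.read()
    if isinstance(source, str) and "\n" not in source:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    lines = _data_lines(text)
    if len(lines) < 2:
        raise ValueError("contingency table file needs a category line and rows")
    split = lambda ln: [t for t in ln.replace(",", " ").split() if t]
    categories = tuple(int(t) for t in split(lines[0]))
    counts = np.array([[int(t) for t in split(ln)] for ln in lines[1:]], dtype=np.int64)
    return ContingencyTable(categories, counts)


def read_threshold_counts(text: str) -> tuple[ThresholdPerformance, ...]:
    rows = []
    for ln in _data_lines(text):
        parts = [p.strip() for p in ln.split(",")]
        if parts[0] == "cutoff":
            continue
        cutoff, tp, fn, fp, tn = (int(p) for p in parts)
        rows.append(ThresholdPerformance(cutoff=cutoff, tp=tp, fn=fn, fp=fp, tn=tn))
    return tuple(rows)


def read_exposure_tables(text: str) -> dict[str, CategoricalExposureTable]:
    by_factor: dict[str, list[tuple[str, int, int]]] = {}
    referents: dict[str, int] = {}
    for ln in _data_lines(text):
        parts = [p.strip() for p in ln.split(",")]
        if parts[0] == "factor":
            continue
        factor, level, cases, controls, referent = parts
        levels = by_factor.setdefault(factor, [])
        if referent == "1":
            referents[factor] = len(levels)
        levels.append((level, int(cases), int(controls)))
    return {
        factor: CategoricalExposureTable(
            factor=factor, levels=tuple(levels),
            referent_index=referents.get(factor, 0))
        for factor, levels in by_factor.items()
    }


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSet:
    """The published summary tables, loaded from the packaged CSV files."""

    table1: ContingencyTable
    table2a: ContingencyTable
    table2b: ContingencyTable
    table2c: ContingencyTable
    table2d: ContingencyTable
    table3: tuple[ThresholdPerformance, ...]
    table4: dict[str, CategoricalExposureTable]


def _fixture_text(name: str) -> str:
    return (resources.files("bindm") / "fixtures" / name).read_text(encoding="utf-8")


def load_fixture_table(name: str) -> ContingencyTable:
    """Load one packaged contingency-table fixture, e.g. ``table2a``."""
    return read_contingency_table(_fixture_text(f"{name}.csv"))


def load_fixtures() -> FixtureSet:
    return FixtureSet(
        table1=load_fixture_table("table1"),
        table2a=load_fixture_table("table2a"),
        table2b=load_fixture_table("table2b"),
        table2c=load_fixture_table("table2c"),
        table2d=load_fixture_table("table2d"),
        table3=read_threshold_counts(_fixture_text("table3_counts.csv")),
        table4=read_exposure_tables(_fixture_text("table4_counts.csv")),
    )


def check_fixtures(fixtures: Optional[FixtureSet] = None) -> FixtureSet:
    """Assert every fixture's totals match the published margins."""
    fx = fixtures if fixtures is not None else load_fixtures()
    for name in ("table1", "table2a", "table2b", "table2c", "table2d"):
        t: ContingencyTable = getattr(fx, name)
        if t.n != 333:
            raise AssertionError(f"{name}: total {t.n} != 333")
    if tuple(fx.table1.counts.sum(axis=0)) != (248, 23, 8, 4, 2, 6, 3, 6, 7, 9, 6, 9, 2):
        raise AssertionError("table1: column totals do not match the printed margin")
    if tuple(fx.table2a.counts.sum(axis=0)) != (261, 24, 37, 11):
        raise AssertionError("table2a: column totals do not match the printed margin")
    for row in fx.table3:
        if row.tp + row.fn != 53:
            raise AssertionError(f"table3 cutoff {row.cutoff}: positives != 53")
        if row.n != 333:
            raise AssertionError(f"table3 cutoff {row.cutoff}: N != 333")
    grid = fx.table4["menthol_g6pd"]
    if grid.total_cases != 28 or grid.total_controls != 170:
        raise AssertionError("table4 menthol x G6PD grid margins do not match (28, 170)")
    return fx


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def _fmt_metric(v: Optional[float]) -> str:
    return "N/A" if v is None else f"{v:.1f}"


def _render_table2(payload) -> str:
    table, result = payload
    if not isinstance(table, ContingencyTable) or not isinstance(result, KappaResult):
        raise TypeError("table2 layout needs (ContingencyTable, KappaResult)")
    cats = table.categories
    width = max(6, max(len(str(c)) for c in cats) + 2)
    head = "resident\\consultant".ljust(20) + "".join(str(c).rjust(width) for c in cats) \
        + "Total".rjust(width + 2)
    lines = [head]
    for i, c in enumerate(cats):
        row = table.counts[i]
        lines.append(str(c).ljust(20) + "".join(str(v).rjust(width) for v in row)
                     + str(row.sum()).rjust(width + 2))
    col_tot = table.counts.sum(axis=0)
    lines.append("Total".ljust(20) + "".join(str(v).rjust(width) for v in col_tot)
                 + str(table.n).rjust(width + 2))
    lines.append("")
    lines.append(result.summary())
    return "\n".join(lines)


def _render_table3(sweep: PerformanceSweep) -> str:
    if not isinstance(sweep, PerformanceSweep):
        raise TypeError("table3 layout needs a PerformanceSweep")
    if not sweep.rows:
        raise ValueError("empty sweep")
    header = (f"{'cutoff':>7} {'TP':>4} {'FN':>4} {'FP':>4} {'TN':>4} "
              f"{'Sens%':>7} {'Spec%':>7} {'PPV%':>7} {'NPV%':>7}")
    lines = [f"N = {sweep.n}, ABE-positive = {sweep.n_positive} "
             f"(prevalence {100 * sweep.prevalence:.1f}%)", header]
    for r in sweep.rows:
        lines.append(
            f"{'>=' + str(r.cutoff):>7} {r.tp:>4} {r.fn:>4} {r.fp:>4} {r.tn:>4} "
            f"{_fmt_metric(r.sensitivity):>7} {_fmt_metric(r.specificity):>7} "
            f"{_fmt_metric(r.ppv):>7} {_fmt_metric(r.npv):>7}")
    return "\n".join(lines)


def _render_table4(payload) -> str:
    table, results = payload
    if not isinstance(table, CategoricalExposureTable):
        raise TypeError("table4 layout needs (CategoricalExposureTable, results)")
    n_total = table.total_cases + table.total_controls
    lines = [f"factor: {table.factor}   cases={table.total_cases} "
             f"controls={table.total_controls}",
             f"{'level':<24} {'cases':>6} {'controls':>9} {'number (%)':>14}  OR (95% CI)"]
    for (label, cases, controls), res in zip(table.levels, results):
        n = cases + controls
        pct = 100.0 * n / n_total
        if not isinstance(res, OddsRatioResult):
            raise TypeError("table4 layout needs OddsRatioResult entries")
        rendered = "1.000 [Referent]" if res.label.endswith("[Referent]") else res.format()
        lines.append(f"{label:<24} {cases:>6} {controls:>9} "
                     f"{f'{n} ({pct:.1f}%)':>14}  {rendered}")
    return "\n".join(lines)


def render_report(results, layout: str) -> str:
    """Render results in one of the published table layouts.

    * ``table2``: (contingency table, kappa result) — counts with margins
      and the kappa line;
    * ``table3``: a threshold sweep — confusion counts and metrics per
      cutoff, undefined metrics as "N/A";
    * ``table4``: (categorical exposure table, odds-ratio results) — counts
      and "OR (CI)" per level, referent as "1.000 [Referent]", degenerate
      levels as "0.000 (incalculable)" / upper bounds ">999".
    """
    renderers = {"table2": _render_table2, "table3": _render_table3,
                 "table4": _render_table4}
    if layout not in renderers:
        raise ValueError(f"unknown layout {layout!r}")
    return renderers[layout](results)
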