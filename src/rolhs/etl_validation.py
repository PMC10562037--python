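"""Data-quality checks for cohort tables: the five cleaning rules, the
cell-blanking drop policy, and the mapping-completeness metric.

Rule kinds
----------
``type``         cell parses as the expected primitive (integer/float/string)
``cross_field``  a cell's validity depends on another cell, either a date
                 ordering (possibly across tables, joined on patient ID) or a
                 presence dependency ("X present implies Y present")
``mandatory``    cell must be non-blank
``range``        numeric cell within [lower, upper]
``format``       cell matches a date format (YYYYMMDD)

Drop policy: a violating *cell* is blanked and its row retained, except rows
failing a mandatory key check, which are excluded entirely (a keyless row
cannot anchor triples downstream).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from rolhs.errors import ArgumentFailure, ConfigurationFailure, UndefinedMetricFailure
from rolhs.synthetic_cohort import CohortTables

__all__ = [
    "ValidationRule",
    "Violation",
    "ValidationReport",
    "validate",
    "clean",
    "mapping_completeness",
    "default_rules",
    "load_rules",
    "dump_rules",
]

RULE_KINDS = ("type", "cross_field", "mandatory", "range", "format")
_DATE_RE = re.compile(r"^\d{8}$")


@dataclass(frozen=True)
class ValidationRule:
    kind: str
    table: str
    column: str
    # type
    expected_type: str | None = None          # "integer" | "float" | "string"
    # cross_field date ordering: column >= other (dates)
    other_table: str | None = None
    other_column: str | None = None
    relation: str | None = None               # "not_earlier_than" | "requires"
    # range
    lower: float | None = None
    upper: float | None = None
    # format
    date_format: str = "YYYYMMDD"

    def __post_init__(self):
        if self.kind not in RULE_KINDS:
            raise ArgumentFailure(f"unknown rule kind {self.kind!r}")
        if self.kind == "range" and (self.lower is None or self.upper is None):
            raise ArgumentFailure("range rule needs lower and upper")
        if self.kind == "range" and self.lower > self.upper:
            raise ArgumentFailure("range rule needs lower <= upper")

    def is_cell_local(self) -> bool:
        return self.kind in ("type", "mandatory", "range", "format")


@dataclass(frozen=True)
class Violation:
    table: str
    row: int
    column: str
    kind: str
    message: str

    def cell(self) -> tuple[str, int, str]:
        return (self.table, self.row, self.column)


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def summary(self) -> dict[str, int]:
        counts: dict[str, int] = {k: 0 for k in RULE_KINDS}
        for v in self.violations:
            counts[v.kind] += 1
        return counts

    def cell_set(self) -> set[tuple[str, int, str]]:
        return {v.cell() for v in self.violations}

    def mandatory_rows(self) -> set[tuple[str, int]]:
        return {(v.table, v.row) for v in self.violations if v.kind == "mandatory"}

    def __len__(self) -> int:
        return len(self.violations)

    def to_json(self, path: str | Path) -> Path:
        doc = {
            "summary": self.summary,
            "violations": [v.__dict__ for v in self.violations],
        }
        path = Path(path)
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
        return path


def _parse_date(value: str):
    from datetime import date

    if not _DATE_RE.match(value):
        return None
    try:
        return date(int(value[:4]), int(value[4:6]), int(value[6:]))
    except ValueError:
        return None


def _check_schema(tables: CohortTables, rules: Iterable[ValidationRule]) -> None:
    for rule in rules:
        for table, column in [(rule.table, rule.column)] + (
            [(rule.other_table or rule.table, rule.other_column)]
            if rule.kind == "cross_field"
            else []
        ):
            if table not in tables.tables:
                raise ConfigurationFailure(f"rule targets unknown table {table!r}")
            rows = tables[table]
            if rows and all(column not in r for r in rows):
                raise ConfigurationFailure(
                    f"rule targets unknown column {column!r} in table {table!r}"
                )


def validate(tables: CohortTables, rules: list[ValidationRule]) -> ValidationReport:
    """Evaluate every rule on every applicable row; deterministic order."""
    _check_schema(tables, rules)
    violations: list[Violation] = []
    for rule in rules:
        handler = _HANDLERS[rule.kind]
        violations.extend(handler(tables, rule))
    violations.sort(key=lambda v: (v.table, v.row, v.column, v.kind))
    # set semantics: identical (cell, kind) reported once regardless of rule order
    seen: set[tuple] = set()
    unique = []
    for v in violations:
        key = (v.table, v.row, v.column, v.kind)
        if key not in seen:
            seen.add(key)
            unique.append(v)
    return ValidationReport(violations=unique)


def _iter_rows(tables, rule):
    for i, row in enumerate(tables[rule.table]):
        if rule.column in row:
            yield i, row


def _check_type(tables, rule):
    for i, row in _iter_rows(tables, rule):
        value = row[rule.column]
        if value == "":
            continue  # blankness is the mandatory check's concern
        ok = True
        if rule.expected_type == "integer":
            ok = bool(re.match(r"^[+-]?\d+$", value))
        elif rule.expected_type == "float":
            try:
                float(value)
            except ValueError:
                ok = False
        if not ok:
            yield Violation(rule.table, i, rule.column, "type",
                            f"expected {rule.expected_type}, got {value!r}")


def _check_mandatory(tables, rule):
    for i, row in _iter_rows(tables, rule):
        if row[rule.column].strip() == "":
            yield Violation(rule.table, i, rule.column, "mandatory",
                            f"{rule.column!r} must not be empty")


def _check_range(tables, rule):
    for i, row in _iter_rows(tables, rule):
        value = row[rule.column]
        if value == "":
            continue
        try:
            number = float(value)
        except ValueError:
            continue  # unparseable values are a type rule's concern
        if not rule.lower <= number <= rule.upper:
            yield Violation(rule.table, i, rule.column, "range",
                            f"{value} outside [{rule.lower:g}, {rule.upper:g}]")


def _check_format(tables, rule):
    for i, row in _iter_rows(tables, rule):
        value = row[rule.column]
        if value == "":
            continue
        if _parse_date(value) is None:
            yield Violation(rule.table, i, rule.column, "format",
                            f"{value!r} is not {rule.date_format}")


def _check_cross_field(tables, rule):
    other_table = rule.other_table or rule.table
    if rule.relation == "requires":
        # presence dependency within one row (same table)
        for i, row in _iter_rows(tables, rule):
            if row[rule.column].strip() and not row.get(rule.other_column, "").strip():
                yield Violation(rule.table, i, rule.other_column, "cross_field",
                                f"{rule.column!r} present requires {rule.other_column!r}")
        return
    # date ordering, joined on patient ID when tables differ
    other_by_pid = {}
    if other_table != rule.table:
        for row in tables[other_table]:
            other_by_pid[row.get("Patient ID Number", "")] = row.get(rule.other_column, "")
    for i, row in _iter_rows(tables, rule):
        value = row[rule.column]
        if other_table == rule.table:
            other_value = row.get(rule.other_column, "")
        else:
            other_value = other_by_pid.get(row.get("Patient ID Number", ""), "")
        d1, d2 = _parse_date(value), _parse_date(other_value)
        if d1 is None or d2 is None:
            continue  # unevaluable; malformed dates are the format check's concern
        if rule.relation == "not_earlier_than" and d1 < d2:
            yield Violation(rule.table, i, rule.column, "cross_field",
                            f"{rule.column!r}={value} earlier than "
                            f"{rule.other_column!r}={other_value}")


_HANDLERS = {
    "type": _check_type,
    "mandatory": _check_mandatory,
    "range": _check_range,
    "format": _check_format,
    "cross_field": _check_cross_field,
}


def clean(tables: CohortTables, report: ValidationReport) -> CohortTables:
    """Blank violating cells; drop rows that failed a mandatory key check."""
    cleaned = tables.copy()
    drop_rows = report.mandatory_rows()
    for v in report.violations:
        if v.column in cleaned[v.table][v.row]:
            cleaned[v.table][v.row][v.column] = ""
    for name, rows in cleaned.tables.items():
        kept = [r for i, r in enumerate(rows) if (name, i) not in drop_rows]
        cleaned.tables[name] = kept
    return cleaned


def mapping_completeness(n_source_elements: int, n_mapped_elements: int) -> float:
    """Percentage of source data elements that survived into the graph."""
    if n_source_elements <= 0:
        raise UndefinedMetricFailure("mapping completeness undefined for zero source elements")
    if not 0 <= n_mapped_elements <= n_source_elements:
        raise ArgumentFailure("mapped element count must be within [0, source count]")
    return round(100.0 * n_mapped_elements / n_source_elements, 2)


# ---------------------------------------------------------------------------
# default rule set for the synthetic cohort schema

def default_rules() -> list[ValidationRule]:
    return [
        ValidationRule("type", "treatment_course", "Performance Status Value",
                       expected_type="integer"),
        ValidationRule("type", "treatment_course", "Prescription Dose",
                       expected_type="integer"),
        ValidationRule("mandatory", "demographics", "Patient ID Number"),
        ValidationRule("mandatory", "treatment_course", "RT Course ID"),
        ValidationRule("range", "demographics", "Marital Status", lower=1, upper=9),
        ValidationRule("range", "treatment_course", "Performance Status Value",
                       lower=0, upper=5),
        ValidationRule("format", "diagnosis", "Date of Diagnosis"),
        ValidationRule("format", "treatment_course", "Radiotherapy Treatment Start Date"),
        ValidationRule("cross_field", "treatment_course",
                       "Radiotherapy Treatment Start Date",
                       other_table="diagnosis", other_column="Date of Diagnosis",
                       relation="not_earlier_than"),
        ValidationRule("cross_field", "treatment_course",
                       "Performance Status Instrument",
                       other_column="Performance Status Value", relation="requires"),
        ValidationRule("cross_field", "treatment_course", "Prescription Dose",
                       other_column="Fraction Count", relation="requires"),
        ValidationRule("cross_field", "staging", "T Stage",
                       other_column="N Stage", relation="requires"),
        ValidationRule("cross_field", "staging", "T Stage",
                       other_column="M Stage", relation="requires"),
    ]


def load_rules(path: str | Path) -> list[ValidationRule]:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return [ValidationRule(**obj) for obj in raw]


def dump_rules(rules: list[ValidationRule], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps([{k: v for k, v in r.__dict__.items() if v is not None}
                    for r in rules], indent=1),
        encoding="utf-8",
    )
    return path
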