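"""Synthetic relational-style patient tables with a controlled error ledger.

The generator emulates the shape of a radiation-oncology clinical data
warehouse: five diagnosis groups, 18-25 categorical attributes per patient
spread over demographics / diagnosis / staging / treatment_course / toxicity
/ labs tables, plus a small 3-D dose grid per patient standing in for
DICOM-RT dose+structure pairs.  Group-conditional vocabularies (Gleason/PSA
only for prostate, histology differing by lung group, group-specific
toxicities) make same-group patients share more attribute values than
cross-group patients in expectation.

``inject_errors`` corrupts a clean cohort and returns a ground-truth ledger;
each injected cell violates exactly one of the five cleaning checks under
the default rule set, which is what makes the ledger usable as a validation
oracle.
"""

from __future__ import annotations

import copy
import csv
import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from rolhs.errors import ArgumentFailure

__all__ = [
    "CohortTables",
    "ErrorLedger",
    "LedgerEntry",
    "generate_cohort",
    "inject_errors",
    "attribute_count",
    "diff_tables",
    "GROUPS",
    "CHECKS",
]

# ---------------------------------------------------------------------------
# vocabularies (fixture constants, not claims about any real CDW)

GROUPS = (
    "Prostate Cancer",
    "Non-Small Cell Lung Cancer",
    "Small Cell Lung Cancer",
    "Breast Cancer",
    "Head and Neck Cancer",
)

GROUP_VOCAB: dict[str, dict[str, Sequence[str]]] = {
    "Prostate Cancer": {
        "dx_codes": ("C61",),
        "histology": ("Acinar Adenocarcinoma", "Adenocarcinoma"),
        "toxicity": ("Urinary Frequency", "Cystitis", "Fatigue"),
        "technique": ("IMRT", "VMAT", "SBRT"),
        "oar": ("Bladder",),
        "labs": ("PSA", "Creatinine"),
    },
    "Non-Small Cell Lung Cancer": {
        "dx_codes": ("C34.1", "C34.9"),
        "histology": ("Adenocarcinoma", "Squamous Cell Carcinoma"),
        "toxicity": ("Esophagitis", "Pneumonitis", "Fatigue", "Cough"),
        "technique": ("IMRT", "VMAT", "SBRT", "3D-CRT"),
        "oar": ("Lung_L", "Lung_R"),
        "labs": ("Hemoglobin", "Creatinine"),
    },
    "Small Cell Lung Cancer": {
        "dx_codes": ("C34.9",),
        "histology": ("Small Cell Carcinoma",),
        "toxicity": ("Esophagitis", "Fatigue", "Nausea"),
        "technique": ("IMRT", "3D-CRT"),
        "oar": ("Lung_L", "Lung_R"),
        "labs": ("Hemoglobin", "Creatinine"),
    },
    "Breast Cancer": {
        "dx_codes": ("C50.9",),
        "histology": ("Ductal Carcinoma", "Lobular Carcinoma"),
        "toxicity": ("Radiation Dermatitis", "Lymphedema", "Fatigue"),
        "technique": ("3D-CRT", "IMRT", "VMAT"),
        "oar": ("Heart",),
        "labs": ("Hemoglobin", "GFR"),
    },
    "Head and Neck Cancer": {
        "dx_codes": ("C76.0", "C32.9"),
        "histology": ("Squamous Cell Carcinoma", "Adenocarcinoma"),
        "toxicity": ("Mucositis", "Dysphagia", "Fatigue"),
        "technique": ("IMRT", "VMAT"),
        "oar": ("Parotid_L",),
        "labs": ("Creatinine", "GFR"),
    },
}

LATERAL_GROUPS = frozenset(
    {"Non-Small Cell Lung Cancer", "Small Cell Lung Cancer", "Breast Cancer"}
)

SEXES = ("Male", "Female")
RACES = ("White", "Black or African American", "Asian",
         "American Indian or Alaska Native", "Native Hawaiian or Other Pacific Islander")
ETHNICITIES = ("Hispanic or Latino", "Not Hispanic or Latino")
SMOKING = ("Never Smoker", "Former Smoker", "Current Smoker")
MODALITIES = ("Photon", "Electron", "Proton")
STAGE_GROUPS = ("Stage I", "Stage II", "Stage III", "Stage IV")
T_STAGES = ("T1", "T1a", "T1b", "T1c", "T2", "T2a", "T2b", "T3", "T4")
N_STAGES = ("N0", "N1", "N2", "N3")
M_STAGES = ("M0", "M1")
GLEASON = ("6", "7", "8", "9")
PSA_CATEGORIES = ("Low", "Intermediate", "High")
INTENTS = ("Curative", "Palliative")
LATERALITIES = ("Left", "Right")
PS_INSTRUMENTS = ("ECOG",)

TABLE_NAMES = (
    "demographics", "diagnosis", "staging", "treatment_course", "toxicity", "labs",
)

# categorical (table, column) pairs counted toward the 18-25 budget;
# derived columns (CTCAE Term), keys, dates and free numerics are excluded
CATEGORICAL_COLUMNS: dict[str, tuple[str, ...]] = {
    "demographics": ("Sex", "Race", "Ethnicity", "Marital Status", "Smoking Status"),
    "diagnosis": ("Diagnosis Group", "Diagnosis Code", "Histology", "Laterality"),
    "staging": ("T Stage", "N Stage", "M Stage", "Stage Group",
                "Gleason Score", "PSA Category"),
    "treatment_course": ("Modality", "Technique", "Treatment Intent",
                         "Performance Status Instrument", "Performance Status Value"),
    "toxicity": ("Toxicity", "Grade"),
    "labs": ("Lab Name", "Lab Category"),
}

CHECKS = ("type", "cross_field", "mandatory", "range", "format")

GRID_SHAPE = (12, 12, 12)
VOXEL_VOLUME_CM3 = 0.125


@dataclass
class DoseGridData:
    """Per-patient dose array plus named binary structure masks."""

    dose: np.ndarray                      # cGy, shape GRID_SHAPE
    masks: dict[str, np.ndarray]          # structure name -> bool array
    voxel_volume: float = VOXEL_VOLUME_CM3


@dataclass
class CohortTables:
    """Named relational-style tables; rows are plain dicts of strings."""

    tables: dict[str, list[dict[str, str]]]
    dose_grids: dict[str, DoseGridData] = field(default_factory=dict)

    def __getitem__(self, name: str) -> list[dict[str, str]]:
        return self.tables[name]

    def patient_ids(self) -> list[str]:
        return [row["Patient ID Number"] for row in self.tables["demographics"]]

    def copy(self) -> "CohortTables":
        return CohortTables(
            tables={name: [dict(r) for r in rows] for name, rows in self.tables.items()},
            dose_grids=self.dose_grids,  # grids are never corrupted; share
        )

    def cells(self) -> Iterator[tuple[str, int, str, str]]:
        for name, rows in self.tables.items():
            for i, row in enumerate(rows):
                for col, val in row.items():
                    yield name, i, col, val

    # -- export ------------------------------------------------------------

    def to_csv(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, rows in self.tables.items():
            path = directory / f"{name}.csv"
            columns: list[str] = []
            for row in rows:
                for col in row:
                    if col not in columns:
                        columns.append(col)
            with path.open("w", newline="", encoding="utf-8") as fh:
                writer = csv.DictWriter(fh, fieldnames=columns)
                writer.writeheader()
                writer.writerows(rows)
            written.append(path)
        return written

    @classmethod
    def from_csv(cls, directory: str | Path) -> "CohortTables":
        directory = Path(directory)
        tables = {}
        for name in TABLE_NAMES:
            path = directory / f"{name}.csv"
            if not path.exists():
                continue
            with path.open(newline="", encoding="utf-8") as fh:
                tables[name] = [dict(row) for row in csv.DictReader(fh)]
        return cls(tables=tables)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"tables": self.tables}, indent=1), encoding="utf-8")
        return path


@dataclass(frozen=True)
class LedgerEntry:
    table: str
    row: int
    column: str
    check: str


@dataclass
class ErrorLedger:
    """Ground truth for injected data-quality violations."""

    entries: list[LedgerEntry] = field(default_factory=list)

    def cell_set(self) -> set[tuple[str, int, str]]:
        return {(e.table, e.row, e.column) for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


def _pid(i: int) -> str:
    return f"P{i:04d}"


def _fmt(d: date) -> str:
    return d.strftime("%Y%m%d")


def generate_cohort(
    n_patients: int,
    group_weights: Sequence[float] = (1, 1, 1, 1, 1),
    seed: int = 0,
    with_dose_grids: bool = True,
) -> CohortTables:
    """Generate a clean synthetic cohort; reproducible for a given seed."""
    if n_patients <= 0:
        raise ArgumentFailure(f"n_patients must be positive, got {n_patients}")
    weights = np.asarray(group_weights, dtype=float)
    if weights.shape != (len(GROUPS),):
        raise ArgumentFailure(f"expected {len(GROUPS)} group weights")
    if (weights < 0).any() or weights.sum() == 0:
        raise ArgumentFailure("group weights must be non-negative and not all zero")
    rng = np.random.default_rng(seed)
    probs = weights / weights.sum()

    tables: dict[str, list[dict[str, str]]] = {name: [] for name in TABLE_NAMES}
    dose_grids: dict[str, DoseGridData] = {}

    group_idx = rng.choice(len(GROUPS), size=n_patients, p=probs)
    for i in range(n_patients):
        pid = _pid(i)
        group = GROUPS[group_idx[i]]
        vocab = GROUP_VOCAB[group]

        sex = "Male" if group == "Prostate Cancer" else (
            "Female" if group == "Breast Cancer" else str(rng.choice(SEXES)))
        tables["demographics"].append({
            "Patient ID Number": pid,
            "Sex": sex,
            "Race": str(rng.choice(RACES, p=(0.6, 0.2, 0.1, 0.05, 0.05))),
            "Ethnicity": str(rng.choice(ETHNICITIES, p=(0.15, 0.85))),
            "Marital Status": str(int(rng.integers(1, 10))),
            "Smoking Status": str(
                rng.choice(SMOKING)
                if "Lung" not in group
                else rng.choice(SMOKING, p=(0.1, 0.5, 0.4))
            ),
        })

        dx_date = date(2018, 1, 1) + timedelta(days=int(rng.integers(0, 1461)))
        # group-conditional columns stay present (blank) for a uniform schema
        tables["diagnosis"].append({
            "Patient ID Number": pid,
            "Diagnosis Group": group,
            "Diagnosis Code": str(rng.choice(vocab["dx_codes"])),
            "Histology": str(rng.choice(vocab["histology"])),
            "Laterality": (str(rng.choice(LATERALITIES))
                           if group in LATERAL_GROUPS else ""),
            "Date of Diagnosis": _fmt(dx_date),
        })

        is_prostate = group == "Prostate Cancer"
        tables["staging"].append({
            "Patient ID Number": pid,
            "T Stage": str(rng.choice(T_STAGES)),
            "N Stage": str(rng.choice(N_STAGES, p=(0.55, 0.25, 0.15, 0.05))),
            "M Stage": str(rng.choice(M_STAGES, p=(0.85, 0.15))),
            "Stage Group": str(rng.choice(STAGE_GROUPS)),
            "Gleason Score": str(rng.choice(GLEASON)) if is_prostate else "",
            "PSA Category": str(rng.choice(PSA_CATEGORIES)) if is_prostate else "",
        })

        rx_dose = int(rng.choice((5000, 6000, 6600, 7000, 7400, 7800)))
        fractions = max(1, round(rx_dose / 200))
        start = dx_date + timedelta(days=int(rng.integers(14, 91)))
        tables["treatment_course"].append({
            "Patient ID Number": pid,
            "RT Course ID": f"{pid}-C1",
            "Radiotherapy Treatment Start Date": _fmt(start),
            "Modality": str(rng.choice(MODALITIES, p=(0.9, 0.05, 0.05))),
            "Technique": str(rng.choice(vocab["technique"])),
            "Treatment Intent": str(rng.choice(INTENTS, p=(0.8, 0.2))),
            "Prescription Dose": str(rx_dose),
            "Fraction Count": str(fractions),
            "Performance Status Instrument": "ECOG",
            "Performance Status Value": str(int(rng.integers(0, 4))),
        })

        n_tox = int(rng.integers(1, 3))
        tox_terms = rng.choice(vocab["toxicity"], size=n_tox, replace=False)
        for term in tox_terms:
            grade = str(int(rng.integers(1, 4)))
            tables["toxicity"].append({
                "Patient ID Number": pid,
                "RT Course ID": f"{pid}-C1",
                "Toxicity": str(term),
                "Grade": grade,
                "CTCAE Term": f"{term} Grade {grade}",
            })

        lab = str(rng.choice(vocab["labs"]))
        tables["labs"].append({
            "Patient ID Number": pid,
            "Lab Name": lab,
            "Lab Value": f"{rng.uniform(0.5, 12.0):.2f}",
            "Lab Category": str(rng.choice(("Normal", "Abnormal"), p=(0.7, 0.3))),
        })

        if with_dose_grids:
            dose_grids[pid] = _make_dose_grid(rng, rx_dose, str(rng.choice(vocab["oar"])))

    return CohortTables(tables=tables, dose_grids=dose_grids)


def _make_dose_grid(rng: np.random.Generator, rx_dose: int, oar: str) -> DoseGridData:
    """Small gaussian-falloff dose blob with a PTV mask at the hot centre."""
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in GRID_SHAPE), indexing="ij")
    centre = np.array([s / 2 for s in GRID_SHAPE]) + rng.uniform(-1, 1, size=3)
    r2 = (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
    dose = rx_dose * np.exp(-r2 / (2 * 3.0**2))
    dose *= rng.uniform(0.97, 1.03, size=GRID_SHAPE)  # mild noise
    ptv = r2 <= 2.5**2
    oar_mask = (r2 > 3.0**2) & (r2 <= 5.0**2) & (xx > centre[2])
    if not oar_mask.any():
        oar_mask = r2 > 4.0**2
    return DoseGridData(dose=dose, masks={"PTV": ptv, oar: oar_mask})


def attribute_count(tables: CohortTables, pid: str) -> int:
    """Number of categorical attribute cells this patient carries."""
    count = 0
    for name, cols in CATEGORICAL_COLUMNS.items():
        for row in tables[name]:
            if row.get("Patient ID Number") == pid:
                count += sum(1 for c in cols if row.get(c, "") != "")
    return count


# ---------------------------------------------------------------------------
# error injection

# each check corrupts one fixed (table, column) so violations never overlap
_INJECTION_TARGETS = {
    "type": ("treatment_course", "Performance Status Value"),
    "cross_field": ("treatment_course", "Radiotherapy Treatment Start Date"),
    "mandatory": ("demographics", "Patient ID Number"),
    "range": ("demographics", "Marital Status"),
    "format": ("diagnosis", "Date of Diagnosis"),
}


def inject_errors(
    tables: CohortTables,
    rate_per_check: dict[str, float],
    seed: int = 0,
) -> tuple[CohortTables, ErrorLedger]:
    """Corrupt a clean cohort; returns (corrupted copy, ground-truth ledger).

    A ``format`` corruption of a diagnosis date would mask a ``cross_field``
    corruption of the same patient's RT start date (the comparison becomes
    unevaluable), so the two checks never select the same patient.
    """
    for check in rate_per_check:
        if check not in CHECKS:
            raise ArgumentFailure(f"unknown check {check!r}; valid: {CHECKS}")
    for check, rate in rate_per_check.items():
        if not 0.0 <= rate <= 1.0:
            raise ArgumentFailure(f"rate for {check!r} must be in [0,1], got {rate}")

    rng = np.random.default_rng(seed)
    corrupted = tables.copy()
    ledger = ErrorLedger()

    dx_dates = {
        row["Patient ID Number"]: row["Date of Diagnosis"]
        for row in tables["diagnosis"]
    }
    format_rows: set[str] = set()

    # fixed order so format picks happen before cross_field exclusion
    for check in ("mandatory", "type", "range", "format", "cross_field"):
        rate = rate_per_check.get(check, 0.0)
        if rate == 0.0:
            continue
        table, column = _INJECTION_TARGETS[check]
        rows = corrupted[table]
        for i, row in enumerate(rows):
            if rng.random() >= rate:
                continue
            pid = row.get("Patient ID Number", "")
            if check == "cross_field" and pid in format_rows:
                continue  # would be masked by the malformed diagnosis date
            if check == "mandatory":
                row[column] = ""
            elif check == "type":
                row[column] = "good"
            elif check == "range":
                row[column] = "12"
            elif check == "format":
                d = row[column]
                row[column] = f"{d[:4]}-{d[4:6]}-{d[6:]}"
                format_rows.add(pid)
            elif check == "cross_field":
                dx = dx_dates.get(pid)
                if dx is None:
                    continue
                early = date(int(dx[:4]), int(dx[4:6]), int(dx[6:])) - timedelta(days=100)
                row[column] = _fmt(early)
            ledger.entries.append(LedgerEntry(table, i, column, check))
    return corrupted, ledger


def diff_tables(a: CohortTables, b: CohortTables) -> set[tuple[str, int, str]]:
    """Cells whose values differ between two same-shaped cohorts."""
    cells = set()
    for name in a.tables:
        for i, (ra, rb) in enumerate(zip(a[name], b[name])):
            for col in set(ra) | set(rb):
                if ra.get(col, "") != rb.get(col, ""):
                    cells.add((name, i, col))
    return cells
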