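"""CSV readers/writers for EHR extracts and parsers for configuration artifacts.

Interchange dialect: UTF-8, comma-separated, header row required, ISO-8601
dates.  Five files describe a cohort::

    patients.csv   patient_id, birth_date, sex
    visits.csv     visit_id, patient_id, visit_date, reason_text, left_without_being_seen
    charts.csv     visit_id, specialty, heading, body
    labs.csv       visit_id, analyte, value, unit, positive
    diagnoses.csv  visit_id, icd10_code

Configuration artifacts (code spec, lexicon, keyword list, lab panel,
adjudication parameters) are YAML or JSON; see ``docs/methods.md``.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import defaults
from .errors import ConfigError, IntegrityError, SchemaError
from .records import (
    ChartEntry,
    LabResult,
    PatientRecord,
    Sex,
    Specialty,
    VisitRecord,
    ICD10_RE,
)

# ---------------------------------------------------------------------------
# cohort container

VISIT_COLUMNS = ["visit_id", "patient_id", "visit_date", "reason_text",
                 "left_without_being_seen"]
PATIENT_COLUMNS = ["patient_id", "birth_date", "sex"]
CHART_COLUMNS = ["visit_id", "specialty", "heading", "body"]
LAB_COLUMNS = ["visit_id", "analyte", "value", "unit", "positive"]
DIAGNOSIS_COLUMNS = ["visit_id", "icd10_code"]


@dataclass
class Cohort:
    """In-memory cohort: patient index plus a list of visit records."""

    patients: dict[str, PatientRecord] = field(default_factory=dict)
    visits: list[VisitRecord] = field(default_factory=list)
    #: counts of child rows referencing unknown visit_ids, per file kind
    orphans: dict[str, int] = field(default_factory=dict)

    def visit_index(self) -> dict[str, VisitRecord]:
        return {v.visit_id: v for v in self.visits}

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_visits(self) -> int:
        return len(self.visits)


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", "", "nan"}:
        return False
    raise SchemaError(f"cannot interpret {x!r} as a boolean")


def _read_csv(path, required: Sequence[str], kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{kind} file {path} is missing required column {col!r}")
    return df


def read_cohort(
    visits_path,
    charts_path,
    labs_path,
    diagnoses_path,
    patients_path=None,
) -> Cohort:
    """Load a cohort from CSV extracts.

    Child rows (charts, labs, diagnoses) referencing an unknown ``visit_id``
    are rejected and counted in :attr:`Cohort.orphans`.  A duplicate
    ``visit_id`` in the visits file raises :class:`IntegrityError`.
    """
    visits_df = _read_csv(visits_path, VISIT_COLUMNS, "visits")
    dup = visits_df["visit_id"].duplicated()
    if dup.any():
        raise IntegrityError(
            f"duplicate visit_id in {visits_path}: "
            f"{sorted(visits_df.loc[dup, 'visit_id'].unique())[:5]}"
        )

    cohort = Cohort()
    if patients_path is not None:
        pdf = _read_csv(patients_path, PATIENT_COLUMNS, "patients")
        if pdf["patient_id"].duplicated().any():
            raise IntegrityError(f"duplicate patient_id in {patients_path}")
        for row in pdf.itertuples(index=False):
            cohort.patients[row.patient_id] = PatientRecord(
                patient_id=row.patient_id,
                birth_date=_dt.date.fromisoformat(row.birth_date),
                sex=Sex(row.sex),
            )

    for row in visits_df.itertuples(index=False):
        cohort.visits.append(
            VisitRecord(
                visit_id=row.visit_id,
                patient_id=row.patient_id,
                visit_date=_dt.date.fromisoformat(row.visit_date),
                reason_text=row.reason_text,
                left_without_being_seen=_parse_bool(row.left_without_being_seen),
            )
        )
    index = cohort.visit_index()

    charts_df = _read_csv(charts_path, CHART_COLUMNS, "charts")
    orphans = {"charts": 0, "labs": 0, "diagnoses": 0}
    for row in charts_df.itertuples(index=False):
        visit = index.get(row.visit_id)
        if visit is None:
            orphans["charts"] += 1
            continue
        visit.charts.append(
            ChartEntry(specialty=Specialty(row.specialty), heading=row.heading,
                       body=row.body)
        )

    labs_df = _read_csv(labs_path, LAB_COLUMNS, "labs")
    for row in labs_df.itertuples(index=False):
        visit = index.get(row.visit_id)
        if visit is None:
            orphans["labs"] += 1
            continue
        value = float(row.value) if row.value != "" else 0.0
        if value < 0:
            raise SchemaError(f"negative lab value {row.value!r} for {row.analyte}")
        visit.labs.append(
            LabResult(analyte=row.analyte, value=value, unit=row.unit,
                      positive=_parse_bool(row.positive))
        )

    diag_df = _read_csv(diagnoses_path, DIAGNOSIS_COLUMNS, "diagnoses")
    for row in diag_df.itertuples(index=False):
        visit = index.get(row.visit_id)
        if visit is None:
            orphans["diagnoses"] += 1
            continue
        code = row.icd10_code.strip().upper()
        if not ICD10_RE.match(code):
            raise SchemaError(f"malformed ICD-10 code {row.icd10_code!r}")
        visit.diagnoses.append(code)

    cohort.orphans = orphans
    return cohort


def read_cohort_dir(directory) -> Cohort:
    """Load a cohort from a directory holding the five standard CSV files."""
    d = Path(directory)
    return read_cohort(
        d / "visits.csv", d / "charts.csv", d / "labs.csv", d / "diagnoses.csv",
        patients_path=(d / "patients.csv") if (d / "patients.csv").exists() else None,
    )


def cohort_frames(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """The five interchange tables of a cohort, as DataFrames."""
    patients = pd.DataFrame(
        [(p.patient_id, p.birth_date.isoformat(), p.sex.value)
         for p in cohort.patients.values()],
        columns=PATIENT_COLUMNS,
    )
    visits = pd.DataFrame(
        [(v.visit_id, v.patient_id, v.visit_date.isoformat(), v.reason_text,
          str(v.left_without_being_seen).lower())
         for v in cohort.visits],
        columns=VISIT_COLUMNS,
    )
    charts = pd.DataFrame(
        [(v.visit_id, c.specialty.value, c.heading, c.body)
         for v in cohort.visits for c in v.charts],
        columns=CHART_COLUMNS,
    )
    labs = pd.DataFrame(
        [(v.visit_id, l.analyte, repr(l.value), l.unit, str(l.positive).lower())
         for v in cohort.visits for l in v.labs],
        columns=LAB_COLUMNS,
    )
    diagnoses = pd.DataFrame(
        [(v.visit_id, code) for v in cohort.visits for code in v.diagnoses],
        columns=DIAGNOSIS_COLUMNS,
    )
    return {"patients": patients, "visits": visits, "charts": charts,
            "labs": labs, "diagnoses": diagnoses}


def write_cohort(cohort: Cohort, directory) -> None:
    """Write the five CSV files to *directory* (created if absent)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, frame in cohort_frames(cohort).items():
        frame.to_csv(d / f"{name}.csv", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# ICD-10 code specification

_RANGE_RE = re.compile(r"^([A-Z])([0-9]{2})\s*[-–]\s*([A-Z])([0-9]{2})$")
_SINGLE_RE = re.compile(r"^([A-Z][0-9]{2})(#?)$")


@dataclass(frozen=True)
class CodeSpec:
    """Declarative list of ICD-10 categories, '#'-categories and ranges."""

    entries: tuple[str, ...]


def expand_code_spec(spec: CodeSpec | Iterable[str]) -> frozenset[str]:
    """Expand a code specification to the set of three-character categories.

    Ranges are inclusive at category level ("T51-T65" gives the 15
    categories T51..T65; an en dash is accepted).  A trailing "#" is a
    display marker for "any subcode" and contributes its single category:
    the diagnosis matcher treats *every* category as matching any subcode.
    """
    entries = spec.entries if isinstance(spec, CodeSpec) else tuple(spec)
    out: set[str] = set()
    for raw in entries:
        entry = str(raw).strip().upper()
        m = _SINGLE_RE.match(entry)
        if m:
            out.add(m.group(1))
            continue
        m = _RANGE_RE.match(entry)
        if m:
            letter_lo, lo, letter_hi, hi = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
            if letter_lo != letter_hi:
                raise ConfigError(f"range {entry!r} spans different letter prefixes")
            if hi < lo:
                raise ConfigError(f"range {entry!r} has reversed bounds")
            out.update(f"{letter_lo}{i:02d}" for i in range(lo, hi + 1))
            continue
        raise ConfigError(f"malformed code-spec entry {raw!r}")
    return frozenset(out)


def default_code_spec() -> CodeSpec:
    return CodeSpec(entries=tuple(defaults.DEFAULT_CODE_SPEC))


# ---------------------------------------------------------------------------
# free-word-search lexicon

@dataclass(frozen=True)
class Concept:
    surface: str
    prefix_wildcard: bool = False
    variants: tuple[str, ...] = ()


@dataclass(frozen=True)
class Lexicon:
    concepts: tuple[Concept, ...]

    def __len__(self) -> int:
        return len(self.concepts)


def _normalise_entry(entry) -> Concept:
    if isinstance(entry, str):
        surface, variants = entry, ()
    elif isinstance(entry, Mapping):
        surface = entry.get("surface", "")
        variants = tuple(str(v) for v in entry.get("variants", ()))
    else:
        raise ConfigError(f"lexicon entry must be a string or mapping, got {entry!r}")
    surface = str(surface).strip()
    wildcard = surface.endswith("*")
    if wildcard:
        surface = surface[:-1]
    surface = surface.casefold()
    if not surface:
        raise ConfigError("lexicon entry has an empty surface")
    variants = tuple(
        dict.fromkeys(v.casefold() for v in variants if v.casefold() != surface)
    )
    return Concept(surface=surface, prefix_wildcard=wildcard, variants=variants)


def parse_lexicon(source) -> Lexicon:
    """Parse a lexicon from a YAML/JSON file path, YAML text, or entry list.

    Duplicate (surface, prefix_wildcard) pairs are collapsed, keeping the
    first occurrence (variants merged).
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        entries = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    elif isinstance(source, str):
        entries = yaml.safe_load(source)
    else:
        entries = list(source)
    if not isinstance(entries, list):
        raise ConfigError("lexicon must be a list of entries")
    seen: dict[tuple[str, bool], Concept] = {}
    for entry in entries:
        concept = _normalise_entry(entry)
        key = (concept.surface, concept.prefix_wildcard)
        if key in seen:
            merged = tuple(dict.fromkeys(seen[key].variants + concept.variants))
            seen[key] = Concept(concept.surface, concept.prefix_wildcard, merged)
        else:
            seen[key] = concept
    return Lexicon(concepts=tuple(seen.values()))


def default_lexicon() -> Lexicon:
    return parse_lexicon(list(defaults.DEFAULT_LEXICON_ENTRIES))


# ---------------------------------------------------------------------------
# run configuration

def load_config(path) -> dict:
    """Load a YAML/JSON run configuration file into a plain dict."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    loaded = yaml.safe_load(text)
    return loaded or {}
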