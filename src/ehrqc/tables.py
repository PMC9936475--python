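"""OMOP-lite data model: table schemas, bundle container, IO and invariant checking.

The dialect is a deliberately small subset of the OMOP common data model:
person, visit_occurrence, drug_exposure, measurement, condition_occurrence,
death, concept, concept_ancestor, plus a site metadata table. All dates are
day-resolution calendar dates (timestamps in input are truncated), intervals
are closed on both ends, and missing values are encoded by absence (NaN/NaT),
never by sentinel numbers.

Invalid rows are *flagged* by :func:`validate_bundle`, never dropped at load:
each analysis stage applies its own documented cleaning rules, mirroring the
stage-specific curation a multi-site extract requires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

DIALECT_VERSION = "1.0"

#: Measurement variables supported by the dialect (units fixed per variable).
MEASUREMENT_VARIABLES = (
    "BMI", "creatinine", "bilirubin", "PaO2", "FiO2", "body_temperature",
    "WBC", "ferritin", "CRP", "IL-6", "SpO2", "respiration_rate", "heart_rate",
)

MEASUREMENT_UNITS = {
    "BMI": "kg/m2", "creatinine": "mg/dL", "bilirubin": "mg/dL",
    "PaO2": "mmHg", "FiO2": "fraction", "body_temperature": "degC",
    "WBC": "10^3/uL", "ferritin": "ng/mL", "CRP": "mg/L", "IL-6": "pg/mL",
    "SpO2": "%", "respiration_rate": "breaths/min", "heart_rate": "beats/min",
}

VISIT_KINDS = ("inpatient", "emergency", "outpatient", "other")
SEX_VALUES = ("female", "male")
CONCEPT_LEVELS = ("ingredient", "clinical_drug", "branded_drug", "other")
SOURCE_CDMS = ("OMOP", "PCORnet", "ACT", "TriNetX")

# column -> logical type; "date" columns are parsed/serialized as ISO-8601
# and truncated to day resolution.
SCHEMA: dict[str, dict[str, str]] = {
    "person": {
        "person_id": "str", "site_id": "str", "birth_year": "int?",
        "sex": "str?", "race": "str?", "ethnicity": "str?",
    },
    "visit_occurrence": {
        "visit_id": "str", "person_id": "str", "site_id": "str",
        "visit_kind": "str", "start_date": "date", "end_date": "date?",
        "discharge_disposition": "str?",
    },
    "drug_exposure": {
        "person_id": "str", "site_id": "str", "concept_id": "int",
        "start_date": "date", "end_date": "date?", "drug_type_label": "str?",
    },
    "measurement": {
        "person_id": "str", "site_id": "str", "variable": "str",
        "value": "float", "date": "date",
    },
    "condition_occurrence": {
        "person_id": "str", "site_id": "str", "concept_id": "int",
        "date": "date",
    },
    "death": {
        "person_id": "str", "site_id": "str", "death_date": "date",
    },
    "concept": {
        "concept_id": "int", "name": "str", "level": "str",
    },
    "concept_ancestor": {
        "ancestor_id": "int", "descendant_id": "int",
    },
    "site": {
        "site_id": "str", "source_cdm": "str", "max_date_shift_days": "int",
    },
}

REQUIRED_TABLES = tuple(SCHEMA)


def _empty_table(name: str) -> pd.DataFrame:
    cols = {}
    for col, kind in SCHEMA[name].items():
        base = kind.rstrip("?")
        if base == "date":
            cols[col] = pd.Series(dtype="datetime64[ns]")
        elif base == "int":
            cols[col] = pd.Series(dtype="Int64")
        elif base == "float":
            cols[col] = pd.Series(dtype="float64")
        else:
            cols[col] = pd.Series(dtype="object")
    return pd.DataFrame(cols)


def coerce_table(name: str, df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a raw DataFrame to the dialect's schema for table ``name``.

    Unknown columns are dropped (warn-and-ignore at the load level); missing
    optional columns are added as all-missing. Dates are truncated to day
    resolution.
    """
    if name not in SCHEMA:
        raise KeyError(f"unknown table {name!r}")
    out = pd.DataFrame(index=df.index)
    for col, kind in SCHEMA[name].items():
        base = kind.rstrip("?")
        if col in df.columns:
            s = df[col]
        else:
            s = pd.Series([pd.NA] * len(df), index=df.index)
        if base == "date":
            s = pd.to_datetime(s, errors="coerce").dt.normalize()
        elif base == "int":
            s = pd.to_numeric(s, errors="coerce").astype("Int64")
        elif base == "float":
            s = pd.to_numeric(s, errors="coerce").astype("float64")
        else:
            s = s.astype("object")
            s = s.where(~pd.isna(s), None)
        out[col] = s
    return out


@dataclass
class EHRBundle:
    """One multi-site OMOP-lite extract held as a set of DataFrames."""

    person: pd.DataFrame
    visit_occurrence: pd.DataFrame
    drug_exposure: pd.DataFrame
    measurement: pd.DataFrame
    condition_occurrence: pd.DataFrame
    death: pd.DataFrame
    concept: pd.DataFrame
    concept_ancestor: pd.DataFrame
    site: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "EHRBundle":
        return cls(**{name: _empty_table(name) for name in REQUIRED_TABLES},
                   provenance={"dialect_version": DIALECT_VERSION})

    def tables(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for name in REQUIRED_TABLES:
            yield name, getattr(self, name)

    def copy(self) -> "EHRBundle":
        return EHRBundle(**{n: t.copy() for n, t in self.tables()},
                         provenance=dict(self.provenance))


@dataclass
class ValidationReport:
    """Itemized invariant violations, counted per (table, rule, site)."""

    items: pd.DataFrame  # columns: table, rule, site_id, count

    @property
    def is_clean(self) -> bool:
        return len(self.items) == 0

    def count(self, rule: str | None = None, table: str | None = None) -> int:
        df = self.items
        if rule is not None:
            df = df[df["rule"] == rule]
        if table is not None:
            df = df[df["table"] == table]
        return int(df["count"].sum())

    def summary(self) -> pd.DataFrame:
        return (self.items.groupby(["table", "rule"], as_index=False)["count"]
                .sum().sort_values(["table", "rule"]).reset_index(drop=True))


def _report_items(df: pd.DataFrame, mask: pd.Series, table: str,
                  rule: str) -> list[dict]:
    if not mask.any():
        return []
    if "site_id" in df.columns:
        counts = df.loc[mask].groupby("site_id", dropna=False).size()
        return [{"table": table, "rule": rule,
                 "site_id": (None if pd.isna(k) else k), "count": int(v)}
                for k, v in counts.items()]
    return [{"table": table, "rule": rule, "site_id": None,
             "count": int(mask.sum())}]


def validate_bundle(bundle: EHRBundle) -> ValidationReport:
    """Check all dialect invariants; report violations, never mutate.

    Rules checked (rule names appear in the report):

    - ``duplicate_person_id``, ``implausible_birth_year``,
      ``missing_birth_year``, ``missing_sex``, ``invalid_sex``
    - ``visit_end_before_start``, ``invalid_visit_kind``
    - ``reversed_drug_interval``, ``unresolvable_drug_concept``
    - ``unknown_measurement_variable``, ``nonfinite_measurement_value``
    - ``unresolvable_condition_concept``
    - ``multiple_death_records``
    - ``orphan_person_reference`` (rows pointing at an unknown person),
      ``orphan_site_reference``
    - ``duplicate_site_row``, ``invalid_source_cdm``
    - ``cyclic_concept_ancestry``
    """
    items: list[dict] = []
    p = bundle.person
    items += _report_items(p, p["person_id"].duplicated(keep=False),
                           "person", "duplicate_person_id")
    by = pd.to_numeric(p["birth_year"], errors="coerce")
    items += _report_items(p, by.notna() & ~by.between(1900, 2021),
                           "person", "implausible_birth_year")
    items += _report_items(p, by.isna(), "person", "missing_birth_year")
    sex = p["sex"]
    items += _report_items(p, pd.isna(sex), "person", "missing_sex")
    items += _report_items(p, sex.notna() & ~sex.isin(SEX_VALUES),
                           "person", "invalid_sex")

    v = bundle.visit_occurrence
    bad_end = v["end_date"].notna() & (v["end_date"] < v["start_date"])
    items += _report_items(v, bad_end, "visit_occurrence",
                           "visit_end_before_start")
    items += _report_items(v, ~v["visit_kind"].isin(VISIT_KINDS),
                           "visit_occurrence", "invalid_visit_kind")

    d = bundle.drug_exposure
    rev = d["end_date"].notna() & (d["end_date"] < d["start_date"])
    items += _report_items(d, rev, "drug_exposure", "reversed_drug_interval")
    known = set(bundle.concept["concept_id"].dropna().astype(int))
    items += _report_items(d, ~d["concept_id"].isin(known),
                           "drug_exposure", "unresolvable_drug_concept")

    m = bundle.measurement
    items += _report_items(m, ~m["variable"].isin(MEASUREMENT_VARIABLES),
                           "measurement", "unknown_measurement_variable")
    items += _report_items(m, ~np.isfinite(m["value"].to_numpy(dtype=float)),
                           "measurement", "nonfinite_measurement_value")

    c = bundle.condition_occurrence
    items += _report_items(c, ~c["concept_id"].isin(known),
                           "condition_occurrence",
                           "unresolvable_condition_concept")

    de = bundle.death
    items += _report_items(de, de["person_id"].duplicated(keep=False),
                           "death", "multiple_death_records")

    persons = set(p["person_id"].dropna())
    sites = set(bundle.site["site_id"].dropna())
    for name in ("visit_occurrence", "drug_exposure", "measurement",
                 "condition_occurrence", "death"):
        t = getattr(bundle, name)
        items += _report_items(t, ~t["person_id"].isin(persons),
                               name, "orphan_person_reference")
        items += _report_items(t, ~t["site_id"].isin(sites),
                               name, "orphan_site_reference")
    items += _report_items(p, ~p["site_id"].isin(sites),
                           "person", "orphan_site_reference")

    s = bundle.site
    items += _report_items(s, s["site_id"].duplicated(keep=False),
                           "site", "duplicate_site_row")
    items += _report_items(s, ~s["source_cdm"].isin(SOURCE_CDMS),
                           "site", "invalid_source_cdm")

    if _ancestry_has_cycle(bundle.concept_ancestor):
        items.append({"table": "concept_ancestor",
                      "rule": "cyclic_concept_ancestry",
                      "site_id": None, "count": 1})

    df = pd.DataFrame(items, columns=["table", "rule", "site_id", "count"])
    return ValidationReport(items=df)


def _ancestry_has_cycle(anc: pd.DataFrame) -> bool:
    # Kahn's algorithm on the directed edge set, ignoring self-loops
    # (every ingredient is its own ancestor by convention).
    edges = anc[anc["ancestor_id"] != anc["descendant_id"]]
    children: dict[int, list[int]] = {}
    indeg: dict[int, int] = {}
    for a, b in zip(edges["ancestor_id"], edges["descendant_id"]):
        a, b = int(a), int(b)
        children.setdefault(a, []).append(b)
        indeg[b] = indeg.get(b, 0) + 1
        indeg.setdefault(a, 0)
    queue = [n for n, k in indeg.items() if k == 0]
    seen = 0
    while queue:
        n = queue.pop()
        seen += 1
        for ch in children.get(n, ()):
            indeg[ch] -= 1
            if indeg[ch] == 0:
                queue.append(ch)
    return seen < len(indeg)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _date_columns(name: str) -> list[str]:
    return [c for c, k in SCHEMA[name].items() if k.rstrip("?") == "date"]


def write_bundle(bundle: EHRBundle, path: str | Path,
                 format: str = "csv") -> Path:
    """Write one file per table (RFC-4180 CSV with ISO-8601 dates, or
    Parquet with identical schema) plus a machine-readable dialect schema."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if format not in ("csv", "parquet"):
        raise ValueError(f"unsupported format {format!r}")
    for name, df in bundle.tables():
        df = coerce_table(name, df)
        if format == "csv":
            out = df.copy()
            for col in _date_columns(name):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
            out.to_csv(path / f"{name}.csv", index=False)
        else:
            df.to_parquet(path / f"{name}.parquet", index=False)
    schema_doc = {
        "dialect_version": DIALECT_VERSION,
        "tables": SCHEMA,
        "measurement_units": MEASUREMENT_UNITS,
        "notes": "dates ISO-8601 day resolution; intervals closed; "
                 "missing encoded by absence",
    }
    (path / "dialect.json").write_text(json.dumps(schema_doc, indent=2))
    return path


def load_bundle(path: str | Path, format: str = "csv") -> EHRBundle:
    """Load a bundle directory, coercing to the dialect schema.

    A missing required table is fatal (the error names all missing tables);
    unknown columns are ignored. Invariant violations are *not* raised here —
    call :func:`validate_bundle` to collect them.
    """
    path = Path(path)
    ext = {"csv": "csv", "parquet": "parquet"}[format]
    missing = [n for n in REQUIRED_TABLES
               if not (path / f"{n}.{ext}").exists()]
    if missing:
        raise FileNotFoundError(
            f"bundle at {path} is missing required tables: "
            + ", ".join(sorted(missing)))
    tables = {}
    for name in REQUIRED_TABLES:
        f = path / f"{name}.{ext}"
        raw = pd.read_csv(f) if format == "csv" else pd.read_parquet(f)
        tables[name] = coerce_table(name, raw)
    prov = {"dialect_version": DIALECT_VERSION, "source_path": str(path),
            "format": format}
    return EHRBundle(**tables, provenance=prov)
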