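"""Cohort schemas, validation, and delimited-text readers/writers.

One non-temporal patient table plus five temporal event tables, all
comma-delimited UTF-8 with a header row:

* ``patients.csv``   — one row per patient (demographics, comorbidity
  flags, labs at registration, treatment flags).
* ``scr.csv``        — serum-creatinine measurements with timestamps at
  hour resolution (``YYYY-MM-DDTHH``) and age at measurement.
* ``ct.csv``         — CT-scan dates.
* ``iv_chemo.csv``   — IV chemotherapeutic administrations with a
  nephrotoxicity class (yes / no / unknown).
* ``oral_chemo.csv`` — oral chemotherapeutics, same classes.
* ``nephrotoxic.csv``— nephrotoxic drug prescriptions grouped as
  ACEI_ARB vs DIURETIC, with an optional duration in days.

Dates are ISO-8601; the null marker is the empty field; categorical
labels are case-sensitive exact strings.  Date-only sources are assigned
hour 00:00 of their date, and multi-day prescriptions are expanded to
one event per covered day at load time, so in-memory events always have
``duration_days == 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TEMPORAL_FILES = ("scr", "ct", "iv_chemo", "oral_chemo", "nephrotoxic")
EVENT_KINDS = {"ct": "CT", "iv_chemo": "IV_CHEMO",
               "oral_chemo": "ORAL_CHEMO", "nephrotoxic": "NEPHROTOXIC"}
NEPHROTOXICITY_LEVELS = ("yes", "no", "unknown")
DRUG_GROUPS = ("ACEI_ARB", "DIURETIC")
EVENT_COLUMNS = ["patient_id", "time", "kind", "nephrotoxicity",
                 "drug_group", "duration_days"]


def default_schema() -> dict:
    """The versioned column schema shipped with the package."""
    text = resources.files("akih").joinpath("_schema.yaml").read_text("utf-8")
    return yaml.safe_load(text)


@dataclass
class Cohort:
    """Validated in-memory cohort.

    ``patients`` is indexed by patient_id; ``scr`` and ``events`` are
    long tables sorted by (patient_id, time).
    """

    patients: pd.DataFrame
    scr: pd.DataFrame
    events: pd.DataFrame
    read_log: dict = field(default_factory=dict, compare=False)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def subset(self, patient_ids) -> "Cohort":
        keep = self.patients.index.isin(patient_ids)
        pats = self.patients.loc[keep]
        return Cohort(
            patients=pats,
            scr=self.scr[self.scr["patient_id"].isin(pats.index)].reset_index(drop=True),
            events=self.events[self.events["patient_id"].isin(pats.index)].reset_index(drop=True),
        )

    def equals(self, other: "Cohort") -> bool:
        try:
            pd.testing.assert_frame_equal(self.patients, other.patients,
                                          check_like=True)
            pd.testing.assert_frame_equal(
                self.scr.reset_index(drop=True), other.scr.reset_index(drop=True))
            pd.testing.assert_frame_equal(
                self.events.reset_index(drop=True), other.events.reset_index(drop=True))
        except AssertionError:
            return False
        return True


def _parse_column(raw: pd.Series, ctype: str, errors: list, fname: str):
    """Coerce a string column per its schema type; record row errors."""
    if ctype in ("id", "category"):
        return raw.astype(object)  # nulls stay NaN
    if ctype == "bool":
        mapped = raw.map({"true": True, "false": False})
        bad = raw.notna() & mapped.isna()
        for idx in raw.index[bad]:
            errors.append({"file": fname, "line": int(idx) + 2,
                           "column": raw.name, "value": raw[idx],
                           "reason": "unparseable bool"})
        return mapped.astype(object)
    if ctype in ("float", "int"):
        vals = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & vals.isna()
        for idx in raw.index[bad]:
            errors.append({"file": fname, "line": int(idx) + 2,
                           "column": raw.name, "value": raw[idx],
                           "reason": "unparseable number"})
        return vals.astype(float)
    if ctype in ("date", "timestamp"):
        fmt = "%Y-%m-%d" if ctype == "date" else "%Y-%m-%dT%H"
        vals = pd.to_datetime(raw, format=fmt, errors="coerce")
        bad = raw.notna() & vals.isna()
        for idx in raw.index[bad]:
            errors.append({"file": fname, "line": int(idx) + 2,
                           "column": raw.name, "value": raw[idx],
                           "reason": "unparseable date"})
        return vals
    raise ValueError(f"unknown schema type {ctype!r}")


def _read_table(path: Path, colspec: dict, errors: list) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace("", np.nan)
    unknown = [c for c in df.columns if c not in colspec]
    if unknown:
        raise ValueError(f"{path.name}: columns not in schema: {unknown}")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        out[col] = _parse_column(df[col], colspec[col], errors, path.name)
    return out


def read_cohort(directory, schema: dict | None = None) -> Cohort:
    """Read and validate the six cohort tables from ``directory``.

    Rows violating type or value constraints are rejected with row-level
    diagnostics; temporal rows referencing unknown patients are dropped
    and counted.  Missing files are fatal for patients.csv and scr.csv;
    event files may be absent (empty streams).
    """
    directory = Path(directory)
    schema = schema or default_schema()
    errors: list[dict] = []
    log: dict = {"row_errors": errors, "dropped": {}}

    ppath = directory / "patients.csv"
    if not ppath.exists():
        raise FileNotFoundError(ppath)
    patients = _read_table(ppath, schema["patients"], errors)
    if patients["patient_id"].isna().any():
        raise ValueError("patients.csv: null patient_id")
    dup = patients["patient_id"].duplicated(keep="first")
    if dup.any():
        log["dropped"]["duplicate_patients"] = int(dup.sum())
        patients = patients[~dup]
    patients = patients.set_index("patient_id")
    known = set(patients.index)

    spath = directory / "scr.csv"
    if not spath.exists():
        raise FileNotFoundError(spath)
    scr = _read_table(spath, schema["scr"], errors)
    bad_value = ~(scr["value"] > 0)
    log["dropped"]["scr_nonpositive"] = int(bad_value.sum())
    bad_time = scr["time"].isna()
    unknown_pat = ~scr["patient_id"].isin(known)
    log["dropped"]["scr_unknown_patient"] = int((unknown_pat & ~bad_value).sum())
    scr = scr[~(bad_value | bad_time | unknown_pat)]
    scr = scr.sort_values(["patient_id", "time", "value"], kind="mergesort")
    # timestamp collisions: keep the smaller value (conservative toward non-AKI)
    dup_ts = scr.duplicated(["patient_id", "time"], keep="first")
    log["dropped"]["scr_time_collisions"] = int(dup_ts.sum())
    scr = scr[~dup_ts].reset_index(drop=True)

    frames = []
    for name in TEMPORAL_FILES[1:]:
        path = directory / f"{name}.csv"
        if not path.exists():
            continue
        tab = _read_table(path, schema[name], errors)
        tab = tab[tab["date"].notna()]
        bad_pat = ~tab["patient_id"].isin(known)
        log["dropped"][f"{name}_unknown_patient"] = int(bad_pat.sum())
        tab = tab[~bad_pat]
        ev = pd.DataFrame({
            "patient_id": tab["patient_id"],
            "time": tab["date"],
            "kind": EVENT_KINDS[name],
            "nephrotoxicity": tab.get("nephrotoxicity"),
            "drug_group": tab.get("drug_group"),
            "duration_days": tab.get(
                "duration_days", pd.Series(1.0, index=tab.index)).fillna(1.0),
        })
        frames.append(ev)
    if frames:
        events = pd.concat(frames, ignore_index=True)
        events = _expand_durations(events)
    else:
        events = _empty_events()
    events = events.sort_values(["patient_id", "time", "kind"],
                                kind="mergesort").reset_index(drop=True)
    if errors:
        logger.warning("read_cohort: %d row errors", len(errors))
    return Cohort(patients=patients, scr=scr, events=events, read_log=log)


def _empty_events() -> pd.DataFrame:
    ev = pd.DataFrame(columns=EVENT_COLUMNS)
    ev["time"] = pd.to_datetime(ev["time"])
    ev["duration_days"] = ev["duration_days"].astype(int)
    return ev


def _expand_durations(events: pd.DataFrame) -> pd.DataFrame:
    """One event per covered day: a prescription spanning d days becomes
    d daily events ("whether dosed" within a window needs day coverage)."""
    dur = events["duration_days"].astype(int).clip(lower=1)
    events = events.loc[events.index.repeat(dur)].copy()
    offset = events.groupby(level=0).cumcount()
    events["time"] = events["time"] + pd.to_timedelta(offset, unit="D")
    events["duration_days"] = 1
    return events.reset_index(drop=True)[EVENT_COLUMNS]


def _format_column(series: pd.Series, ctype: str) -> pd.Series:
    if ctype == "bool":
        return series.map({True: "true", False: "false"})
    if ctype == "date":
        return pd.to_datetime(series).dt.strftime("%Y-%m-%d")
    if ctype == "timestamp":
        return pd.to_datetime(series).dt.strftime("%Y-%m-%dT%H")
    if ctype == "int":
        return series.map(lambda v: "" if pd.isna(v) else str(int(v)))
    return series


def write_cohort(cohort: Cohort, directory, schema: dict | None = None) -> dict:
    """Write the six tables; ``read_cohort(write_cohort(c))`` is lossless.

    Returns the mapping of table name to file path.  Optional fields are
    emitted as empty-string nulls; header-only files are written for
    empty streams.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    schema = schema or default_schema()
    paths = {}

    pats = cohort.patients.reset_index()
    out = pd.DataFrame(index=pats.index)
    for col, ctype in schema["patients"].items():
        if col in pats.columns:
            out[col] = _format_column(pats[col], ctype)
    extra = [c for c in pats.columns if c not in schema["patients"]]
    if extra:
        raise ValueError(f"patients table has columns outside the schema: {extra}")
    paths["patients"] = directory / "patients.csv"
    out.to_csv(paths["patients"], index=False)

    scr = cohort.scr.copy()
    for col, ctype in schema["scr"].items():
        scr[col] = _format_column(scr[col], ctype)
    paths["scr"] = directory / "scr.csv"
    scr[list(schema["scr"])].to_csv(paths["scr"], index=False)

    for name in TEMPORAL_FILES[1:]:
        kind = EVENT_KINDS[name]
        sub = cohort.events[cohort.events["kind"] == kind].copy()
        cols = list(schema[name])
        tab = pd.DataFrame(index=sub.index)
        for col in cols:
            src = "date" if col == "date" else col
            if col == "date":
                tab[col] = _format_column(sub["time"], "date")
            else:
                tab[col] = _format_column(sub[col], schema[name][col])
        paths[name] = directory / f"{name}.csv"
        tab.to_csv(paths[name], index=False)
    return paths


def validate_cohort(cohort: Cohort) -> list[dict]:
    """Pure invariant check: returns one entry per violation (empty = valid)."""
    report: list[dict] = []

    if cohort.patients.index.has_duplicates:
        for pid in cohort.patients.index[cohort.patients.index.duplicated()]:
            report.append({"patient_id": pid, "field": "patient_id",
                           "message": "duplicate patient_id"})
    for field_name in ("registration_date", "sex"):
        if field_name not in cohort.patients.columns:
            report.append({"patient_id": None, "field": field_name,
                           "message": "column missing"})
            continue
        for pid in cohort.patients.index[cohort.patients[field_name].isna()]:
            report.append({"patient_id": pid, "field": field_name,
                           "message": "required field is null"})
    bad_sex = ~cohort.patients["sex"].isin(["male", "female"]) if "sex" in cohort.patients else None
    if bad_sex is not None:
        for pid in cohort.patients.index[bad_sex & cohort.patients["sex"].notna()]:
            report.append({"patient_id": pid, "field": "sex",
                           "message": "sex not in {male, female}"})

    known = set(cohort.patients.index)
    for pid in cohort.scr.loc[~cohort.scr["patient_id"].isin(known), "patient_id"].unique():
        report.append({"patient_id": pid, "field": "scr.patient_id",
                       "message": "SCr stream references unknown patient"})
    nonpos = ~(cohort.scr["value"] > 0)
    for pid in cohort.scr.loc[nonpos, "patient_id"].unique():
        report.append({"patient_id": pid, "field": "scr.value",
                       "message": "non-positive SCr value"})
    for pid, grp in cohort.scr.groupby("patient_id", sort=True):
        if not grp["time"].is_monotonic_increasing:
            report.append({"patient_id": pid, "field": "scr.time",
                           "message": "SCr stream not sorted ascending"})

    for pid in cohort.events.loc[~cohort.events["patient_id"].isin(known), "patient_id"].unique():
        report.append({"patient_id": pid, "field": "events.patient_id",
                       "message": "event stream references unknown patient"})
    ev = cohort.events
    chem = ev["kind"].isin(["IV_CHEMO", "ORAL_CHEMO"])
    bad_tox = chem & ~ev["nephrotoxicity"].isin(NEPHROTOXICITY_LEVELS)
    for pid in ev.loc[bad_tox, "patient_id"].unique():
        report.append({"patient_id": pid, "field": "events.nephrotoxicity",
                       "message": "chemo event without valid nephrotoxicity class"})
    neph = ev["kind"] == "NEPHROTOXIC"
    bad_grp = neph & ~ev["drug_group"].isin(DRUG_GROUPS)
    for pid in ev.loc[bad_grp, "patient_id"].unique():
        report.append({"patient_id": pid, "field": "events.drug_group",
                       "message": "nephrotoxic event without valid drug group"})
    return report
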