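import numpy as np
import pandas as pd
import pytest

from akih.io import Cohort, EVENT_COLUMNS
from akih.synth import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """100-patient synthetic cohort shared by read-only tests."""
    return generate_cohort(SyntheticConfig(n_patients=100, seed=11))


def make_cohort(patients_rows, scr_rows, event_rows=()):
    """Hand-build a cohort from plain tuples.

    patients_rows: (pid, registration_date, sex, birth_date, dialysis)
    scr_rows:      (pid, timestamp, value, age)
    event_rows:    (pid, timestamp, kind, nephrotoxicity, drug_group)
    """
    patients = pd.DataFrame(
        patients_rows, columns=["patient_id", "registration_date", "sex",
                                "birth_date", "maintenance_dialysis"])
    patients["registration_date"] = pd.to_datetime(patients["registration_date"])
    patients["birth_date"] = pd.to_datetime(patients["birth_date"])
    patients["maintenance_dialysis"] = patients["maintenance_dialysis"].astype(object)
    patients = patients.set_index("patient_id")
    scr = pd.DataFrame(scr_rows, columns=["patient_id", "time", "value",
                                          "age_at_measurement"])
    scr["time"] = pd.to_datetime(scr["time"])
    scr = scr.sort_values(["patient_id", "time"]).reset_index(drop=True)
    ev = pd.DataFrame(
        [(p, pd.Timestamp(t), k, tox, grp, 1)
         for p, t, k, tox, grp in event_rows], columns=EVENT_COLUMNS)
    if ev.empty:
        ev["time"] = pd.to_datetime(ev["time"])
    return Cohort(patients=patients, scr=scr, events=ev)


@pytest.fixture
def crafted_cohort():
    """Five hand-crafted patients exercising every feature-row skip rule.

    A: long dense history, several eligible rows.  B: history too short
    (nothing older than 30 d).  C: no SCr in any horizon (single late
    cluster).  D: sparse outpatient with a gap.  E: eligible rows plus
    exposure events of every stream.
    """
    reg = "2010-01-01"
    rows_p, rows_s, rows_e = [], [], []
    for pid in "ABCDE":
        rows_p.append((pid, reg, "male" if pid in "ACE" else "female",
                       "1960-06-01", False))

    t0 = pd.Timestamp("2010-01-01")
    # A: measurement every 10 days for 300 days, mild rise in the middle
    for k in range(31):
        rows_s.append(("A", t0 + pd.Timedelta(days=10 * k, hours=9),
                       1.0 + (0.8 if 12 <= k <= 14 else 0.0), 50.0))
    # B: burst of 5 measurements over 8 days only
    for k in range(5):
        rows_s.append(("B", t0 + pd.Timedelta(days=2 * k), 0.9, 49.0))
    # C: old anchor then a final cluster with no horizon after it
    rows_s.append(("C", t0, 1.1, 60.0))
    rows_s.append(("C", t0 + pd.Timedelta(days=100), 1.1, 60.3))
    rows_s.append(("C", t0 + pd.Timedelta(days=130), 1.2, 60.4))
    # D: outpatient cadence, 40-day gaps
    for k in range(8):
        rows_s.append(("D", t0 + pd.Timedelta(days=40 * k, hours=14),
                       0.7 + 0.01 * k, 71.0))
    # E: dense with exposures
    for k in range(40):
        rows_s.append(("E", t0 + pd.Timedelta(days=5 * k, hours=11),
                       1.2 + 0.002 * k, 55.0))
    rows_e = [
        ("E", t0 + pd.Timedelta(days=80), "CT", None, None),
        ("E", t0 + pd.Timedelta(days=95), "CT", None, None),
        ("E", t0 + pd.Timedelta(days=90), "IV_CHEMO", "yes", None),
        ("E", t0 + pd.Timedelta(days=91), "IV_CHEMO", "no", None),
        ("E", t0 + pd.Timedelta(days=60), "IV_CHEMO", "unknown", None),
        ("E", t0 + pd.Timedelta(days=85), "ORAL_CHEMO", "yes", None),
        ("E", t0 + pd.Timedelta(days=88), "ORAL_CHEMO", "unknown", None),
        ("E", t0 + pd.Timedelta(days=99), "NEPHROTOXIC", None, "ACEI_ARB"),
        ("E", t0 + pd.Timedelta(days=40), "NEPHROTOXIC", None, "DIURETIC"),
    ]
    return make_cohort(rows_p, rows_s, rows_e)


@pytest.fixture
def crafted_nontemporal(crafted_cohort):
    return pd.DataFrame({"age_at_diagnosis": [50.0, 49.0, 60.0, 71.0, 55.0],
                         "diabetes": [0.0, 1.0, 0.0, 1.0, 0.0]},
                        index=list("ABCDE"))
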