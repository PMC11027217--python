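import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ddiprev.types import StudyWindow, SyntheticConfig

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=60)
settings.load_profile("suite")


@pytest.fixture
def daily_window():
    return StudyWindow(dt.date(2014, 1, 1), dt.date(2015, 6, 30), "daily")


@pytest.fixture
def monthly_window():
    return StudyWindow(dt.date(2014, 1, 1), dt.date(2015, 6, 30), "monthly")


@pytest.fixture
def patients_small():
    return pd.DataFrame({
        "patient_id": ["p1", "p2", "p3", "p4"],
        "gender": ["W", "M", "W", "M"],
        "birth_date": pd.to_datetime(
            ["1960-05-01", "1950-01-15", "2000-01-01", "1980-07-07"]),
    })


def make_records(rows, window):
    """rows: (patient_id, drug_id, start_day_offset, duration)."""
    start0 = window.start_ts
    return pd.DataFrame({
        "patient_id": [r[0] for r in rows],
        "drug_id": [r[1] for r in rows],
        "start": [start0 + pd.Timedelta(days=r[2]) for r in rows],
        "duration": np.array([r[3] for r in rows], dtype=np.int64),
    })


def brute_force_pairs(records, window):
    """Independent oracle: materialize every (patient, drug, day) triple and
    intersect day sets per unordered pair.

    Returns {(patient, i, j): (alpha, lambda_ij, lambda_i, lambda_j)}.
    """
    day_sets = {}
    for r in records.itertuples(index=False):
        days = day_sets.setdefault((r.patient_id, r.drug_id), set())
        off = (pd.Timestamp(r.start) - window.start_ts).days
        days.update(range(off, off + int(r.duration)))
    by_patient = {}
    for (pid, drug), days in day_sets.items():
        by_patient.setdefault(pid, {})[drug] = days
    out = {}
    for pid, drugs in by_patient.items():
        names = sorted(drugs)
        for a_i in range(len(names)):
            for b_i in range(a_i + 1, len(names)):
                i, j = names[a_i], names[b_i]
                shared = drugs[i] & drugs[j]
                if not shared:
                    continue
                runs = 0
                for d in sorted(shared):
                    if d - 1 not in shared:
                        runs += 1
                out[(pid, i, j)] = (runs, len(shared),
                                    len(drugs[i]), len(drugs[j]))
    return out


@pytest.fixture
def small_synth_daily():
    cfg = SyntheticConfig(n_patients=400, seed=42, ddi_fraction=0.05)
    from ddiprev import synthetic as sy
    patients = sy.generate_population(cfg)
    records = sy.generate_dispensations(patients, cfg)
    ddi = sy.generate_ddi_reference(cfg)
    return cfg, patients, records, ddi
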