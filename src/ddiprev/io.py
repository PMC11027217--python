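"""Reading, validation and canonicalization of the four input tables.

All tables are delimited text (comma by default, tab accepted) with a header
row. Dates are ISO-8601; billing months are written as ``YYYY-MM``. In-memory
representations are plain pandas DataFrames:

* patients:       ``patient_id, gender, birth_date``
* dispensations:  ``patient_id, drug_id, start, duration``
* DDI reference:  ``drug_a, drug_b, severity`` (canonically ordered pairs)
* drug classes:   ``class_id, drug_id``

Day intervals are half-open ``[start, start + duration)``; in monthly mode
``start`` is the first day of the billing month and ``duration`` is 1 month.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import DataError, SEVERITIES, StudyWindow

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = ["patient_id", "gender", "birth_date"]
DISPENSATION_COLUMNS = ["patient_id", "drug_id", "start", "duration"]
DDI_COLUMNS = ["drug_a", "drug_b", "severity"]
CLASS_COLUMNS = ["class_id", "drug_id"]


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       keep_default_na=False)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_dates(raw: pd.Series, path, what: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    bad = parsed.isna() & raw.ne("")
    bad |= raw.eq("")
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise DataError(
            f"{path}: unparsable {what} in file row(s) {rows[:20]}"
            + (" ..." if len(rows) > 20 else "")
        )
    return parsed


# ---------------------------------------------------------------------------
# patients


def read_patients(path, study_end=None) -> pd.DataFrame:
    """Read the demographics table; genders outside {W, M} are excluded
    with a logged count (the analysis is two-gender only)."""
    df = _read_delimited(path)
    _require_columns(df, PATIENT_COLUMNS, path)
    df = df[PATIENT_COLUMNS].copy()
    df["birth_date"] = _parse_dates(df["birth_date"], path, "birth_date")
    keep = df["gender"].isin(["W", "M"])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_patients: excluded %d rows with gender outside {W, M}",
                    n_dropped)
        df = df[keep]
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].unique()[:5]
        raise DataError(f"{path}: duplicate patient_id values, e.g. {list(dups)}")
    if study_end is not None:
        late = df["birth_date"] > pd.Timestamp(study_end)
        if late.any():
            raise DataError(
                f"{path}: {int(late.sum())} patient(s) born after the study end"
            )
    return df.reset_index(drop=True)


def write_patients(df: pd.DataFrame, path) -> None:
    out = df[PATIENT_COLUMNS].copy()
    out["birth_date"] = pd.to_datetime(out["birth_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dispensations


def read_dispensations(path, window: StudyWindow) -> pd.DataFrame:
    """Read and canonicalize a dispensation table.

    Daily mode: records are clipped to the window (a record spanning the
    window end keeps its final day equal to the window's final day); rows
    with no overlap are dropped. Monthly mode: months outside the window are
    dropped and duration is forced to 1. Exact duplicate rows are
    deduplicated with a logged count; malformed rows raise DataError citing
    file row numbers.
    """
    df = _read_delimited(path)
    _require_columns(df, ["patient_id", "drug_id", "start"], path)
    if window.resolution == "daily":
        _require_columns(df, ["duration"], path)
    df = df.copy()
    n0 = len(df)
    df = df.drop_duplicates(subset=[c for c in DISPENSATION_COLUMNS
                                    if c in df.columns])
    if len(df) < n0:
        logger.info("read_dispensations: removed %d exact duplicate rows",
                    n0 - len(df))
    if df.empty:
        return pd.DataFrame({
            "patient_id": pd.Series(dtype=str),
            "drug_id": pd.Series(dtype=str),
            "start": pd.Series(dtype="datetime64[ns]"),
            "duration": pd.Series(dtype=np.int64),
        })
    empty_drug = df["drug_id"].eq("")
    if empty_drug.any():
        rows = (np.flatnonzero(empty_drug.to_numpy()) + 2).tolist()
        raise DataError(f"{path}: empty drug_id in file row(s) {rows[:20]}")
    start = _parse_dates(df["start"], path, "start date")

    if window.resolution == "monthly":
        start = start.dt.to_period("M").dt.to_timestamp()
        out = pd.DataFrame({
            "patient_id": df["patient_id"].to_numpy(),
            "drug_id": df["drug_id"].to_numpy(),
            "start": start.to_numpy(),
            "duration": np.int64(1),
        })
        lo = window.start_ts.to_period("M").to_timestamp()
        hi = pd.Timestamp(window.end).to_period("M").to_timestamp()
        out = out[(out["start"] >= lo) & (out["start"] <= hi)]
        out = out.drop_duplicates(subset=["patient_id", "drug_id", "start"])
        return out.sort_values(["patient_id", "drug_id", "start"],
                               kind="stable").reset_index(drop=True)

    dur_raw = pd.to_numeric(df["duration"], errors="coerce")
    bad = dur_raw.isna() | (dur_raw < 1) | (dur_raw != dur_raw.round())
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        raise DataError(
            f"{path}: invalid duration (must be a positive integer number of "
            f"days) in file row(s) {rows[:20]}"
        )
    out = pd.DataFrame({
        "patient_id": df["patient_id"].to_numpy(),
        "drug_id": df["drug_id"].to_numpy(),
        "start": start.to_numpy(),
        "duration": dur_raw.astype(np.int64).to_numpy(),
    })
    return clip_to_window(out, window)


def clip_to_window(records: pd.DataFrame, window: StudyWindow) -> pd.DataFrame:
    """Clip daily records to the window; drop records with no overlap."""
    end = records["start"] + pd.to_timedelta(records["duration"], unit="D")
    new_start = records["start"].clip(lower=window.start_ts)
    new_end = end.clip(upper=window.end_ts)
    keep = new_end > new_start
    out = records.loc[keep].copy()
    out["start"] = new_start[keep]
    out["duration"] = (new_end[keep] - new_start[keep]).dt.days.astype(np.int64)
    return out.sort_values(["patient_id", "drug_id", "start"],
                           kind="stable").reset_index(drop=True)


def write_dispensations(df: pd.DataFrame, path, resolution: str = "daily") -> None:
    out = df[DISPENSATION_COLUMNS].copy()
    start = pd.to_datetime(out["start"])
    if resolution == "monthly":
        out["start"] = start.dt.strftime("%Y-%m")
        out["duration"] = 1
    else:
        out["start"] = start.dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# DDI reference


def canonicalize_ddi(df: pd.DataFrame, source="DDI reference") -> pd.DataFrame:
    """Canonically order pairs (drug_a < drug_b), reject self-pairs,
    duplicates and severity conflicts."""
    a = df["drug_a"].astype(str).to_numpy()
    b = df["drug_b"].astype(str).to_numpy()
    if (a == b).any():
        raise DataError(f"{source}: self-pairs are not allowed")
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    out = pd.DataFrame({"drug_a": lo, "drug_b": hi,
                        "severity": df["severity"].astype(str).to_numpy()})
    bad_sev = ~out["severity"].isin(SEVERITIES)
    if bad_sev.any():
        tokens = sorted(out.loc[bad_sev, "severity"].unique())
        raise DataError(
            f"{source}: unknown severity token(s) {tokens}; allowed tokens are "
            f"{list(SEVERITIES)}"
        )
    grouped = out.groupby(["drug_a", "drug_b"])["severity"].nunique()
    conflicts = grouped[grouped > 1]
    if len(conflicts):
        pairs = list(conflicts.index[:5])
        raise DataError(
            f"{source}: conflicting severities for pair(s) {pairs}"
        )
    out = out.drop_duplicates()
    return out.sort_values(["drug_a", "drug_b"], kind="stable").reset_index(drop=True)


def read_ddi_reference(path) -> pd.DataFrame:
    df = _read_delimited(path)
    _require_columns(df, DDI_COLUMNS, path)
    if df.empty:
        return pd.DataFrame({c: pd.Series(dtype=str) for c in DDI_COLUMNS})
    return canonicalize_ddi(df[DDI_COLUMNS], source=str(path))


def write_ddi_reference(df: pd.DataFrame, path) -> None:
    df[DDI_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# drug classes


def read_drug_classes(path) -> pd.DataFrame:
    df = _read_delimited(path)
    _require_columns(df, CLASS_COLUMNS, path)
    df = df[CLASS_COLUMNS].drop_duplicates()
    return df.reset_index(drop=True)


def write_drug_classes(df: pd.DataFrame, path) -> None:
    df[CLASS_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# interval canonicalization


def merge_same_drug_intervals(records: pd.DataFrame,
                              resolution: str = "daily") -> pd.DataFrame:
    """Merge overlapping or abutting day intervals per (patient, drug).

    Refills that overlap or abut form one continuous administration episode,
    so after merging the episode count per (patient, drug) is the number of
    disjoint episodes and the summed duration is the number of distinct
    administration days. Half-open arithmetic: [0,10) and [10,12) merge.
    """
    if resolution != "daily":
        raise DataError("merge_same_drug_intervals requires daily-resolution records")
    if records.empty:
        return records.copy()
    df = records.sort_values(["patient_id", "drug_id", "start"],
                             kind="stable").reset_index(drop=True)
    start = df["start"].to_numpy()
    end = start + pd.to_timedelta(df["duration"], unit="D").to_numpy()
    key = (df["patient_id"] + "\x00" + df["drug_id"]).to_numpy()
    new_group = np.ones(len(df), dtype=bool)
    new_group[1:] = key[1:] != key[:-1]
    group_id = np.cumsum(new_group)
    # running max of interval ends within each (patient, drug) group
    end_cummax = pd.Series(end).groupby(group_id).cummax().to_numpy()
    prev_cummax = np.empty_like(end_cummax)
    prev_cummax[1:] = end_cummax[:-1]
    # episode break: start strictly after the running end of the previous rows
    breaks = new_group | (start > prev_cummax)
    breaks[new_group] = True
    episode_id = np.cumsum(breaks)
    out = pd.DataFrame({
        "patient_id": df["patient_id"],
        "drug_id": df["drug_id"],
        "start": df["start"],
        "_end": end,
        "_ep": episode_id,
    })
    agg = out.groupby("_ep", sort=True).agg(
        patient_id=("patient_id", "first"),
        drug_id=("drug_id", "first"),
        start=("start", "min"),
        end=("_end", "max"),
    )
    agg["duration"] = (agg["end"] - agg["start"]).dt.days.astype(np.int64)
    res = agg[["patient_id", "drug_id", "start", "duration"]]
    return res.sort_values(["patient_id", "drug_id", "start"],
                           kind="stable").reset_index(drop=True)
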