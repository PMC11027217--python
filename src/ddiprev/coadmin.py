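"""Per-patient co-administration episodes and the pairwise γ/τ statistics.

Two drugs are co-administered by a patient when their administration day
sets share at least one day (daily resolution) or when both are billed in
the same calendar month (monthly resolution). Per patient and unordered
drug pair (i, j) this module computes:

* ``alpha`` — the number of disjoint co-administration episodes,
* ``lambda_ij`` — the total co-administered time units,
* ``tau`` — the normalized co-administration length
  λ_ij / (λ_i + λ_j − λ_ij) ∈ (0, 1], i.e. the Jaccard overlap of the two
  drugs' administered time units; 1 at complete temporal overlap.

Population-level aggregation yields the directed conditional likelihoods
γ_ij = |U_ij| / |U_i| and the pair's mean strength of co-administration,
the edge weights of the co-administration graph.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as dio
from .types import DataError, StudyWindow

PAIR_KEY = ["patient_id", "drug_i", "drug_j"]


def pair_intervals(records: pd.DataFrame, window: StudyWindow) -> pd.DataFrame:
    """Disjoint co-administration episodes, one row per episode.

    Columns: patient_id, drug_i, drug_j (canonical order, drug_i < drug_j),
    start (episode start), length (shared days, or 1 per shared month).
    """
    empty = pd.DataFrame({
        "patient_id": pd.Series(dtype=str),
        "drug_i": pd.Series(dtype=str),
        "drug_j": pd.Series(dtype=str),
        "start": pd.Series(dtype="datetime64[ns]"),
        "length": pd.Series(dtype=np.int64),
    })
    if records.empty:
        return empty

    if window.resolution == "monthly":
        m = records.drop_duplicates(subset=["patient_id", "drug_id", "start"])
        j = m.merge(m, on=["patient_id", "start"], suffixes=("_i", "_j"))
        j = j[j["drug_id_i"] < j["drug_id_j"]]
        if j.empty:
            return empty
        out = pd.DataFrame({
            "patient_id": j["patient_id"].to_numpy(),
            "drug_i": j["drug_id_i"].to_numpy(),
            "drug_j": j["drug_id_j"].to_numpy(),
            "start": j["start"].to_numpy(),
            "length": np.int64(1),
        })
        return out.sort_values(PAIR_KEY + ["start"],
                               kind="stable").reset_index(drop=True)

    merged = dio.merge_same_drug_intervals(records)
    merged = merged.assign(
        _end=merged["start"] + pd.to_timedelta(merged["duration"], unit="D")
    )
    j = merged.merge(merged, on="patient_id", suffixes=("_i", "_j"))
    j = j[j["drug_id_i"] < j["drug_id_j"]]
    if j.empty:
        return empty
    ov_start = np.maximum(j["start_i"].to_numpy(), j["start_j"].to_numpy())
    ov_end = np.minimum(j["_end_i"].to_numpy(), j["_end_j"].to_numpy())
    keep = ov_end > ov_start
    # Per-drug intervals are merged (disjoint, non-abutting), so pairwise
    # overlap fragments are themselves disjoint, non-abutting episodes.
    out = pd.DataFrame({
        "patient_id": j["patient_id"].to_numpy()[keep],
        "drug_i": j["drug_id_i"].to_numpy()[keep],
        "drug_j": j["drug_id_j"].to_numpy()[keep],
        "start": ov_start[keep],
        "length": ((ov_end[keep] - ov_start[keep])
                   / np.timedelta64(1, "D")).astype(np.int64),
    })
    return out.sort_values(PAIR_KEY + ["start"],
                           kind="stable").reset_index(drop=True)


def drug_time_totals(records: pd.DataFrame, window: StudyWindow) -> pd.DataFrame:
    """λ_i per (patient, drug): distinct administration days or months."""
    if records.empty:
        return pd.DataFrame({
            "patient_id": pd.Series(dtype=str),
            "drug_id": pd.Series(dtype=str),
            "lambda_": pd.Series(dtype=np.int64),
        })
    if window.resolution == "monthly":
        m = records.drop_duplicates(subset=["patient_id", "drug_id", "start"])
        g = m.groupby(["patient_id", "drug_id"], sort=True)["start"].size()
    else:
        merged = dio.merge_same_drug_intervals(records)
        g = merged.groupby(["patient_id", "drug_id"], sort=True)["duration"].sum()
    return g.rename("lambda_").reset_index()


def tau_patient(lambda_i, lambda_j, lambda_ij):
    """Strength of co-administration for one patient and pair.

    τ = λ_ij / (λ_i + λ_j − λ_ij): the fraction of the union of the two
    drugs' administered time units that is shared. Symmetric in (i, j),
    bounded in (0, 1], and 1 exactly when the day sets coincide.
    """
    lam_i = np.asarray(lambda_i, dtype=float)
    lam_j = np.asarray(lambda_j, dtype=float)
    lam_ij = np.asarray(lambda_ij, dtype=float)
    return lam_ij / (lam_i + lam_j - lam_ij)


def detect_pair_episodes(records: pd.DataFrame, ddi: pd.DataFrame,
                         window: StudyWindow) -> pd.DataFrame:
    """Per (patient, pair) co-administration summary.

    Columns: patient_id, drug_i, drug_j, alpha (disjoint episodes),
    lambda_ij, lambda_i, lambda_j, tau, first_start, is_ddi, severity.
    """
    intervals = pair_intervals(records, window)
    return aggregate_pair_episodes(intervals, records, ddi, window)


def aggregate_pair_episodes(intervals: pd.DataFrame, records: pd.DataFrame,
                            ddi: pd.DataFrame,
                            window: StudyWindow) -> pd.DataFrame:
    if intervals.empty:
        return pd.DataFrame(columns=PAIR_KEY + [
            "alpha", "lambda_ij", "lambda_i", "lambda_j", "tau",
            "first_start", "is_ddi", "severity",
        ])
    g = intervals.groupby(PAIR_KEY, sort=True)
    out = g.agg(alpha=("length", "size"),
                lambda_ij=("length", "sum"),
                first_start=("start", "min")).reset_index()
    totals = drug_time_totals(records, window)
    out = out.merge(
        totals.rename(columns={"drug_id": "drug_i", "lambda_": "lambda_i"}),
        on=["patient_id", "drug_i"], how="left",
    ).merge(
        totals.rename(columns={"drug_id": "drug_j", "lambda_": "lambda_j"}),
        on=["patient_id", "drug_j"], how="left",
    )
    bad = out["lambda_ij"] > np.minimum(out["lambda_i"], out["lambda_j"])
    if bad.any():
        raise DataError("aggregate_pair_episodes: co-administered time exceeds "
                        "a drug's total administered time")
    out["tau"] = tau_patient(out["lambda_i"], out["lambda_j"], out["lambda_ij"])
    out = annotate_ddi(out, ddi)
    return out


def annotate_ddi(pairs: pd.DataFrame, ddi: pd.DataFrame) -> pd.DataFrame:
    """Attach is_ddi/severity by lookup of the canonical pair."""
    out = pairs.copy()
    if ddi is None or len(ddi) == 0:
        out["is_ddi"] = False
        out["severity"] = pd.Series([pd.NA] * len(out), dtype="string")
        return out
    ref = ddi.rename(columns={"drug_a": "drug_i", "drug_b": "drug_j"})
    out = out.merge(ref, on=["drug_i", "drug_j"], how="left")
    out["is_ddi"] = out["severity"].notna()
    out["severity"] = out["severity"].astype("string")
    return out


def pair_population_stats(episodes: pd.DataFrame, records: pd.DataFrame,
                          window: StudyWindow) -> pd.DataFrame:
    """Population-level pair statistics: γ in both directions and mean τ.

    ``episodes`` is the per-(patient, pair) table from
    :func:`detect_pair_episodes`; a pair is counted once per patient.
    """
    cols = ["drug_i", "drug_j", "n_users_i", "n_users_j", "n_coadmin_users",
            "gamma_ij", "gamma_ji", "tau_mean", "is_ddi", "severity"]
    if episodes.empty:
        return pd.DataFrame(columns=cols)
    users = records.groupby("drug_id")["patient_id"].nunique()
    g = episodes.groupby(["drug_i", "drug_j"], sort=True)
    out = g.agg(n_coadmin_users=("patient_id", "nunique"),
                tau_mean=("tau", "mean"),
                is_ddi=("is_ddi", "first"),
                severity=("severity", "first")).reset_index()
    out["n_users_i"] = users.reindex(out["drug_i"]).to_numpy()
    out["n_users_j"] = users.reindex(out["drug_j"]).to_numpy()
    out["gamma_ij"] = out["n_coadmin_users"] / out["n_users_i"]
    out["gamma_ji"] = out["n_coadmin_users"] / out["n_users_j"]
    return out[cols]
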