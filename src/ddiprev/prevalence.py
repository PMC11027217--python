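"""Stratified prevalence of co-administration (PC) and interaction (PI),
and gender relative risks with exact tests.

PC is the fraction of patients with at least one co-administered drug pair;
PI the fraction with at least one co-administered pair that is a known
interaction. Strata are gender × 5-year age bin × severity. Patient age is
computed at the date of the drug event, so one patient can contribute to
several age bins; a stratum's denominator is the number of patients with at
least one administration in that stratum.

The relative risk for women, RR^W = prevalence(W) / prevalence(M), is
tested with a two-sided Fisher exact test on the 2×2 of gender ×
affected/unaffected, with Benjamini–Hochberg (default) or Bonferroni
correction across the strata of one report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coadmin import annotate_ddi
from .types import AGE_BIN_LABELS, DataError, SEVERITIES

MEASURES = ("coadmin", "any", "major", "moderate", "minor")


def completed_years(birth_dates, event_dates) -> np.ndarray:
    """Completed-years age at each event date (vectorized)."""
    b = pd.DatetimeIndex(birth_dates)
    e = pd.DatetimeIndex(event_dates)
    yrs = e.year - b.year
    adj = (b.month > e.month) | ((b.month == e.month) & (b.day > e.day))
    return (yrs - adj.astype(int)).to_numpy()


def assign_age_bins(events: pd.DataFrame, patients: pd.DataFrame,
                    date_col: str = "start") -> pd.DataFrame:
    """Tag each event row with the patient's age and 5-year age bin at the
    event's start date. Negative ages are a data error."""
    birth = patients.set_index("patient_id")["birth_date"]
    b = birth.reindex(events["patient_id"])
    if b.isna().any():
        missing = sorted(set(events.loc[b.isna().to_numpy(),
                                        "patient_id"]))[:5]
        raise DataError(f"assign_age_bins: unknown patient id(s) {missing}")
    age = completed_years(b.to_numpy(), events[date_col].to_numpy())
    if (age < 0).any():
        n_bad = int((age < 0).sum())
        raise DataError(
            f"assign_age_bins: {n_bad} event(s) dated before patient birth"
        )
    out = events.copy()
    out["age"] = age
    bin_idx = np.minimum(age // 5, len(AGE_BIN_LABELS) - 1)
    out["age_bin"] = np.asarray(AGE_BIN_LABELS, dtype=object)[bin_idx]
    return out


def _affected_tables(intervals: pd.DataFrame, records: pd.DataFrame,
                     patients: pd.DataFrame, ddi: pd.DataFrame):
    """Distinct (patient, gender, age_bin) membership tables for the
    denominator, co-administration, and each interaction severity."""
    gender = patients.set_index("patient_id")["gender"]

    recs = assign_age_bins(records, patients)
    denom = recs[["patient_id", "age_bin"]].drop_duplicates()
    denom["gender"] = gender.reindex(denom["patient_id"]).to_numpy()

    if len(intervals):
        ints = assign_age_bins(intervals, patients)
        ints = annotate_ddi(ints, ddi)
        co = ints[["patient_id", "age_bin"]].drop_duplicates()
        co["gender"] = gender.reindex(co["patient_id"]).to_numpy()
        hits = {}
        ddi_ints = ints[ints["is_ddi"]]
        hits["any"] = ddi_ints
        for sev in SEVERITIES:
            hits[sev] = ddi_ints[ddi_ints["severity"] == sev]
        affected = {}
        for key, sub in hits.items():
            t = sub[["patient_id", "age_bin"]].drop_duplicates()
            t = t.copy()
            t["gender"] = gender.reindex(t["patient_id"]).to_numpy()
            affected[key] = t
    else:
        co = denom.iloc[0:0]
        affected = {k: denom.iloc[0:0] for k in ("any",) + SEVERITIES}
    return denom, co, affected


def _count_cells(table: pd.DataFrame) -> pd.Series:
    """Distinct-patient counts for every (gender, age_bin) cell including
    'all' margins."""
    pieces = []
    for gsel in ("W", "M", "all"):
        sub = table if gsel == "all" else table[table["gender"] == gsel]
        per_bin = sub.groupby("age_bin")["patient_id"].nunique()
        per_bin.index = pd.MultiIndex.from_product([[gsel], per_bin.index])
        pieces.append(per_bin)
        total = pd.Series({(gsel, "all"): sub["patient_id"].nunique()})
        pieces.append(total)
    return pd.concat(pieces) if pieces else pd.Series(dtype=int)


def compute_prevalence(intervals: pd.DataFrame, records: pd.DataFrame,
                       patients: pd.DataFrame, ddi: pd.DataFrame,
                       ) -> pd.DataFrame:
    """PC and PI per (gender, age_bin, severity) stratum.

    Severity strata are non-exclusive: a patient with one major and one
    moderate interaction counts in both. Rows with an empty denominator get
    null prevalences and ``empty = True``.
    """
    denom, co, affected = _affected_tables(intervals, records, patients, ddi)
    n_pat = _count_cells(denom)
    n_co = _count_cells(co)
    n_aff = {k: _count_cells(v) for k, v in affected.items()}

    bins = [b for b in AGE_BIN_LABELS if ("W", b) in n_pat.index
            or ("M", b) in n_pat.index or ("all", b) in n_pat.index]
    rows = []
    for gsel in ("W", "M", "all"):
        for age_bin in bins + ["all"]:
            key = (gsel, age_bin)
            np_ = int(n_pat.get(key, 0))
            nc = int(n_co.get(key, 0))
            for sev in ("any",) + SEVERITIES:
                ni = int(n_aff[sev].get(key, 0))
                rows.append({
                    "gender": gsel, "age_bin": age_bin, "severity": sev,
                    "n_patients": np_, "n_coadmin": nc, "n_interact": ni,
                    "pc": nc / np_ if np_ else np.nan,
                    "pi": ni / np_ if np_ else np.nan,
                    "empty": np_ == 0,
                })
    return pd.DataFrame(rows)


def relative_risk_from_prevalence(prev_w: float, prev_m: float) -> float:
    """Relative risk for women: prevalence in women / prevalence in men."""
    if prev_m == 0:
        return np.inf if prev_w > 0 else np.nan
    return prev_w / prev_m


def relative_risk(n_aff_w: int, n_w: int, n_aff_m: int, n_m: int) -> dict:
    """Point RR for women (and its reciprocal for men) plus a two-sided
    Fisher exact p-value from the gender × affected 2×2 table."""
    if n_w <= 0 or n_m <= 0:
        raise ValueError("relative_risk: both gender denominators must be > 0")
    rr_w = relative_risk_from_prevalence(n_aff_w / n_w, n_aff_m / n_m)
    rr_m = (1.0 / rr_w) if np.isfinite(rr_w) and rr_w > 0 else (
        np.inf if rr_w == 0 else np.nan if np.isnan(rr_w) else 0.0)
    table = [[n_aff_w, n_w - n_aff_w], [n_aff_m, n_m - n_aff_m]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {"rr_women": rr_w, "rr_men": rr_m, "p_value": float(p),
            "n_aff_w": n_aff_w, "n_w": n_w, "n_aff_m": n_aff_m, "n_m": n_m}


def gender_relative_risks(prev: pd.DataFrame, correction: str = "fdr",
                          alpha: float = 0.05) -> pd.DataFrame:
    """RRC/RRI per (age_bin, measure) with multiplicity-corrected
    significance flags.

    ``measure`` is 'coadmin' (RRC) or an interaction severity filter
    ('any', 'major', 'moderate', 'minor') for RRI.
    """
    if correction not in ("fdr", "bonferroni"):
        raise ValueError("correction must be 'fdr' or 'bonferroni'")
    w = prev[prev["gender"] == "W"].set_index(["age_bin", "severity"])
    m = prev[prev["gender"] == "M"].set_index(["age_bin", "severity"])
    rows = []
    age_bins = prev["age_bin"].unique()
    for age_bin in age_bins:
        for measure in MEASURES:
            sev = "any" if measure == "coadmin" else measure
            try:
                rw = w.loc[(age_bin, sev)]
                rm = m.loc[(age_bin, sev)]
            except KeyError:
                continue
            if rw["n_patients"] == 0 or rm["n_patients"] == 0:
                continue
            col = "n_coadmin" if measure == "coadmin" else "n_interact"
            res = relative_risk(int(rw[col]), int(rw["n_patients"]),
                                int(rm[col]), int(rm["n_patients"]))
            res.update({"age_bin": age_bin, "measure": measure})
            rows.append(res)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    method = "fdr_bh" if correction == "fdr" else "bonferroni"
    rej, p_adj, _, _ = multipletests(out["p_value"], alpha=alpha, method=method)
    out["p_adjusted"] = p_adj
    out["significant"] = rej
    front = ["age_bin", "measure", "rr_women", "rr_men", "p_value",
             "p_adjusted", "significant"]
    return out[front + [c for c in out.columns if c not in front]]
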