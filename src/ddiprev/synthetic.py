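"""Synthetic EHR-like cohort generator.

Generates populations, dispensation histories, interaction references and
drug-class tables with the statistical structure the downstream analysis
assumes:

* drug popularity follows a rank power law (a few hub drugs dominate);
* the number of distinct drugs per patient is negative-binomial with a mean
  that increases linearly with age (polypharmacy);
* a small subset of drugs is gender-specific (contraceptive-like);
* optional planted effects multiply the probability that a chosen drug pair
  is dispensed with temporal overlap inside a gender/age stratum, enabling
  parameter-recovery experiments for stratified relative risks.

All randomness flows from ``SyntheticConfig.seed`` through named substreams
so each table can be regenerated independently and deterministically.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import io as dio
from ._sampling import weighted_distinct
from .types import (
    DataError,
    N_AGE_BINS,
    SEVERITIES,
    SyntheticConfig,
    PlantedEffect,
    StudyWindow,
)

_SUBSTREAMS = {
    "population": 1,
    "gender_drugs": 2,
    "drug_sets": 3,
    "dispensations": 4,
    "ddi": 5,
    "planted": 7,
}


def _rng(seed: int, name: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _SUBSTREAMS[name], int(index)])
    )


def drug_ids(n_drugs: int) -> list[str]:
    """Drug identifiers in popularity-rank order (D0001 most popular)."""
    return [f"D{k:04d}" for k in range(1, n_drugs + 1)]


def popularity_weights(config: SyntheticConfig) -> np.ndarray:
    ranks = np.arange(1, config.n_drugs + 1, dtype=float)
    w = ranks ** (-config.popularity_exponent)
    return w / w.sum()


def gender_specific_drugs(config: SyntheticConfig) -> tuple[set[int], set[int]]:
    """Indices of women-only and men-only drugs (disjoint)."""
    n_gs = int(round(config.gender_specific_fraction * config.n_drugs))
    if n_gs == 0:
        return set(), set()
    rng = _rng(config.seed, "gender_drugs")
    chosen = rng.choice(config.n_drugs, size=n_gs, replace=False)
    half = (n_gs + 1) // 2
    return set(chosen[:half].tolist()), set(chosen[half:].tolist())


# ---------------------------------------------------------------------------
# population


def generate_population(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the demographics table: id, gender, birth date.

    Ages at study start are uniform over ``age_range`` (completed years);
    gender is W with probability ``gender_ratio``.
    """
    config.validate()
    rng = _rng(config.seed, "population")
    n = config.n_patients
    gender = np.where(rng.random(n) < config.gender_ratio, "W", "M")
    lo, hi = config.age_range
    age_years = rng.uniform(lo, hi + 1, size=n)
    start = config.window.start_ts
    birth = start - pd.to_timedelta(np.floor(age_years * 365.25).astype(np.int64),
                                    unit="D")
    return pd.DataFrame({
        "patient_id": [f"P{i:06d}" for i in range(1, n + 1)],
        "gender": gender,
        "birth_date": birth,
    })


# ---------------------------------------------------------------------------
# dispensations


def _completed_years(birth: np.ndarray, at: pd.Timestamp) -> np.ndarray:
    b = pd.DatetimeIndex(birth)
    yrs = at.year - b.year
    adj = (b.month > at.month) | ((b.month == at.month) & (b.day > at.day))
    return (yrs - adj.astype(int)).to_numpy()


def generate_dispensations(patients: pd.DataFrame,
                           config: SyntheticConfig) -> pd.DataFrame:
    """Generate the dispensation table for a synthetic population."""
    if patients.empty:
        raise DataError("generate_dispensations: patient table is empty")
    config.validate()
    window = config.window
    rng_sets = _rng(config.seed, "drug_sets")
    rng_disp = _rng(config.seed, "dispensations")

    ages = _completed_years(patients["birth_date"].to_numpy(), window.start_ts)
    mean = np.maximum(
        config.baseline_mean_drugs + config.polypharmacy_slope * ages / 10.0,
        0.05,
    )
    r = config.drug_count_dispersion
    n_distinct = rng_sets.negative_binomial(r, r / (r + mean))

    w = popularity_weights(config)
    w_only, m_only = gender_specific_drugs(config)
    weights_by_gender = {}
    for g in ("W", "M"):
        wg = w.copy()
        blocked = m_only if g == "W" else w_only
        if blocked:
            wg[list(blocked)] = 0.0
        weights_by_gender[g] = wg

    rows_pid: list[np.ndarray] = []
    rows_drug: list[np.ndarray] = []
    gender_arr = patients["gender"].to_numpy()
    pid_arr = patients["patient_id"].to_numpy()
    for g in ("W", "M"):  # fixed order keeps the stream deterministic
        sel = np.flatnonzero(gender_arr == g)
        if sel.size == 0:
            continue
        picks = weighted_distinct(rng_sets, weights_by_gender[g], n_distinct[sel])
        row_idx, col_idx = np.nonzero(picks >= 0)
        rows_pid.append(pid_arr[sel][row_idx])
        rows_drug.append(picks[row_idx, col_idx])
    if rows_pid:
        pid = np.concatenate(rows_pid)
        drug_idx = np.concatenate(rows_drug)
    else:
        pid = np.array([], dtype=object)
        drug_idx = np.array([], dtype=np.int64)
    ids = np.array(drug_ids(config.n_drugs))
    base = pd.DataFrame({"patient_id": pid, "drug_id": ids[drug_idx]})
    base = base.sort_values(["patient_id", "drug_id"], kind="stable")

    n_pd = len(base)
    if window.resolution == "daily":
        records = _daily_records(base, n_pd, window, config, rng_disp)
    else:
        records = _monthly_records(base, n_pd, window, config, rng_disp)

    for e_idx, effect in enumerate(config.planted_effects):
        records = _apply_planted_effect(records, patients, config, effect, e_idx)

    records = records.sort_values(["patient_id", "drug_id", "start"],
                                  kind="stable").reset_index(drop=True)
    return records[dio.DISPENSATION_COLUMNS]


def _daily_records(base, n_pd, window, config, rng) -> pd.DataFrame:
    p_dur = min(1.0, 1.0 / config.mean_duration_days)
    start_off = rng.integers(0, window.n_days, size=n_pd)
    duration = rng.geometric(p_dur, size=n_pd)
    refill = rng.random(n_pd) < config.refill_prob
    start2 = rng.integers(0, window.n_days, size=n_pd)
    dur2 = rng.geometric(p_dur, size=n_pd)
    first = pd.DataFrame({
        "patient_id": base["patient_id"].to_numpy(),
        "drug_id": base["drug_id"].to_numpy(),
        "start": window.start_ts + pd.to_timedelta(start_off, unit="D"),
        "duration": duration.astype(np.int64),
    })
    second = pd.DataFrame({
        "patient_id": base["patient_id"].to_numpy()[refill],
        "drug_id": base["drug_id"].to_numpy()[refill],
        "start": window.start_ts + pd.to_timedelta(start2[refill], unit="D"),
        "duration": dur2[refill].astype(np.int64),
    })
    records = pd.concat([first, second], ignore_index=True)
    return dio.clip_to_window(records, window)


def _monthly_records(base, n_pd, window, config, rng) -> pd.DataFrame:
    months = window.month_starts()
    n_months = len(months)
    mean_months = max(1.0, config.mean_duration_days / 30.0)
    start_idx = rng.integers(0, n_months, size=n_pd)
    length = rng.geometric(min(1.0, 1.0 / mean_months), size=n_pd)
    length = np.minimum(length, n_months - start_idx)
    rep = np.repeat(np.arange(n_pd), length)
    offsets = np.concatenate([np.arange(k) for k in length]) if n_pd else \
        np.array([], dtype=np.int64)
    month_idx = start_idx[rep] + offsets
    records = pd.DataFrame({
        "patient_id": base["patient_id"].to_numpy()[rep],
        "drug_id": base["drug_id"].to_numpy()[rep],
        "start": months.to_numpy()[month_idx],
        "duration": np.int64(1),
    })
    return records.drop_duplicates(subset=["patient_id", "drug_id", "start"])


# ---------------------------------------------------------------------------
# planted effects


def _add_years(dates: pd.DatetimeIndex, years: int) -> pd.DatetimeIndex:
    """Shift dates by whole calendar years (Feb 29 clamped to Feb 28)."""
    day = np.where((dates.month == 2) & (dates.day == 29), 28, dates.day)
    return pd.to_datetime({
        "year": dates.year + years, "month": dates.month, "day": day,
    })


def _eligible_date_range(birth: pd.DatetimeIndex, effect: PlantedEffect,
                         window: StudyWindow):
    """Per-patient [lo, hi) date range where completed age is in the target
    bins, intersected with the window."""
    bin_lo, bin_hi = effect.age_bin_range
    lo = pd.DatetimeIndex(_add_years(birth, 5 * bin_lo))
    if bin_hi >= N_AGE_BINS - 1:  # open-ended 90+ bin
        hi = pd.DatetimeIndex([window.end_ts] * len(birth))
    else:
        hi = pd.DatetimeIndex(_add_years(birth, 5 * bin_hi + 5))
    lo = pd.DatetimeIndex(np.maximum(lo.to_numpy(),
                                     window.start_ts.to_numpy()))
    hi = pd.DatetimeIndex(np.minimum(hi.to_numpy(), window.end_ts.to_numpy()))
    return lo, hi


def _apply_planted_effect(records, patients, config, effect, e_idx):
    from .coadmin import pair_intervals  # local import avoids cycles

    window = config.window
    m = effect.risk_multiplier
    drug_a, drug_b = sorted((effect.drug_a, effect.drug_b))
    rng = _rng(config.seed, "planted", e_idx)
    # Per-patient coupled uniforms: drawn for everyone, independent of m, so
    # the co-dispensation indicator is pathwise monotone in the multiplier.
    u_keep = rng.random(len(patients))
    u_start = rng.random(len(patients))

    gender_ok = np.ones(len(patients), dtype=bool) if effect.gender == "both" \
        else (patients["gender"].to_numpy() == effect.gender)
    birth = pd.DatetimeIndex(patients["birth_date"])
    lo, hi = _eligible_date_range(birth, effect, window)
    eligible = gender_ok & (lo.to_numpy() < hi.to_numpy())
    elig_idx = np.flatnonzero(eligible)
    if elig_idx.size == 0:
        return records

    elig_ids = patients["patient_id"].to_numpy()[elig_idx]
    pair_recs = records[
        records["drug_id"].isin([drug_a, drug_b])
        & records["patient_id"].isin(elig_ids)
    ]
    overlaps = pair_intervals(pair_recs, window)
    if len(overlaps):
        # qualifying overlap: co-administration episode starting at an
        # age inside the targeted bins
        lo_by_pid = pd.Series(lo.to_numpy(), index=patients["patient_id"])
        hi_by_pid = pd.Series(hi.to_numpy(), index=patients["patient_id"])
        o_lo = lo_by_pid.loc[overlaps["patient_id"]].to_numpy()
        o_hi = hi_by_pid.loc[overlaps["patient_id"]].to_numpy()
        s = overlaps["start"].to_numpy()
        qualifying = overlaps[(s >= o_lo) & (s < o_hi)]
    else:
        qualifying = overlaps
    has_overlap_ids = set(qualifying["patient_id"]) if len(qualifying) else set()
    has = np.isin(elig_ids, list(has_overlap_ids))
    q = has.mean()

    if m < 1.0 and has.any():
        # remove qualifying overlaps with probability 1 - m
        drop_pids = elig_ids[has & (u_keep[elig_idx] >= m)]
        if drop_pids.size:
            records = _remove_pair_overlaps(records, drop_pids, drug_a, drug_b,
                                            qualifying)
    elif m > 1.0 and 0.0 < q < 1.0:
        p_inj = min(1.0, q * (m - 1.0) / (1.0 - q))
        inject_mask = (~has) & (u_keep[elig_idx] < p_inj)
        inj_idx = elig_idx[inject_mask]
        if inj_idx.size:
            records = _inject_overlaps(records, patients, config, inj_idx,
                                       drug_a, drug_b, lo, hi, u_start)
    return records


def _remove_pair_overlaps(records, drop_pids, drug_a, drug_b, qualifying):
    """Drop drug_b records that overlap a qualifying co-administration
    episode for the given patients."""
    qual = qualifying[qualifying["patient_id"].isin(drop_pids)]
    b_rows = records[(records["drug_id"] == drug_b)
                     & records["patient_id"].isin(drop_pids)]
    if b_rows.empty or qual.empty:
        return records
    j = b_rows.reset_index().merge(qual[["patient_id", "start", "length"]],
                                   on="patient_id", suffixes=("", "_q"))
    b_end = j["start"] + pd.to_timedelta(j["duration"], unit="D")
    q_end = j["start_q"] + pd.to_timedelta(j["length"], unit="D")
    hit = (j["start"] < q_end) & (j["start_q"] < b_end)
    drop_index = j.loc[hit, "index"].unique()
    return records.drop(index=drop_index)


def _inject_overlaps(records, patients, config, inj_idx, drug_a, drug_b,
                     lo, hi, u_start):
    window = config.window
    pid = patients["patient_id"].to_numpy()[inj_idx]
    span_days = ((hi.to_numpy() - lo.to_numpy())[inj_idx]
                 / np.timedelta64(1, "D")).astype(np.int64)
    off = np.floor(u_start[inj_idx] * np.maximum(span_days, 1)).astype(np.int64)
    start = pd.DatetimeIndex(lo.to_numpy()[inj_idx]) + pd.to_timedelta(off, unit="D")
    if window.resolution == "monthly":
        start = start.to_period("M").to_timestamp()
        dur = np.int64(1)
    else:
        dur = np.full(inj_idx.size,
                      max(1, int(round(config.mean_duration_days))),
                      dtype=np.int64)
    extra = pd.DataFrame({
        "patient_id": np.concatenate([pid, pid]),
        "drug_id": np.concatenate([np.full(inj_idx.size, drug_a, dtype=object),
                                   np.full(inj_idx.size, drug_b, dtype=object)]),
        "start": np.concatenate([start.to_numpy(), start.to_numpy()]),
        "duration": np.concatenate([np.broadcast_to(dur, (inj_idx.size,)),
                                    np.broadcast_to(dur, (inj_idx.size,))]),
    })
    if window.resolution == "daily":
        extra = dio.clip_to_window(extra, window)
    out = pd.concat([records, extra], ignore_index=True)
    if window.resolution == "monthly":
        out = out.drop_duplicates(subset=["patient_id", "drug_id", "start"])
    return out


# ---------------------------------------------------------------------------
# DDI reference and drug classes


def generate_ddi_reference(config: SyntheticConfig) -> pd.DataFrame:
    """Mark a fraction of unordered drug pairs as interacting, with
    severities drawn from ``severity_probs``."""
    config.validate()
    if config.n_drugs < 2:
        raise ValueError("generate_ddi_reference: n_drugs must be >= 2")
    n = config.n_drugs
    n_pairs = n * (n - 1) // 2
    k = int(round(config.ddi_fraction * n_pairs))
    ids = np.array(drug_ids(n))
    if k == 0:
        return pd.DataFrame({c: pd.Series(dtype=str) for c in dio.DDI_COLUMNS})
    rng = _rng(config.seed, "ddi")
    chosen = np.sort(rng.choice(n_pairs, size=k, replace=False))
    ia, ib = np.triu_indices(n, k=1)
    severity = rng.choice(list(SEVERITIES), size=k, p=list(config.severity_probs))
    df = pd.DataFrame({
        "drug_a": ids[ia[chosen]],
        "drug_b": ids[ib[chosen]],
        "severity": severity,
    })
    return dio.canonicalize_ddi(df, source="synthetic")


def generate_drug_classes(config: SyntheticConfig,
                          ddi: pd.DataFrame) -> pd.DataFrame:
    """Emit one interchangeable class: a hub drug (most interaction partners)
    plus alternatives with strictly fewer known interactions."""
    config.validate()
    if config.n_drugs < 2:
        raise ValueError("generate_drug_classes: n_drugs must be >= 2")
    if config.n_class_alternatives < 1:
        raise ValueError(
            "generate_drug_classes: a class needs at least one alternative "
            "(n_class_alternatives >= 1)"
        )
    counts = interaction_counts(ddi, drug_ids(config.n_drugs))
    hub = min(counts.index[counts == counts.max()])
    hub_count = counts[hub]
    # fewest interactions first, ties broken lexicographically by drug id
    cands = counts[counts < hub_count].loc[
        lambda s: sorted(s.index)
    ].sort_values(kind="stable")
    if cands.empty:
        raise DataError(
            "generate_drug_classes: no drug has strictly fewer interactions "
            "than the hub"
        )
    alts = list(cands.index[: config.n_class_alternatives])
    members = [hub] + alts
    return pd.DataFrame({"class_id": "C01", "drug_id": members})


def interaction_counts(ddi: pd.DataFrame, all_drugs) -> pd.Series:
    """Known-interaction partner count per drug (0 for absent drugs)."""
    counts = pd.Series(0, index=pd.Index(all_drugs, name="drug_id"), dtype=int)
    if len(ddi):
        stacked = pd.concat([ddi["drug_a"], ddi["drug_b"]])
        vc = stacked.value_counts()
        counts = counts.add(vc.reindex(counts.index, fill_value=0), fill_value=0)
    return counts.astype(int)


# ---------------------------------------------------------------------------
# resolution conversion


def daily_to_monthly(records: pd.DataFrame, window: StudyWindow) -> pd.DataFrame:
    """Map each administration day range to its covered calendar months."""
    if records.empty:
        return records.copy()
    start = pd.DatetimeIndex(records["start"])
    end = start + pd.to_timedelta(records["duration"].to_numpy() - 1, unit="D")
    m0 = start.to_period("M")
    m1 = end.to_period("M")
    n_m = (m1.year - m0.year) * 12 + (m1.month - m0.month) + 1
    rep = np.repeat(np.arange(len(records)), n_m)
    offsets = np.concatenate([np.arange(k) for k in n_m])
    month = (m0[rep] + offsets).to_timestamp()
    out = pd.DataFrame({
        "patient_id": records["patient_id"].to_numpy()[rep],
        "drug_id": records["drug_id"].to_numpy()[rep],
        "start": month,
        "duration": np.int64(1),
    })
    mwin = StudyWindow(window.start, window.end, "monthly")
    lo = mwin.start_ts.to_period("M").to_timestamp()
    hi = pd.Timestamp(mwin.end).to_period("M").to_timestamp()
    out = out[(out["start"] >= lo) & (out["start"] <= hi)]
    out = out.drop_duplicates(subset=["patient_id", "drug_id", "start"])
    return out.sort_values(["patient_id", "drug_id", "start"],
                           kind="stable").reset_index(drop=True)
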