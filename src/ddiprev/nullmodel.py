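"""Age-matched random-dispensation null model for the expected DDI prevalence.

The null asks: if patients kept their observed polypharmacy (number of
distinct drugs and number of co-administered pairs) but drew their drugs at
random from the drugs observed in their own age bin, what fraction would be
exposed to a known interaction? Per replicate and patient:

1. draw |D^u| distinct drugs from the bin's pool — weighted by each drug's
   observed patient count in the bin (``frequency_weighted``, approximating
   a label shuffle) or uniformly (``uniform_distinct``);
2. draw the patient's observed number of distinct co-administered pairs
   (capped at C(|D^u|, 2)) without replacement from the pairs of the
   randomized set;
3. the patient counts as interacting if any drawn pair is in the reference.

Expected prevalence per bin is averaged over replicates; the observed
counts are compared against the pooled null counts with an odds ratio and
Fisher's exact test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._sampling import (
    codes_in_sorted,
    distinct_subsets,
    pair_code,
    weighted_distinct,
)
from .coadmin import annotate_ddi
from .prevalence import assign_age_bins
from .types import NullModelConfig, StudyWindow

logger = logging.getLogger(__name__)

_DRUG_STREAM = 11
_PAIR_STREAM = 12


def build_profiles(intervals: pd.DataFrame, records: pd.DataFrame,
                   patients: pd.DataFrame, ddi: pd.DataFrame) -> dict:
    """Observed per-(age bin, patient) polypharmacy profiles and bin pools.

    Returns a dict with the drug vocabulary, the distinct
    (bin, patient, drug) usage table, per-(bin, patient) counts
    (n_drugs, n_pairs, interacting), and the interaction reference encoded
    over the vocabulary.
    """
    vocab = np.array(sorted(records["drug_id"].unique()))
    code_of = pd.Series(np.arange(len(vocab)), index=vocab)

    recs = assign_age_bins(records, patients)
    usage = recs[["age_bin", "patient_id", "drug_id"]].drop_duplicates()
    usage = usage.assign(drug_code=code_of.reindex(usage["drug_id"]).to_numpy())

    per_bp = usage.groupby(["age_bin", "patient_id"], sort=True)["drug_code"] \
        .size().rename("n_drugs").reset_index()

    if len(intervals):
        ints = annotate_ddi(assign_age_bins(intervals, patients), ddi)
        pairs = ints[["age_bin", "patient_id", "drug_i", "drug_j", "is_ddi"]] \
            .drop_duplicates(subset=["age_bin", "patient_id",
                                     "drug_i", "drug_j"])
        pg = pairs.groupby(["age_bin", "patient_id"], sort=True).agg(
            n_pairs=("is_ddi", "size"), interacting=("is_ddi", "any"),
        ).reset_index()
    else:
        pg = pd.DataFrame(columns=["age_bin", "patient_id", "n_pairs",
                                   "interacting"])
    per_bp = per_bp.merge(pg, on=["age_bin", "patient_id"], how="left")
    per_bp["n_pairs"] = per_bp["n_pairs"].fillna(0).astype(np.int64)
    per_bp["interacting"] = per_bp["interacting"].notna() \
        & per_bp["interacting"].astype(object).eq(True)
    cap = per_bp["n_drugs"] * (per_bp["n_drugs"] - 1) // 2
    over = per_bp["n_pairs"] > cap
    if over.any():
        logger.info("build_profiles: capped the pair count of %d "
                    "(bin, patient) rows at C(n_drugs, 2)", int(over.sum()))
    per_bp["n_pairs"] = np.minimum(per_bp["n_pairs"], cap)

    if ddi is not None and len(ddi):
        a = code_of.reindex(ddi["drug_a"]).to_numpy()
        b = code_of.reindex(ddi["drug_b"]).to_numpy()
        ok = ~(np.isnan(a) | np.isnan(b))
        ddi_codes = np.sort(pair_code(a[ok].astype(np.int64),
                                      b[ok].astype(np.int64), len(vocab)))
    else:
        ddi_codes = np.array([], dtype=np.int64)
    return {"vocab": vocab, "usage": usage, "per_bp": per_bp,
            "ddi_codes": ddi_codes}


def _bin_pools(profiles: dict, sampling: str) -> dict:
    pools = {}
    counts = profiles["usage"].groupby(["age_bin", "drug_code"], sort=True) \
        .size().rename("n").reset_index()
    for age_bin, sub in counts.groupby("age_bin", sort=True):
        drugs = sub["drug_code"].to_numpy()
        w = sub["n"].to_numpy(dtype=float) if sampling == "frequency_weighted" \
            else np.ones(len(sub))
        pools[age_bin] = (drugs, w)
    return pools


def randomize_patient_drugs(profiles: dict, config: NullModelConfig,
                            rep: int = 0) -> pd.DataFrame:
    """One replicate of the randomized drug assignment.

    Deterministic given (config.seed, rep): each patient in each bin
    receives exactly their observed number of distinct drugs, drawn from
    the bin's pool. If a patient's count exceeds the pool size, the full
    pool is assigned and the shortfall is logged.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _DRUG_STREAM, int(rep)]))
    pools = _bin_pools(profiles, config.sampling)
    per_bp = profiles["per_bp"]
    out = []
    for age_bin, sub in per_bp.groupby("age_bin", sort=True):
        drugs, w = pools[age_bin]
        sizes = sub["n_drugs"].to_numpy()
        if (sizes > len(drugs)).any():
            logger.info("randomize_patient_drugs: bin %s pool smaller than "
                        "%d patient drug count(s); assigning the full pool",
                        age_bin, int((sizes > len(drugs)).sum()))
        picks = weighted_distinct(rng, w, sizes)
        row, col = np.nonzero(picks >= 0)
        out.append(pd.DataFrame({
            "age_bin": age_bin,
            "patient_id": sub["patient_id"].to_numpy()[row],
            "drug_code": drugs[picks[row, col]],
        }))
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["age_bin", "patient_id", "drug_code"])


def _decode_pair_index(t: np.ndarray, d: np.ndarray):
    """Invert the lexicographic index of combination (a, b), a < b < d."""
    t = t.astype(np.float64)
    df = d.astype(np.float64)
    disc = np.maximum((2 * df - 1) ** 2 - 8 * t, 0.0)
    a = np.floor(((2 * df - 1) - np.sqrt(disc)) / 2).astype(np.int64)
    a = np.clip(a, 0, np.maximum(d - 2, 0))
    t_int = t.astype(np.int64)

    def s_of(a_):
        return a_ * (2 * d - a_ - 1) // 2

    for _ in range(4):  # float rounding can be off by one either way
        too_high = s_of(a) > t_int
        a = np.where(too_high, a - 1, a)
        too_low = (a + 1 <= d - 2) & (s_of(a + 1) <= t_int)
        a = np.where(too_low, a + 1, a)
        if not (too_high.any() or too_low.any()):
            break
    b = t_int - s_of(a) + a + 1
    return a, b


def _sampling_plan(profiles: dict, pools: dict) -> list[dict]:
    """Per-bin precomputation for the replicate loop.

    Only (bin, patient) rows with at least one observed co-administered
    pair are sampled: a patient with zero pairs can never draw an
    interacting pair, so their null outcome is False by construction.
    """
    per_bp = profiles["per_bp"]
    plan = []
    offset = 0
    for age_bin, sub in per_bp.groupby("age_bin", sort=True):
        drugs, w = pools[age_bin]
        sizes_all = np.minimum(sub["n_drugs"].to_numpy(), len(drugs))
        k_all = np.minimum(sub["n_pairs"].to_numpy(),
                           sizes_all * (sizes_all - 1) // 2)
        active = np.flatnonzero(k_all > 0)
        if active.size:
            plan.append({
                "drugs": drugs, "w": w,
                "sizes": sizes_all[active], "k": k_all[active],
                "rows": offset + active,
            })
        offset += len(sub)
    return plan


def _rep_outcomes(plan: list[dict], n_rows: int, n_vocab: int,
                  ddi_codes: np.ndarray, config: NullModelConfig,
                  rep: int) -> np.ndarray:
    """Interacting indicator per (bin, patient) row for one replicate."""
    rng_drugs = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _DRUG_STREAM, int(rep)]))
    rng_pairs = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _PAIR_STREAM, int(rep)]))
    outcome = np.zeros(n_rows, dtype=bool)
    for bin_plan in plan:
        drugs, w = bin_plan["drugs"], bin_plan["w"]
        sizes, k = bin_plan["sizes"], bin_plan["k"]
        n = sizes.shape[0]
        picks = weighted_distinct(rng_drugs, w, sizes)  # (n, d_max) pool idx
        n_opts = sizes * (sizes - 1) // 2
        t = distinct_subsets(rng_pairs, n_opts, k)  # (n, k_max)
        valid = t >= 0
        tv = np.where(valid, t, 0)
        d_bcast = np.broadcast_to(sizes[:, None], tv.shape)
        a, b = _decode_pair_index(tv, d_bcast)
        row = np.broadcast_to(np.arange(n)[:, None], tv.shape)
        drug_a = drugs[picks[row, a]]
        drug_b = drugs[picks[row, b]]
        codes = pair_code(drug_a, drug_b, n_vocab)
        hit = codes_in_sorted(codes, ddi_codes) & valid
        outcome[bin_plan["rows"]] = hit.any(axis=1)
    return outcome


def run_null_model(intervals: pd.DataFrame, records: pd.DataFrame,
                   patients: pd.DataFrame, ddi: pd.DataFrame,
                   config: NullModelConfig,
                   window: StudyWindow) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed vs expected DDI prevalence per age bin.

    Returns (summary, per_rep): ``summary`` has one row per age bin plus an
    all-ages row with observed_pi, expected_pi_mean, the pooled
    observed-vs-null odds ratio and its Fisher exact p-value; ``per_rep``
    is the long table of expected PI per (age_bin, rep).
    """
    profiles = build_profiles(intervals, records, patients, ddi)
    pools = _bin_pools(profiles, config.sampling)
    per_bp = profiles["per_bp"]
    n_rows = len(per_bp)
    plan = _sampling_plan(profiles, pools)
    n_vocab = len(profiles["vocab"])
    outcomes = np.zeros((n_rows, config.n_reps), dtype=bool)
    for rep in range(config.n_reps):
        outcomes[:, rep] = _rep_outcomes(plan, n_rows, n_vocab,
                                         profiles["ddi_codes"], config, rep)

    bin_of_row = per_bp["age_bin"].to_numpy()
    obs = per_bp["interacting"].to_numpy()
    pid_codes, pid_index = pd.factorize(per_bp["patient_id"])
    n_patients = len(pid_index)

    # patient-level 'any bin' aggregation for the all-ages row
    obs_patient = np.zeros(n_patients, dtype=bool)
    np.logical_or.at(obs_patient, pid_codes, obs)
    null_patient = np.zeros((n_patients, config.n_reps), dtype=bool)
    for rep in range(config.n_reps):
        np.logical_or.at(null_patient[:, rep], pid_codes, outcomes[:, rep])

    summary_rows, rep_rows = [], []

    def _summarize(age_bin, obs_vec, null_mat):
        n = obs_vec.shape[0]
        obs_int = int(obs_vec.sum())
        null_int = null_mat.sum(axis=0)
        exp_pi = null_int / n
        a, b = obs_int, n - obs_int
        c, d = int(null_int.sum()), n * null_mat.shape[1] - int(null_int.sum())
        if b > 0 and c > 0:
            or_ = (a * d) / (b * c)
        else:
            or_ = np.inf if a > 0 and d > 0 else np.nan
        _, p = stats.fisher_exact([[a, b], [c, d]])
        summary_rows.append({
            "age_bin": age_bin, "n_patients": n, "observed_pi": obs_int / n,
            "expected_pi_mean": float(exp_pi.mean()),
            "expected_pi_sd": float(exp_pi.std(ddof=1)) if len(exp_pi) > 1
            else 0.0,
            "odds_ratio": or_, "p_value": float(p),
            "n_reps": null_mat.shape[1],
        })
        for rep, v in enumerate(exp_pi):
            rep_rows.append({"age_bin": age_bin, "rep": rep,
                             "expected_pi": float(v)})

    for age_bin in pd.unique(bin_of_row):
        sel = bin_of_row == age_bin
        _summarize(age_bin, obs[sel], outcomes[sel])
    _summarize("all", obs_patient, null_patient)

    return pd.DataFrame(summary_rows), pd.DataFrame(rep_rows)
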