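"""Counterfactual substitution of a target drug by same-class alternatives.

Emulates replacing an interaction-prone drug (e.g. omeprazole) with an
interchangeable alternative from its therapeutic class (e.g. another proton
pump inhibitor) wherever the alternative avoids all known interactions with
the drugs the patient is concurrently administered, then re-computing the
prevalence measures. Substitution is evaluated per administration episode,
so one patient may keep the target in one episode and replace it in
another.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as dio
from .coadmin import pair_intervals
from .prevalence import compute_prevalence
from .synthetic import interaction_counts
from .types import DataError, SEVERITIES, StudyWindow

PLAN_COLUMNS = ["patient_id", "start", "duration", "action", "alternative",
                "blocked_by"]


def _merged_view(records: pd.DataFrame, window: StudyWindow) -> pd.DataFrame:
    if window.resolution == "daily":
        return dio.merge_same_drug_intervals(records)
    return records.drop_duplicates(subset=["patient_id", "drug_id", "start"])


def _partner_map(ddi: pd.DataFrame) -> dict[str, set[str]]:
    partners: dict[str, set[str]] = {}
    for row in ddi.itertuples(index=False):
        partners.setdefault(row.drug_a, set()).add(row.drug_b)
        partners.setdefault(row.drug_b, set()).add(row.drug_a)
    return partners


def ordered_alternatives(target: str, classes: pd.DataFrame,
                         ddi: pd.DataFrame) -> list[str]:
    """Same-class alternatives, safest first: ascending count of known
    interactions, ties broken lexicographically by drug id."""
    target_classes = classes.loc[classes["drug_id"] == target, "class_id"]
    if len(target_classes) == 0:
        raise ValueError(f"target drug {target!r} is not in the class table")
    if target_classes.nunique() > 1:
        raise ValueError(f"target drug {target!r} belongs to multiple classes")
    cls = target_classes.iloc[0]
    members = classes.loc[(classes["class_id"] == cls)
                          & (classes["drug_id"] != target), "drug_id"]
    alts = sorted(set(members))
    if not alts:
        raise ValueError(f"class {cls!r} has no alternative to {target!r}")
    counts = interaction_counts(ddi, alts)
    return sorted(alts, key=lambda d: (counts[d], d))


def plan_substitutions(records: pd.DataFrame, target: str,
                       classes: pd.DataFrame, ddi: pd.DataFrame,
                       window: StudyWindow,
                       scope: str = "ddi") -> pd.DataFrame:
    """Decide, per target administration episode, whether a same-class
    alternative can replace the target without any known interaction with
    concurrently administered drugs.

    ``scope='ddi'`` (default) only considers episodes where the target
    currently participates in a known interaction; ``scope='all'`` attempts
    replacement of every target episode.
    """
    if scope not in ("ddi", "all"):
        raise ValueError("scope must be 'ddi' or 'all'")
    alts = ordered_alternatives(target, classes, ddi)
    partners = _partner_map(ddi)
    target_partners = partners.get(target, set())

    merged = _merged_view(records, window)
    t_iv = merged[merged["drug_id"] == target].reset_index(drop=True)
    if t_iv.empty:
        return pd.DataFrame(columns=PLAN_COLUMNS)
    t_iv = t_iv.assign(ep_id=np.arange(len(t_iv)))
    others = merged[merged["drug_id"] != target]
    j = t_iv.merge(others, on="patient_id", suffixes=("", "_o"))
    if window.resolution == "daily":
        end = j["start"] + pd.to_timedelta(j["duration"], unit="D")
        end_o = j["start_o"] + pd.to_timedelta(j["duration_o"], unit="D")
        ov = (np.maximum(j["start"], j["start_o"])
              < np.minimum(end, end_o))
    else:
        ov = j["start"] == j["start_o"]
    conc = j.loc[ov].groupby("ep_id")["drug_id_o"].agg(set)

    rows = []
    for ep in t_iv.itertuples(index=False):
        concurrent: set = conc.get(ep.ep_id, set())
        has_ddi = bool(concurrent & target_partners)
        if scope == "ddi" and not has_ddi:
            continue
        chosen = None
        blocking: set = set()
        for alt in alts:
            clash = partners.get(alt, set()) & concurrent
            if not clash:
                chosen = alt
                break
            blocking |= clash
        rows.append({
            "patient_id": ep.patient_id, "start": ep.start,
            "duration": ep.duration,
            "action": "replaced" if chosen else "kept",
            "alternative": chosen or "",
            "blocked_by": "" if chosen else ";".join(sorted(blocking)),
        })
    plan = pd.DataFrame(rows, columns=PLAN_COLUMNS)
    plan.attrs["target"] = target
    plan.attrs["scope"] = scope
    return plan


def apply_substitutions(records: pd.DataFrame, plan: pd.DataFrame,
                        target: str, window: StudyWindow) -> pd.DataFrame:
    """Rewrite the dispensation table according to the plan: target records
    inside a replaced episode get the chosen alternative's id, with dates
    and durations unchanged."""
    replaced = plan[plan["action"] == "replaced"]
    if replaced.empty:
        return records.copy()
    t_recs = records[records["drug_id"] == target].reset_index()
    rest = records[records["drug_id"] != target]
    j = t_recs.merge(
        replaced[["patient_id", "start", "duration", "alternative"]],
        on="patient_id", suffixes=("", "_ep"),
    )
    if window.resolution == "daily":
        rec_end = j["start"] + pd.to_timedelta(j["duration"], unit="D")
        ep_end = j["start_ep"] + pd.to_timedelta(j["duration_ep"], unit="D")
        inside = (j["start"] >= j["start_ep"]) & (rec_end <= ep_end)
    else:
        inside = j["start"] == j["start_ep"]
    j = j[inside]
    new_drug = j.set_index("index")["alternative"]
    out = records.copy()
    out.loc[new_drug.index, "drug_id"] = new_drug
    return out.sort_values(["patient_id", "drug_id", "start"],
                           kind="stable").reset_index(drop=True)


def apply_and_recompute(records: pd.DataFrame, patients: pd.DataFrame,
                        ddi: pd.DataFrame, plan: pd.DataFrame, target: str,
                        window: StudyWindow
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the plan and report PI before vs after per (gender, severity).

    Returns (report, rewritten records). Report columns: pi_before,
    pi_after, relative_reduction = (PI_b − PI_a)/PI_b (0 where PI_b = 0),
    and n_freed — patients with ≥ 1 interaction before and none after in
    the stratum.
    """
    new_records = apply_substitutions(records, plan, target, window)

    def _patient_flags(recs):
        ints = pair_intervals(recs, window)
        prev = compute_prevalence(ints, recs, patients, ddi)
        from .coadmin import annotate_ddi
        tagged = annotate_ddi(ints, ddi)
        ddi_pairs = tagged[tagged["is_ddi"]]
        flags = {}
        flags["any"] = set(ddi_pairs["patient_id"])
        for sev in SEVERITIES:
            flags[sev] = set(ddi_pairs.loc[ddi_pairs["severity"] == sev,
                                           "patient_id"])
        return prev, flags

    prev_b, flags_b = _patient_flags(records)
    prev_a, flags_a = _patient_flags(new_records)

    gender_of = patients.set_index("patient_id")["gender"]
    rows = []
    for gsel in ("W", "M", "all"):
        for sev in ("any",) + SEVERITIES:
            def _cell(prev):
                r = prev[(prev["gender"] == gsel)
                         & (prev["age_bin"] == "all")
                         & (prev["severity"] == sev)]
                return (float(r["pi"].iloc[0]), int(r["n_patients"].iloc[0])) \
                    if len(r) else (np.nan, 0)
            pi_b, n_b = _cell(prev_b)
            pi_a, _ = _cell(prev_a)
            freed = flags_b[sev] - flags_a[sev]
            if gsel != "all":
                freed = {p for p in freed if gender_of.get(p) == gsel}
            rel = (pi_b - pi_a) / pi_b if pi_b and pi_b > 0 else 0.0
            rows.append({
                "gender": gsel, "severity": sev, "n_patients": n_b,
                "pi_before": pi_b, "pi_after": pi_a,
                "relative_reduction": rel, "n_freed": len(freed),
            })
    report = pd.DataFrame(rows)
    return report, new_records
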