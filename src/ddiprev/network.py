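"""Significance-filtered network of co-administered interacting drug pairs.

Each observed interacting pair is tested for co-usage enrichment: a
hypergeometric (one-sided Fisher) test of the 2×2 of (takes drug i) ×
(takes drug j), with the joint cell the number of patients who
co-administered the pair concomitantly. Pairs at FDR ≤ 0.05 (Benjamini–
Hochberg across all observed interacting pairs) form the network's edges.
Node weight is the probability that a patient taking the drug is exposed to
a significant interaction involving it; edge weight is the pair's mean
strength of co-administration, and edge color in the published rendering is
the pair's gender relative risk.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DataError


def pair_significance(pair_stats: pd.DataFrame, n_patients: int,
                      ) -> pd.DataFrame:
    """One-sided enrichment p, Bonferroni-adjusted p and BH q per
    observed interacting pair."""
    ddi_pairs = pair_stats[pair_stats["is_ddi"]].copy()
    if ddi_pairs.empty:
        for col in ("p_value", "p_bonferroni", "fdr_q"):
            ddi_pairs[col] = pd.Series(dtype=float)
        return ddi_pairs
    k = ddi_pairs["n_coadmin_users"].to_numpy()
    ki = ddi_pairs["n_users_i"].to_numpy()
    kj = ddi_pairs["n_users_j"].to_numpy()
    if (k > np.minimum(ki, kj)).any():
        raise DataError("pair_significance: co-users exceed a drug's user count")
    if (ki > n_patients).any() or (kj > n_patients).any():
        raise DataError("pair_significance: drug user count exceeds population")
    # P(X >= k) for X ~ Hypergeom(N = patients, K = users of i, n = users of j)
    p = stats.hypergeom.sf(k - 1, n_patients, ki, kj)
    p = np.clip(p, 0.0, 1.0)
    ddi_pairs["p_value"] = p
    _, p_bonf, _, _ = multipletests(p, method="bonferroni")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    ddi_pairs["p_bonferroni"] = p_bonf
    ddi_pairs["fdr_q"] = q
    return ddi_pairs


def pair_gender_rr(episodes: pd.DataFrame, records: pd.DataFrame,
                   patients: pd.DataFrame) -> pd.DataFrame:
    """Per-pair relative risk for women of co-administering the pair:
    (pair users W / patients W) / (pair users M / patients M)."""
    gender = patients.set_index("patient_id")["gender"]
    denom = records[["patient_id"]].drop_duplicates()
    denom = denom.assign(gender=gender.reindex(denom["patient_id"]).to_numpy())
    n_w = int((denom["gender"] == "W").sum())
    n_m = int((denom["gender"] == "M").sum())
    ep = episodes[["patient_id", "drug_i", "drug_j"]].drop_duplicates()
    ep = ep.assign(gender=gender.reindex(ep["patient_id"]).to_numpy())
    g = ep.groupby(["drug_i", "drug_j"])["gender"]
    counts = g.value_counts().unstack(fill_value=0)
    for col in ("W", "M"):
        if col not in counts:
            counts[col] = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        prev_w = counts["W"] / n_w if n_w else np.nan
        prev_m = counts["M"] / n_m if n_m else np.nan
        rr = np.where(prev_m > 0, prev_w / prev_m,
                      np.where(prev_w > 0, np.inf, np.nan))
    out = counts.reset_index()[["drug_i", "drug_j"]]
    out["rr_gender"] = rr
    return out


def build_network(sig_pairs: pd.DataFrame, episodes: pd.DataFrame,
                  records: pd.DataFrame, patients: pd.DataFrame,
                  fdr: float = 0.05,
                  classes: pd.DataFrame | None = None) -> nx.Graph:
    """Build the interaction network over pairs with BH q ≤ ``fdr``.

    Node attribute ``node_risk`` = |patients exposed to a significant DDI
    involving the drug| / |patients taking the drug|; edge attributes carry
    tau_mean, the gender RR (unclipped, plus a display copy clipped to
    [1, 5]), severity, co-user count, p-value and q-value.
    """
    edges = sig_pairs[sig_pairs["fdr_q"] <= fdr].copy()
    G = nx.Graph()
    G.graph["fdr_threshold"] = fdr
    if edges.empty:
        return G

    rr = pair_gender_rr(episodes, records, patients)
    edges = edges.merge(rr, on=["drug_i", "drug_j"], how="left")

    users = records.groupby("drug_id")["patient_id"].nunique()
    ep = episodes.merge(edges[["drug_i", "drug_j"]], on=["drug_i", "drug_j"])
    exposed = pd.concat([
        ep[["patient_id", "drug_i"]].rename(columns={"drug_i": "drug_id"}),
        ep[["patient_id", "drug_j"]].rename(columns={"drug_j": "drug_id"}),
    ]).drop_duplicates()
    n_exposed = exposed.groupby("drug_id")["patient_id"].nunique()

    class_of = {}
    if classes is not None and len(classes):
        class_of = classes.set_index("drug_id")["class_id"].to_dict()

    for drug in sorted(set(edges["drug_i"]) | set(edges["drug_j"])):
        risk = float(n_exposed.get(drug, 0)) / float(users[drug])
        G.add_node(drug, node_risk=risk,
                   drug_class=str(class_of.get(drug, "")))
    for row in edges.itertuples(index=False):
        rr_val = float(row.rr_gender) if np.isfinite(row.rr_gender) else np.nan
        G.add_edge(row.drug_i, row.drug_j,
                   tau_mean=float(row.tau_mean),
                   rr_gender=rr_val,
                   rr_gender_display=float(np.clip(rr_val, 1.0, 5.0))
                   if np.isfinite(rr_val) else np.nan,
                   severity=str(row.severity),
                   n_coadmin_users=int(row.n_coadmin_users),
                   p_value=float(row.p_value),
                   fdr_q=float(row.fdr_q))
    return G


def export_network(G: nx.Graph, path, fmt: str = "graphml",
                   min_tau: float | None = None) -> None:
    """Write the network as GraphML or a flat delimited edge list.

    ``min_tau`` keeps only edges whose strength of co-administration is at
    least the threshold (the published rendering shows strengths above
    0.18)."""
    H = G
    if min_tau is not None:
        H = G.copy()
        drop = [(u, v) for u, v, d in H.edges(data=True)
                if d.get("tau_mean", 0.0) < min_tau]
        H.remove_edges_from(drop)
        H.remove_nodes_from([n for n in list(H) if H.degree(n) == 0])
    if fmt == "graphml":
        nx.write_graphml(H, path)
    elif fmt == "edgelist":
        rows = [{"drug_i": u, "drug_j": v, **d}
                for u, v, d in sorted(H.edges(data=True))]
        df = pd.DataFrame(rows) if rows else pd.DataFrame(
            columns=["drug_i", "drug_j", "tau_mean", "rr_gender",
                     "severity", "n_coadmin_users", "p_value", "fdr_q"])
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"export_network: unknown format {fmt!r}; "
                         "use 'graphml' or 'edgelist'")


def read_network(path) -> nx.Graph:
    return nx.read_graphml(path)
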