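import numpy as np
import pandas as pd
import pytest

from conftest import make_records
from ddiprev import coadmin as ca
from ddiprev import network as net
from ddiprev.types import DataError


def _pair_stats_row(**kw):
    base = dict(drug_i="A", drug_j="B", n_users_i=1, n_users_j=1,
                n_coadmin_users=1, gamma_ij=1.0, gamma_ji=1.0, tau_mean=0.5,
                is_ddi=True, severity="major")
    base.update(kw)
    return base


class TestPairSignificance:
    def test_single_couser_with_unit_margins(self):
        # N=4 patients, 1 user of each drug, 1 co-user:
        # P(X >= 1) for Hypergeom(N=4, K=1, n=1) = 1/4
        stats_ = pd.DataFrame([_pair_stats_row()])
        out = net.pair_significance(stats_, n_patients=4)
        assert out["p_value"].iloc[0] == pytest.approx(0.25)

    def test_degenerate_margins_p_one(self):
        # everyone takes both drugs: only one table possible
        stats_ = pd.DataFrame([_pair_stats_row(
            n_users_i=10, n_users_j=10, n_coadmin_users=10)])
        out = net.pair_significance(stats_, n_patients=10)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_non_ddi_pairs_not_tested(self):
        stats_ = pd.DataFrame([_pair_stats_row(is_ddi=False)])
        out = net.pair_significance(stats_, n_patients=10)
        assert out.empty

    def test_integrity_error_when_cousers_exceed_users(self):
        stats_ = pd.DataFrame([_pair_stats_row(n_coadmin_users=5)])
        with pytest.raises(DataError):
            net.pair_significance(stats_, n_patients=10)

    def test_matches_scipy_fisher_greater(self):
        from scipy.stats import fisher_exact
        stats_ = pd.DataFrame([_pair_stats_row(
            n_users_i=40, n_users_j=25, n_coadmin_users=15)])
        out = net.pair_significance(stats_, n_patients=200)
        table = [[15, 40 - 15], [25 - 15, 200 - 40 - 25 + 15]]
        _, p = fisher_exact(table, alternative="greater")
        assert out["p_value"].iloc[0] == pytest.approx(p, rel=1e-9)


def _cohort(daily_window):
    """30 patients; pair (A,B) strongly enriched and interacting."""
    rows = []
    for k in range(12):
        rows += [(f"u{k:02d}", "A", 0, 10), (f"u{k:02d}", "B", 0, 10)]
    for k in range(12, 21):
        rows.append((f"u{k:02d}", "C", 0, 10))
    for k in range(21, 30):
        rows.append((f"u{k:02d}", "D", 0, 10))
    recs = make_records(rows, daily_window)
    pats = pd.DataFrame({
        "patient_id": [f"u{k:02d}" for k in range(30)],
        "gender": ["W", "M"] * 15,
        "birth_date": pd.Timestamp("1960-01-01"),
    })
    ddi = pd.DataFrame({"drug_a": ["A", "C"], "drug_b": ["B", "D"],
                        "severity": ["major", "minor"]})
    return recs, pats, ddi


class TestBuildNetwork:
    def test_single_significant_pair(self, daily_window):
        recs, pats, ddi = _cohort(daily_window)
        eps = ca.detect_pair_episodes(recs, ddi, daily_window)
        stats_ = ca.pair_population_stats(eps, recs, daily_window)
        sig = net.pair_significance(stats_, recs["patient_id"].nunique())
        G = net.build_network(sig, eps, recs, pats)
        assert set(G.nodes) == {"A", "B"}
        assert G.number_of_edges() == 1
        # all A-takers are exposed to the significant DDI involving A
        assert G.nodes["A"]["node_risk"] == 1.0
        assert G.edges["A", "B"]["severity"] == "major"
        assert G.edges["A", "B"]["fdr_q"] <= 0.05

    def test_no_significant_pairs_empty_graph(self, daily_window):
        rows = [("u1", "A", 0, 10), ("u1", "B", 0, 10),
                ("u2", "A", 0, 10), ("u3", "B", 0, 10)]
        recs = make_records(rows, daily_window)
        pats = pd.DataFrame({"patient_id": ["u1", "u2", "u3"],
                             "gender": ["W", "M", "W"],
                             "birth_date": pd.Timestamp("1960-01-01")})
        ddi = pd.DataFrame({"drug_a": ["A"], "drug_b": ["B"],
                            "severity": ["minor"]})
        eps = ca.detect_pair_episodes(recs, ddi, daily_window)
        stats_ = ca.pair_population_stats(eps, recs, daily_window)
        sig = net.pair_significance(stats_, 3)
        G = net.build_network(sig, eps, recs, pats, fdr=0.001)
        assert G.number_of_nodes() == 0

    def test_node_risk_union_of_disjoint_patient_sets(self):
        # drug X in 3 significant pairs touching disjoint sets of 2, 3 and
        # 5 patients out of 20 X-takers -> node risk 10/20
        episodes = []
        pid = 0
        for other, n in (("P", 2), ("Q", 3), ("R", 5)):
            for _ in range(n):
                episodes.append({"patient_id": f"x{pid:02d}", "drug_i": "X",
                                 "drug_j": other})
                pid += 1
        eps = pd.DataFrame(episodes).assign(tau=0.5)
        recs_rows = [{"patient_id": f"x{k:02d}", "drug_id": "X"}
                     for k in range(20)]
        for e in episodes:
            recs_rows.append({"patient_id": e["patient_id"],
                              "drug_id": e["drug_j"]})
        recs = pd.DataFrame(recs_rows).assign(
            start=pd.Timestamp("2014-01-01"), duration=np.int64(10))
        pats = pd.DataFrame({
            "patient_id": [f"x{k:02d}" for k in range(20)],
            "gender": ["W", "M"] * 10,
            "birth_date": pd.Timestamp("1960-01-01"),
        })
        sig = pd.DataFrame([
            _pair_stats_row(drug_i="X", drug_j=o, tau_mean=0.4,
                            n_users_i=20, n_users_j=n, n_coadmin_users=n)
            for o, n in (("P", 2), ("Q", 3), ("R", 5))
        ]).assign(p_value=1e-6, p_bonferroni=3e-6, fdr_q=1e-6)
        G = net.build_network(sig, eps, recs, pats)
        assert G.nodes["X"]["node_risk"] == pytest.approx(0.5)

    def test_fdr_monotonicity(self, daily_window):
        recs, pats, ddi = _cohort(daily_window)
        eps = ca.detect_pair_episodes(recs, ddi, daily_window)
        stats_ = ca.pair_population_stats(eps, recs, daily_window)
        sig = net.pair_significance(stats_, recs["patient_id"].nunique())
        for lo, hi in ((0.001, 0.01), (0.01, 0.05), (0.05, 0.2)):
            g_lo = net.build_network(sig, eps, recs, pats, fdr=lo)
            g_hi = net.build_network(sig, eps, recs, pats, fdr=hi)
            assert set(g_lo.edges) <= set(g_hi.edges)

    def test_edges_subset_of_reference(self, small_synth_daily):
        cfg, patients, records, ddi = small_synth_daily
        eps = ca.detect_pair_episodes(records, ddi, cfg.window)
        stats_ = ca.pair_population_stats(eps, records, cfg.window)
        sig = net.pair_significance(stats_, records["patient_id"].nunique())
        G = net.build_network(sig, eps, records, patients, fdr=0.25)
        ref_pairs = set(zip(ddi["drug_a"], ddi["drug_b"]))
        for u, v in G.edges:
            assert tuple(sorted((u, v))) in ref_pairs
            assert G.edges[u, v]["fdr_q"] <= 0.25

    def test_node_risk_invariant_to_row_order(self, daily_window):
        recs, pats, ddi = _cohort(daily_window)
        shuffled = recs.sample(frac=1, random_state=3).reset_index(drop=True)
        def risks(r):
            eps = ca.detect_pair_episodes(r, ddi, daily_window)
            stats_ = ca.pair_population_stats(eps, r, daily_window)
            sig = net.pair_significance(stats_, r["patient_id"].nunique())
            G = net.build_network(sig, eps, r, pats)
            return {n: G.nodes[n]["node_risk"] for n in G}
        assert risks(recs) == risks(shuffled)


class TestExport:
    def test_graphml_roundtrip_preserves_attributes(self, tmp_path,
                                                    daily_window):
        recs, pats, ddi = _cohort(daily_window)
        eps = ca.detect_pair_episodes(recs, ddi, daily_window)
        stats_ = ca.pair_population_stats(eps, recs, daily_window)
        sig = net.pair_significance(stats_, recs["patient_id"].nunique())
        G = net.build_network(sig, eps, recs, pats)
        path = tmp_path / "net.graphml"
        net.export_network(G, path, "graphml")
        H = net.read_network(path)
        assert set(H.nodes) == set(G.nodes)
        for u, v, d in G.edges(data=True):
            back = H.edges[u, v]
            assert back["severity"] == d["severity"]
            assert back["tau_mean"] == pytest.approx(d["tau_mean"])
            assert back["n_coadmin_users"] == d["n_coadmin_users"]

    def test_empty_network_valid_graphml(self, tmp_path):
        import networkx as nx
        path = tmp_path / "empty.graphml"
        net.export_network(nx.Graph(), path, "graphml")
        assert net.read_network(path).number_of_nodes() == 0

    def test_min_tau_filter(self, tmp_path, daily_window):
        recs, pats, ddi = _cohort(daily_window)
        eps = ca.detect_pair_episodes(recs, ddi, daily_window)
        stats_ = ca.pair_population_stats(eps, recs, daily_window)
        sig = net.pair_significance(stats_, recs["patient_id"].nunique())
        G = net.build_network(sig, eps, recs, pats)
        path = tmp_path / "net.csv"
        net.export_network(G, path, "edgelist", min_tau=2.0)
        assert pd.read_csv(path).empty  # no edge reaches tau_mean of 2

    def test_unknown_format_rejected(self):
        import networkx as nx
        with pytest.raises(ValueError, match="format"):
            net.export_network(nx.Graph(), "x.bin", "binary")
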