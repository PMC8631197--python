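import numpy as np
import pandas as pd
import pytest

from _oracles import hypergeom_upper_tail, pearson_perm_p
from cernapipe.cerna import (CorrEdge, assemble_network, export_network,
                             filter_coexpression, filter_mirna_target,
                             hypergeom_sponge_test, import_network_tsv,
                             intersect_hub_mrnas, network_summary,
                             pearson_edge)
from cernapipe.config import Thresholds


class TestPearsonEdge:
    def test_identity_is_one(self):
        x = np.array([1.0, 2, 3, 5, 8])
        e = pearson_edge(x, x)
        assert e.r == pytest.approx(1.0)
        assert e.p == pytest.approx(0.0, abs=1e-12)

    def test_affine_anti_identity(self):
        x = np.array([1.0, 2, 3, 5, 8])
        e = pearson_edge(x, -x + 3)
        assert e.r == pytest.approx(-1.0)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            x = rng.normal(size=8)
            y = 0.5 * x + rng.normal(size=8)
            e = pearson_edge(x, y)
            p_perm = pearson_perm_p(x, y, n_perm=100_000, seed=seed)
            assert abs(e.p - p_perm) < 0.02

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            pearson_edge([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_edge([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson_edge([1, 2, 3], [1, 2, 3, 4])


def _expr(rows: dict[str, np.ndarray]) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    df.index.name = "feature_id"
    return df


class TestCorrelationFilters:
    def setup_method(self):
        t = np.linspace(0, 1, 12)
        rng = np.random.default_rng(0)
        self.expr_mi = _expr({
            "m_anti": 10 - 8 * t,            # r = -1 vs target
            "m_weak": 10 - 8 * t + 3.0 * rng.normal(size=12),
            "m_pos": 2 + 8 * t,
        })
        self.expr_t = _expr({"g1": 1 + 9 * t})

    def test_anti_correlated_pair_retained(self):
        pairs = pd.DataFrame({"mirna_id": ["m_anti"], "target_id": ["g1"]})
        out = filter_mirna_target(pairs, self.expr_mi, self.expr_t,
                                  log2=False)
        assert len(out) == 1
        assert out["r"].iloc[0] < -0.9

    def test_weak_and_positive_pairs_dropped(self):
        pairs = pd.DataFrame({"mirna_id": ["m_weak", "m_pos"],
                              "target_id": ["g1", "g1"]})
        out = filter_mirna_target(pairs, self.expr_mi, self.expr_t,
                                  log2=False)
        assert out.empty

    def test_threshold_is_strict(self):
        # r exactly at the cutoff must not pass (r < r_max is strict)
        pairs = pd.DataFrame({"mirna_id": ["m_anti"], "target_id": ["g1"]})
        out = filter_mirna_target(pairs, self.expr_mi, self.expr_t,
                                  r_max=-1.0, log2=False)
        assert out.empty

    def test_coexpression_keeps_only_strong_positive(self):
        t = np.linspace(0, 1, 12)
        rng = np.random.default_rng(1)
        ce = _expr({"ce_good": 1 + t, "ce_anti": 2 - t,
                    "ce_noisy": 1 + t + 2.0 * rng.normal(size=12)})
        mr = _expr({"g": 3 + 2 * t})
        out = filter_coexpression(list(ce.index), ["g"], ce, mr, log2=False)
        assert set(out["ce_id"]) == {"ce_good"}

    def test_missing_feature_raises(self):
        pairs = pd.DataFrame({"mirna_id": ["nope"], "target_id": ["g1"]})
        with pytest.raises(KeyError):
            filter_mirna_target(pairs, self.expr_mi, self.expr_t)


class TestHypergeomSpongeTest:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_sponge_test(20, 5, 6, 0) == 1.0

    def test_degenerate_full_marking(self):
        assert hypergeom_sponge_test(10, 10, 4, 4) == pytest.approx(1.0)

    def test_worked_example(self):
        assert hypergeom_sponge_test(20, 5, 6, 3) == pytest.approx(
            hypergeom_upper_tail(20, 5, 6, 3), abs=1e-12)
        assert hypergeom_sponge_test(20, 5, 6, 3) == pytest.approx(
            0.1313, abs=5e-5)

    def test_matches_enumeration_for_small_populations(self):
        for N in range(1, 16):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_sponge_test(N, K, n, k) == \
                            pytest.approx(hypergeom_upper_tail(N, K, n, k),
                                          abs=1e-12)

    def test_monotone_in_k(self):
        prev = 1.1
        for k in range(7):
            p = hypergeom_sponge_test(30, 10, 7, k)
            assert p <= prev + 1e-15
            prev = p

    def test_inconsistent_counts_rejected(self):
        for bad in ((10, 11, 3, 1), (10, 3, 4, 4), (10, 3, 4, -1)):
            with pytest.raises(ValueError):
                hypergeom_sponge_test(*bad)


# ---------------------------------------------------------------------------
# a hand-built near-noiseless system with exactly one planted triplet
# ---------------------------------------------------------------------------

def one_triplet_inputs():
    """One noiseless planted triplet (ce1, {m1,m2,m3}, g1).

    Five further DE miRNAs (m4-m8) retain an anti-correlated target g2, so
    the sponge-test population is N = 8 and the triplet's overlap
    (K=n=k=3) has p_hyper = 1/C(8,3) ~= 0.018; g2 itself has no sponge and
    never enters the network.
    """
    t = np.array([0., 1, 2, 3, 4, 5, 10, 11, 12, 13, 14, 15])
    ce = 5 + t
    mr = 3 + 2 * t
    mi = 40 - 2 * t
    extra = {f"m{i}": mi + 0.3 * i for i in range(4, 9)}
    expr = {
        "lncRNA": _expr({"ce1": ce}),
        "mRNA": _expr({"g1": mr, "g2": 1 + 3 * t}),
        "circRNA": _expr({"c_none": np.linspace(5, 6, 12)}),
        "miRNA": _expr({"m1": mi, "m2": mi + 0.5, "m3": mi * 1.1, **extra}),
    }
    def de(ids, direction):
        return pd.DataFrame({"direction": direction},
                            index=pd.Index(ids, name="feature_id"))
    de_tables = {
        "mRNA": de(["g1", "g2"], "up"),
        "lncRNA": de(["ce1"], "up"),
        "circRNA": de(["c_none"], "down"),
        "miRNA": de(["m1", "m2", "m3", "m4", "m5", "m6", "m7", "m8"],
                    "down"),
    }
    pairs = pd.DataFrame(
        {"mirna_id": ["m1", "m2", "m3", "m1", "m2", "m3",
                      "m4", "m5", "m6", "m7", "m8"],
         "target_id": ["ce1", "ce1", "ce1", "g1", "g1", "g1",
                       "g2", "g2", "g2", "g2", "g2"],
         "n_sites": 1, "best_class": "8mer", "best_score": None})
    return de_tables, pairs, expr


class TestAssembleNetwork:
    def test_single_triplet_network_shape(self):
        de_tables, pairs, expr = one_triplet_inputs()
        net = assemble_network(de_tables, pairs, expr, "lncRNA",
                               Thresholds(log_expression=False))
        assert net.number_of_nodes() == 5
        assert net.number_of_edges() == 7
        summary = network_summary(net)
        assert summary["nodes_by_type"]["lncRNA"]["total"] == 1
        assert summary["nodes_by_type"]["miRNA"]["total"] == 3
        assert summary["nodes_by_type"]["mRNA"]["total"] == 1
        assert summary["edges_by_type"] == {"miRNA-mRNA": 3, "miRNA-ce": 3,
                                            "ce-mRNA": 1}

    def test_no_de_features_gives_empty_network(self):
        de_tables, pairs, expr = one_triplet_inputs()
        empty = {cls: t.assign(direction="ns")
                 for cls, t in de_tables.items()}
        net = assemble_network(empty, pairs, expr, "lncRNA",
                               Thresholds(log_expression=False))
        assert net.number_of_nodes() == 0

    def test_two_shared_mirnas_insufficient(self):
        de_tables, pairs, expr = one_triplet_inputs()
        pairs2 = pairs[~((pairs.mirna_id == "m3") &
                         (pairs.target_id == "g1"))]
        net = assemble_network(de_tables, pairs2, expr, "lncRNA",
                               Thresholds(log_expression=False))
        assert net.number_of_edges() == 0

    def test_min_shared_relaxation_recovers_pair(self):
        de_tables, pairs, expr = one_triplet_inputs()
        pairs2 = pairs[~((pairs.mirna_id == "m3") &
                         (pairs.target_id == "g1"))]
        th = Thresholds(log_expression=False, min_shared_mirnas=2,
                        p_hyper_cut=1.0)
        net = assemble_network(de_tables, pairs2, expr, "lncRNA", th)
        assert net.has_edge("ce1", "g1")
        assert net.edges["ce1", "g1"]["k"] == 2


class TestSummaryAndHubs:
    def test_empty_summary(self):
        import networkx as nx
        s = network_summary(nx.Graph())
        assert s["n_nodes"] == 0 and s["n_edges"] == 0

    def test_hub_intersection_cases(self):
        import networkx as nx

        def mk(mrnas, others=()):
            g = nx.Graph()
            for m in mrnas:
                g.add_node(m, rna_type="mRNA", direction="up")
            for o in others:
                g.add_node(o, rna_type="miRNA", direction="down")
            return g

        assert intersect_hub_mrnas(mk(["a", "b", "c"]), mk(["b", "c", "d"])) \
            == ["b", "c"]
        assert intersect_hub_mrnas(mk(["a"]), mk(["z"])) == []
        assert intersect_hub_mrnas(mk(["a", "b"]), mk(["a", "b"])) \
            == ["a", "b"]
        # non-mRNA nodes never count
        assert intersect_hub_mrnas(mk([], ["x"]), mk([], ["x"])) == []


class TestExport:
    def test_sif_rows(self, tmp_path):
        de_tables, pairs, expr = one_triplet_inputs()
        net = assemble_network(de_tables, pairs, expr, "lncRNA",
                               Thresholds(log_expression=False))
        sif = tmp_path / "net.sif"
        export_network(net, sif, "sif")
        lines = sif.read_text().splitlines()
        assert len(lines) == 7
        assert all(len(l.split("\t")) == 3 for l in lines)

    def test_empty_sif(self, tmp_path):
        import networkx as nx
        export_network(nx.Graph(), tmp_path / "e.sif", "sif")
        assert (tmp_path / "e.sif").read_text() == ""

    def test_tsv_round_trip(self, tmp_path):
        de_tables, pairs, expr = one_triplet_inputs()
        net = assemble_network(de_tables, pairs, expr, "lncRNA",
                               Thresholds(log_expression=False))
        base = tmp_path / "net"
        export_network(net, base, "tsv")
        back = import_network_tsv(base)
        assert set(back.nodes) == set(net.nodes)
        assert set(map(frozenset, back.edges)) == \
            set(map(frozenset, net.edges))
        for a, b in net.edges:
            assert back.edges[a, b]["edge_type"] == net.edges[a, b]["edge_type"]
            assert back.edges[a, b]["r"] == pytest.approx(net.edges[a, b]["r"])

    def test_graphml_written_with_attributes(self, tmp_path):
        import networkx as nx
        de_tables, pairs, expr = one_triplet_inputs()
        net = assemble_network(de_tables, pairs, expr, "lncRNA",
                               Thresholds(log_expression=False))
        path = tmp_path / "net.graphml"
        export_network(net, path, "graphml")
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == 5
        node = dict(back.nodes(data=True))["ce1"]
        assert node["rna_type"] == "lncRNA"

    def test_unknown_format_rejected(self, tmp_path):
        import networkx as nx
        with pytest.raises(ValueError):
            export_network(nx.Graph(), tmp_path / "x", "xlsx")
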