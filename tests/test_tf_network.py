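import numpy as np
import pandas as pd
import pytest

from lncregnet.enrichment import hypergeom_upper_tail
from lncregnet.io_formats import (
    GeneSet,
    GeneSetCollection,
    read_network_graphml,
    write_network,
)
from lncregnet.tf_network import (
    associate_tfs,
    build_lncrna_tf_gene_network,
    build_lncrna_tf_network,
    network_summary,
)


def tf_collection(*sets):
    return GeneSetCollection([GeneSet(n, "d", list(m)) for n, m in sets],
                             kind_tag="tf_targets")


# ---------------------------------------------------------------------------
# associations
# ---------------------------------------------------------------------------

def test_maximal_overlap_retained():
    targets = [f"T{i}" for i in range(20)]
    universe = targets + [f"U{i}" for i in range(980)]
    sets = tf_collection(("TF1", targets),
                         ("TF2", [f"U{i}" for i in range(20)]))
    table = associate_tfs({"L1": targets}, sets, universe)
    assert list(table["tf"]) == ["TF1"]
    assert table.loc[0, "k"] == 20
    expected = hypergeom_upper_tail(20, 20, 20, 1000)
    assert table.loc[0, "p_value"] == pytest.approx(expected, rel=1e-12)


def test_disjoint_lists_give_no_association():
    sets = tf_collection(("TF1", ["A", "B"]))
    table = associate_tfs({"L1": ["X", "Y"]}, sets, ["A", "B", "X", "Y"])
    assert table.empty


def test_empty_inputs_empty_table():
    sets = tf_collection(("TF1", ["A"]))
    assert associate_tfs({}, sets, ["A"]).empty


def test_association_p_equals_enrichment_hypergeom():
    rng = np.random.default_rng(3)
    universe = [f"G{i}" for i in range(200)]
    sets = tf_collection(
        *[(f"TF{j}", list(rng.choice(universe, 30, replace=False)))
          for j in range(4)])
    lists = {f"L{j}": list(rng.choice(universe, 40, replace=False))
             for j in range(3)}
    table = associate_tfs(lists, sets, universe, q_max=1.0)
    assert len(table) == 12
    for rec in table.itertuples(index=False):
        assert rec.p_value == pytest.approx(
            hypergeom_upper_tail(rec.k, rec.K, rec.n, rec.N), rel=1e-12)


def test_planted_module_recovery():
    """Planted lncRNA->TF couplings recovered with at most one false edge."""
    from lncregnet.diffexpr import (ThresholdConfig, differential_expression,
                                    select_differential)
    from lncregnet.coexpression import coexpressed_genes
    from lncregnet.preprocess import preprocess
    from lncregnet.synthetic import SimulationConfig, simulate_dataset

    ok_true = ok_false = 0
    reps = 5  # scaled from the 100-rep design for suite runtime
    for seed in range(1, reps + 1):
        cfg = SimulationConfig(n_mrna=800, n_lncrna=300, frac_de_mrna=0.0,
                               frac_de_lncrna=0.0, n_cis_pairs=0,
                               n_trans_pairs=0, n_tf_modules=5, seed=seed)
        ds = simulate_dataset(cfg)
        mat, _ = preprocess(ds.matrix, ds.design)
        res = differential_expression(mat, ds.design, ds.annotation)
        de_l = list(pd.concat(
            select_differential(res, ThresholdConfig(), "lncRNA"))["probe_id"])
        universe = sorted({ds.annotation.symbol_of(p)
                           for p in ds.annotation.probes_of_type("mRNA")
                           if p in set(mat.probe_ids)})
        lists = {p: coexpressed_genes(p, mat, ds.annotation) for p in de_l}
        table = associate_tfs(lists, ds.tf_sets, universe)
        truth = {(m["driver_lncrna_probe_id"], m["tf"])
                 for m in ds.truth.tf_modules}
        got = set(zip(table["lncrna"], table["tf"]))
        ok_true += len(truth & got) >= 4
        ok_false += len(got - truth) <= 1
    assert ok_true >= reps - 1
    assert ok_false >= reps - 1


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def _assoc(rows):
    return pd.DataFrame(rows, columns=["lncrna", "tf", "k", "K", "n", "N",
                                       "p_value", "q_value", "overlap_members"])


def test_shared_tf_connected_component():
    table = _assoc([("L1", "TF1", 1, 1, 1, 10, 0.01, 0.01, "G1"),
                    ("L2", "TF1", 1, 1, 1, 10, 0.01, 0.01, "G1")])
    g = build_lncrna_tf_network(table)
    summary = network_summary(g)
    assert summary["n_nodes"] == 3
    assert summary["n_components"] == 1
    assert g.node_type("TF1") == "TF"
    assert g.node_type("L1") == "lncRNA"


def test_empty_associations_empty_graph():
    g = build_lncrna_tf_network(_assoc([]))
    assert g.n_nodes == 0 and g.n_edges == 0


def test_edge_score_is_neg_log10_p():
    table = _assoc([("L1", "TF1", 1, 1, 1, 10, 1e-4, 1e-4, "G1")])
    g = build_lncrna_tf_network(table)
    assert g.edges[0][3] == pytest.approx(4.0)


def _union_find_components(edges, nodes):
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for s, t in edges:
        parent[find(s)] = find(t)
    return len({find(n) for n in nodes})


def test_component_count_matches_union_find_oracle():
    rng = np.random.default_rng(13)
    for _ in range(10):
        n_l, n_t = 8, 5
        rows = []
        for i in range(n_l):
            for j in range(n_t):
                if rng.random() < 0.15:
                    rows.append((f"L{i}", f"TF{j}", 1, 1, 1, 10, 0.01, 0.01, ""))
        g = build_lncrna_tf_network(_assoc(rows))
        expected = _union_find_components(
            [(s, t) for s, t, *_ in g.edges], [n for n, _ in g.nodes])
        assert network_summary(g)["n_components"] == expected


def test_tripartite_construction():
    table = _assoc([("L", "TF1", 2, 3, 2, 10, 0.01, 0.01, "G1,G2")])
    sets = tf_collection(("TF1", ["G1", "G2", "G3"]))
    coexpr = {"L": ["G1", "G2", "G9"]}
    g = build_lncrna_tf_gene_network(table, sets, coexpr)
    assert dict(g.nodes) == {"L": "lncRNA", "TF1": "TF", "G1": "gene", "G2": "gene"}
    relations = {(s, t, rel) for s, t, rel, _ in g.edges}
    assert relations == {("L", "TF1", "tf_association"),
                         ("TF1", "G1", "targets"), ("TF1", "G2", "targets")}
    # G3 targeted but not co-expressed with L -> excluded
    assert "G3" not in dict(g.nodes)


def test_tripartite_hand_enumerated_fixture():
    table = _assoc([
        ("L1", "TF1", 2, 2, 2, 20, 0.001, 0.003, "A,B"),
        ("L2", "TF1", 1, 2, 1, 20, 0.01, 0.01, "A"),
        ("L2", "TF2", 1, 1, 1, 20, 0.005, 0.0075, "C"),
    ])
    sets = tf_collection(("TF1", ["A", "B"]), ("TF2", ["C"]))
    coexpr = {"L1": ["A", "B"], "L2": ["A", "C"]}
    g = build_lncrna_tf_gene_network(table, sets, coexpr)
    # nodes: L1, L2, TF1, TF2, A, B, C
    assert g.n_nodes == 7
    # edges: L1-TF1, L2-TF1, L2-TF2, TF1-A, TF1-B, TF2-C
    assert g.n_edges == 6


def test_summary_matches_bruteforce_on_random_graphs():
    import networkx as nx
    rng = np.random.default_rng(29)
    for _ in range(5):
        n = int(rng.integers(5, 60))
        gnx = nx.gnp_random_graph(n, 0.08, seed=int(rng.integers(1 << 30)))
        nodes = [(f"N{i}", "gene") for i in gnx.nodes]
        edges = [(f"N{u}", f"N{v}", "rel", 1.0) for u, v in gnx.edges]
        from lncregnet.io_formats import NetworkGraph
        g = NetworkGraph(nodes=nodes, edges=edges)
        summary = network_summary(g)
        assert summary["n_nodes"] == gnx.number_of_nodes()
        assert summary["n_edges"] == gnx.number_of_edges()
        assert summary["n_components"] == nx.number_connected_components(gnx)
        degs = sorted(d for _, d in gnx.degree())
        assert sum(k * v for k, v in summary["degree_distribution"].items()) == sum(degs)


def test_export_reimport_preserves_everything(tmp_path):
    table = _assoc([("L1", "TF1", 1, 1, 1, 10, 1e-6, 1e-6, "G1")])
    sets = tf_collection(("TF1", ["G1"]))
    g = build_lncrna_tf_gene_network(table, sets, {"L1": ["G1"]})
    write_network(g, tmp_path / "g.graphml", "GraphML")
    back = read_network_graphml(tmp_path / "g.graphml")
    assert dict(back.nodes) == dict(g.nodes)
    assert sorted(back.edges) == sorted(g.edges)
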