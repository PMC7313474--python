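import networkx as nx
import numpy as np
import pandas as pd
import pytest

from switchscan import (
    CartographyThresholds,
    CommunityPartition,
    CorrelationNetwork,
    SwitchGeneSet,
    average_neighbor_correlation,
    choose_k_scree,
    classify_nodes,
    clusterphobic_coefficient,
    compute_cartography,
    extract_switch_genes,
    kmeans_partition,
    within_module_degree_z,
)
from switchscan.cartography import CartographyError

from conftest import make_em


# ---------------------------------------------------------------------------
# helpers / oracles
# ---------------------------------------------------------------------------

def random_net_partition(seed, n_max=50):
    """Random signed graph + random module partition for oracle checks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, n_max + 1))
    g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.5), seed=int(seed))
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
    for a, b in g.edges:
        g.edges[a, b]["weight"] = float(rng.uniform(-1, 1))
    k = int(rng.integers(1, 5))
    raw = rng.integers(0, k, n)
    remap, assignment = {}, {}
    for node, lab in zip(sorted(g.nodes), raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        assignment[node] = remap[lab]
    net = CorrelationNetwork(g)
    part = CommunityPartition(assignment, len(remap), 0.0, 1)
    return net, part


def zg_oracle(net, part):
    out = {}
    nodes = list(net.graph.nodes)
    kappa = {
        n: sum(1 for nb in net.graph.neighbors(n)
               if part.assignment[nb] == part.assignment[n])
        for n in nodes
    }
    for n in nodes:
        peers = [kappa[m] for m in nodes
                 if part.assignment[m] == part.assignment[n]]
        mu = sum(peers) / len(peers)
        sd = (sum((v - mu) ** 2 for v in peers) / len(peers)) ** 0.5
        out[n] = 0.0 if sd == 0 else (kappa[n] - mu) / sd
    return out


def kpi_oracle(net, part):
    out = {}
    for n in net.graph.nodes:
        k = net.graph.degree(n)
        if k == 0:
            out[n] = 0.0
            continue
        kappa = sum(1 for nb in net.graph.neighbors(n)
                    if part.assignment[nb] == part.assignment[n])
        out[n] = 1.0 - (kappa / k) ** 2
    return out


def apcc_oracle(net):
    out = {}
    for n in net.graph.nodes:
        ws = [net.graph.edges[n, nb]["weight"] for nb in net.graph.neighbors(n)]
        out[n] = sum(ws) / len(ws) if ws else float("nan")
    return out


def star_module_net():
    """One 5-node star module (kappa 4,1,1,1,1) plus a disjoint pair."""
    g = nx.Graph()
    for leaf in "bcde":
        g.add_edge("a", leaf, weight=0.9)
    g.add_edge("x", "y", weight=-0.8)
    assignment = {n: 1 for n in "abcde"} | {"x": 2, "y": 2}
    return CorrelationNetwork(g), CommunityPartition(assignment, 2, 0.0, 1)


# ---------------------------------------------------------------------------
# k-means and scree
# ---------------------------------------------------------------------------

def blobs_em(seed=0, n_per=40, noise=0.05):
    """Three well-separated profile blobs in a 6-sample space."""
    rng = np.random.default_rng(seed)
    shapes = np.array([
        [1, 1, 1, -1, -1, -1],
        [1, -1, 1, -1, 1, -1],
        [-1, -1, 1, 1, -1, 1],
    ], dtype=float)
    rows = [shapes[m] + noise * rng.normal(size=6)
            for m in range(3) for _ in range(n_per)]
    return make_em(np.array(rows), 3, 3)


class TestScree:
    def test_three_blobs_choose_k_three(self):
        em = blobs_em()
        k, curve = choose_k_scree(em, range(2, 9), replicates=10, seed=0)
        assert k == 3
        assert list(curve["k"]) == list(range(2, 9))

    def test_more_replicates_never_increase_min_sse(self):
        em = blobs_em(seed=1, n_per=15, noise=0.5)
        for k in (2, 3, 4):
            sse1 = kmeans_partition(em, k, replicates=1, seed=5).sse
            sse50 = kmeans_partition(em, k, replicates=50, seed=5).sse
            assert sse50 <= sse1 + 1e-9


class TestKmeansPartition:
    def test_duplicate_profile_groups_split_perfectly(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=6), rng.normal(size=6)
        em = make_em(np.array([a, a, a, b, b, b]), 3, 3)
        part = kmeans_partition(em, 2, replicates=5, seed=0)
        assert part.sse == pytest.approx(0.0, abs=1e-20)
        mods = [part.assignment[g] for g in em.gene_ids]
        assert mods[0] == mods[1] == mods[2] != mods[3]
        assert mods[3] == mods[4] == mods[5]

    def test_one_gene_per_cluster_gives_zero_sse(self):
        rng = np.random.default_rng(3)
        em = make_em(rng.normal(size=(8, 6)), 3, 3)
        part = kmeans_partition(em, 8, replicates=5, seed=0)
        assert part.sse == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_reproduces_assignment(self):
        em = blobs_em(seed=4, n_per=10, noise=0.8)
        p1 = kmeans_partition(em, 4, replicates=10, seed=11)
        p2 = kmeans_partition(em, 4, replicates=10, seed=11)
        assert p1.assignment == p2.assignment and p1.sse == p2.sse

    def test_sse_equals_recomputation_from_assignment(self):
        rng = np.random.default_rng(5)
        em = make_em(rng.normal(size=(40, 6)), 3, 3)
        part = kmeans_partition(em, 4, replicates=10, seed=1)
        x = em.values
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        sse = 0.0
        for mod in range(1, part.k + 1):
            idx = [i for i, g in enumerate(em.gene_ids)
                   if part.assignment[g] == mod]
            centroid = z[idx].mean(axis=0)
            sse += ((z[idx] - centroid) ** 2).sum()
        assert part.sse == pytest.approx(sse, rel=1e-9)


# ---------------------------------------------------------------------------
# node statistics
# ---------------------------------------------------------------------------

class TestWithinModuleDegree:
    def test_star_module_hand_value(self):
        net, part = star_module_net()
        zg = within_module_degree_z(net, part)
        assert zg["a"] == pytest.approx(2.0)  # (4-1.6)/1.2 population sd
        assert zg["b"] == pytest.approx(-0.5)

    def test_flat_module_all_zero(self):
        net, part = star_module_net()
        assert within_module_degree_z(net, part)[["x", "y"]].eq(0).all()

    def test_isolated_in_module_below_mean(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.7)
        g.add_node("c")
        net = CorrelationNetwork(g)
        part = CommunityPartition({"a": 1, "b": 1, "c": 1}, 1, 0.0, 1)
        assert within_module_degree_z(net, part)["c"] < 0

    def test_translation_invariance_of_other_modules(self):
        net, part = random_net_partition(99)
        zg_before = within_module_degree_z(net, part)
        g2 = net.graph.copy()
        extra = [f"new{i}" for i in range(5)]
        for i, a in enumerate(extra):
            for b in extra[i + 1:]:
                g2.add_edge(a, b, weight=0.5)
        assignment = dict(part.assignment, **{n: part.k + 1 for n in extra})
        part2 = CommunityPartition(assignment, part.k + 1, 0.0, 1)
        zg_after = within_module_degree_z(CorrelationNetwork(g2), part2)
        for n in net.graph.nodes:
            assert zg_after[n] == pytest.approx(zg_before[n], abs=1e-12)

    def test_internal_degree_sum_conservation(self):
        from switchscan.cartography import internal_degrees
        for seed in range(10):
            net, part = random_net_partition(seed + 300)
            intra = sum(
                1 for a, b in net.graph.edges
                if part.assignment[a] == part.assignment[b]
            )
            assert internal_degrees(net, part).sum() == 2 * intra


class TestKpiAndApcc:
    def test_kpi_formula_cases(self):
        g = nx.Graph()
        # node "i": 1 internal link, 4 external -> kpi = 1 - (1/5)^2
        g.add_edge("i", "in1", weight=0.5)
        for j in range(4):
            g.add_edge("i", f"out{j}", weight=0.5)
        # node "all_in": every link internal -> kpi = 0
        g.add_edge("all_in", "in1", weight=0.5)
        assignment = {"i": 1, "in1": 1, "all_in": 1}
        assignment |= {f"out{j}": 2 for j in range(4)}
        net = CorrelationNetwork(g)
        part = CommunityPartition(assignment, 2, 0.0, 1)
        kpi = clusterphobic_coefficient(net, part)
        assert kpi["i"] == pytest.approx(0.96)
        assert kpi["all_in"] == pytest.approx(0.0)
        assert kpi["out0"] == pytest.approx(1.0)  # only external links

    def test_isolated_node_kpi_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        g.add_node("lonely")
        net = CorrelationNetwork(g)
        part = CommunityPartition({"a": 1, "b": 1, "lonely": 1}, 1, 0.0, 1)
        assert clusterphobic_coefficient(net, part)["lonely"] == 0.0

    def test_apcc_mean_and_single_neighbor(self):
        g = nx.Graph()
        for nb, w in [("p", 0.5), ("q", -0.9), ("r", -0.2)]:
            g.add_edge("c", nb, weight=w)
        g.add_edge("s", "t", weight=-1.0)
        apcc = average_neighbor_correlation(CorrelationNetwork(g))
        assert apcc["c"] == pytest.approx(-0.2)
        assert apcc["s"] == pytest.approx(-1.0)

    def test_no_neighbor_apcc_undefined(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        g.add_node("alone")
        apcc = average_neighbor_correlation(CorrelationNetwork(g))
        assert np.isnan(apcc["alone"])


def test_statistics_match_oracles_on_random_graphs():
    for seed in range(30):
        net, part = random_net_partition(seed)
        zg = within_module_degree_z(net, part)
        kpi = clusterphobic_coefficient(net, part)
        apcc = average_neighbor_correlation(net)
        z_o, k_o, a_o = zg_oracle(net, part), kpi_oracle(net, part), apcc_oracle(net)
        for n in net.graph.nodes:
            assert zg[n] == pytest.approx(z_o[n], abs=1e-12)
            assert kpi[n] == pytest.approx(k_o[n], abs=1e-12)
            if np.isnan(a_o[n]):
                assert np.isnan(apcc[n])
            else:
                assert apcc[n] == pytest.approx(a_o[n], abs=1e-12)


# ---------------------------------------------------------------------------
# classification and extraction
# ---------------------------------------------------------------------------

class TestClassifyNodes:
    @pytest.mark.parametrize(
        "zg,kpi,apcc,region,hub_class,is_switch",
        [
            (1.0, 0.9, -0.2, "R4", "fight_club", True),
            (3.0, 0.9, -0.2, "R7", "fight_club", False),
            (1.0, 0.9, 0.3, "R4", "date", False),
            (1.0, 0.9, 0.7, "R4", "party", False),
            (1.0, 0.03, -0.1, "R1", "fight_club", False),
            (1.0, 0.5, 0.1, "R2", "date", False),
            (1.0, 0.7, 0.1, "R3", "date", False),
            (3.0, 0.2, 0.6, "R5", "party", False),
            (3.0, 0.5, 0.6, "R6", "party", False),
        ],
    )
    def test_plane_regions_and_switch_rule(self, zg, kpi, apcc, region,
                                           hub_class, is_switch):
        cart = classify_nodes(
            pd.Series({"n": zg}), pd.Series({"n": kpi}), pd.Series({"n": apcc})
        )
        row = cart.loc["n"]
        assert row["region"] == region
        assert row["hub_class"] == hub_class
        assert row["is_switch"] == is_switch

    def test_strong_hub_flag_uses_stricter_cut(self):
        cart = classify_nodes(
            pd.Series({"a": 5.5, "b": 3.0}),
            pd.Series({"a": 0.9, "b": 0.9}),
            pd.Series({"a": -0.5, "b": -0.5}),
        )
        assert cart.loc["a", "is_strong_hub"] and not cart.loc["b", "is_strong_hub"]

    def test_isolated_node_excluded_from_switch(self):
        cart = classify_nodes(
            pd.Series({"n": 0.0}), pd.Series({"n": 0.0}),
            pd.Series({"n": np.nan})
        )
        assert cart.loc["n", "hub_class"] == "none"
        assert not cart.loc["n", "is_switch"]

    def test_switch_subset_of_fight_club_subset_of_negative_apcc(self):
        rng = np.random.default_rng(12)
        n = 500
        idx = [f"n{i}" for i in range(n)]
        cart = classify_nodes(
            pd.Series(rng.normal(0, 3, n), index=idx),
            pd.Series(rng.uniform(0, 1, n), index=idx),
            pd.Series(rng.uniform(-1, 1, n), index=idx),
        )
        switch = set(cart.index[cart["is_switch"]])
        fight = set(cart.index[cart["hub_class"] == "fight_club"])
        negative = set(cart.index[cart["apcc"] < 0])
        assert switch <= fight <= negative


class TestExtractSwitchGenes:
    def test_composition_of_classify_examples(self):
        cart = classify_nodes(
            pd.Series({"a": 1.0, "b": 3.0, "c": 1.0}),
            pd.Series({"a": 0.9, "b": 0.9, "c": 0.9}),
            pd.Series({"a": -0.2, "b": -0.2, "c": 0.3}),
        )
        sw = extract_switch_genes(cart, "AD")
        assert sw.genes == ["a"] and sw.condition == "AD"

    def test_all_nonnegative_apcc_gives_empty_set(self):
        cart = classify_nodes(
            pd.Series({"a": 1.0, "b": 1.0}),
            pd.Series({"a": 0.9, "b": 0.95}),
            pd.Series({"a": 0.2, "b": 0.0}),
        )
        assert extract_switch_genes(cart, "VaD").genes == []

    def test_duplicate_genes_rejected(self):
        with pytest.raises(CartographyError):
            SwitchGeneSet("AD", ["g1", "g1"])


def test_full_cartography_on_planted_star_bridge():
    """A node bridging two cliques with negative weights is the lone switch."""
    g = nx.Graph()
    for mod, names in enumerate((list("abcd"), list("efgh"))):
        for i, x in enumerate(names):
            for y in names[i + 1:]:
                g.add_edge(x, y, weight=0.9)
    for other in "abefg":
        g.add_edge("sw", other, weight=-0.8)
    assignment = {n: 1 for n in "abcd"} | {n: 2 for n in "efgh"} | {"sw": 1}
    net = CorrelationNetwork(g)
    part = CommunityPartition(assignment, 2, 0.0, 1)
    cart = compute_cartography(net, part)
    assert cart.loc["sw", "hub_class"] == "fight_club"
    assert extract_switch_genes(cart, "x").genes == ["sw"]
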