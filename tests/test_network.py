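"""Network assembly, centralities vs independent oracles, hub consensus."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from cernanet import (
    CeRNANetwork,
    ContractError,
    DESets,
    EmptyNetworkError,
    InteractionTable,
    assemble,
    betweenness_centrality,
    centrality_table,
    closeness_centrality,
    compare_centrality_by_class,
    consensus_hubs,
    degree_centrality,
    generate_interactions,
    intersect_catalogues,
    kruskal_wallis,
    restrict_to_de,
)
from cernanet.network import betweenness_raw

from helpers import (
    brute_betweenness,
    brute_closeness,
    brute_degree,
    path_net,
    random_tripartite_net,
    total_intermediate_visits,
)


def tbl(pairs, kind):
    return InteractionTable(kind=kind, pairs=set(pairs), catalogue="t")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def test_forced_assembly():
    net = assemble(
        tbl({("L1", "M1"), ("L2", "M1")}, "lnc_mi"),
        tbl({("M1", "G1")}, "mi_mrna"),
    )
    assert net.n_nodes == 4 and net.n_edges == 3
    assert net.mi_nodes == {"M1"}


def test_mirna_without_mrna_target_is_pruned():
    net = assemble(
        tbl({("L1", "M1"), ("L1", "M2")}, "lnc_mi"),
        tbl({("M1", "G1")}, "mi_mrna"),
    )
    assert "M2" not in net.mi_nodes
    assert net.n_nodes == 3


def test_pruning_drops_newly_isolated_nodes():
    # L2 only touches M2, which lacks an mRNA target, so both disappear
    net = assemble(
        tbl({("L1", "M1"), ("L2", "M2")}, "lnc_mi"),
        tbl({("M1", "G1"), ("M3", "G2")}, "mi_mrna"),
    )
    assert net.lnc_nodes == {"L1"}
    assert net.mi_nodes == {"M1"}
    assert net.mrna_nodes == {"G1"}


def test_empty_tables_raise_empty_network():
    with pytest.raises(EmptyNetworkError):
        assemble(tbl(set(), "lnc_mi"), tbl(set(), "mi_mrna"))
    with pytest.raises(EmptyNetworkError):
        assemble(tbl({("L1", "M1")}, "lnc_mi"), tbl({("M2", "G1")}, "mi_mrna"))


def test_assembly_invariants_on_planted_fixture(small_params):
    params = dataclasses.replace(small_params, catalogue_overlap=1.0)
    lnc_mi, cats, truth = generate_interactions(params)
    de = DESets(
        de_lnc_up={p[0] for p in truth.true_pairs_lnc_mi},
        de_mrna_up={p[1] for p in truth.true_pairs_mi_mrna},
    )
    net = assemble(*restrict_to_de(lnc_mi, intersect_catalogues(cats), de))
    # brute-force reference assembly straight from the planted truth
    mi_ok = {
        m for m in {p[1] for p in truth.true_pairs_lnc_mi}
        if any(pm == m for pm, _ in truth.true_pairs_mi_mrna)
    }
    exp_edges = {
        tuple(sorted(p)) for p in truth.true_pairs_lnc_mi if p[1] in mi_ok
    } | {tuple(sorted(p)) for p in truth.true_pairs_mi_mrna if p[0] in mi_ok}
    assert net.mi_nodes == mi_ok
    assert net.edges == exp_edges
    deg = degree_centrality(net)
    assert all(deg[m] >= 2 for m in net.mi_nodes)
    assert all(deg[v] >= 1 for v in net.nodes)


# ---------------------------------------------------------------------------
# centralities: worked cases
# ---------------------------------------------------------------------------

def test_path_p3_worked_case():
    net = path_net("A", "B", "C")
    assert degree_centrality(net) == {"A": 1, "B": 2, "C": 1}
    clo = closeness_centrality(net)
    assert clo["B"] == pytest.approx(1.0)
    assert clo["A"] == pytest.approx(2.0 / 3.0)
    bet = betweenness_centrality(net)
    assert bet["B"] == pytest.approx(1.0)
    assert bet["A"] == pytest.approx(0.0)


def test_four_cycle_betweenness_splits_credit():
    net = CeRNANetwork(
        lnc_nodes={"A", "C"}, mi_nodes={"B", "D"}, mrna_nodes=set(),
        edges={("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")},
    )
    raw = betweenness_raw(net)
    norm = betweenness_centrality(net)
    for v in "ABCD":
        assert raw[v] == pytest.approx(0.5)
        assert norm[v] == pytest.approx(0.5 / 3)


def test_star_degree():
    net = CeRNANetwork(
        lnc_nodes={"H"}, mi_nodes={"a", "b", "c", "d"}, mrna_nodes=set(),
        edges={("H", x) for x in "abcd"},
    )
    assert degree_centrality(net)["H"] == 4


def test_disconnected_closeness_convention():
    # two disjoint edges in a 4-node graph: (1/1) * (1/3) each
    net = CeRNANetwork(
        lnc_nodes={"L1", "L2"}, mi_nodes={"M1", "M2"}, mrna_nodes=set(),
        edges={("L1", "M1"), ("L2", "M2")},
    )
    clo = closeness_centrality(net)
    for v in clo:
        assert clo[v] == pytest.approx(1.0 / 3.0)


def test_harmonic_mode_alternative():
    net = path_net("A", "B", "C")
    h = closeness_centrality(net, mode="harmonic")
    assert h["B"] == pytest.approx(1.0)
    assert h["A"] == pytest.approx((1.0 + 0.5) / 2)


# ---------------------------------------------------------------------------
# centralities: oracle equivalence
# ---------------------------------------------------------------------------

def test_centralities_match_brute_force_oracles(rng):
    for _ in range(40):
        net = random_tripartite_net(rng, max_side=8, p_edge=float(rng.uniform(0.1, 0.6)))
        deg = degree_centrality(net)
        assert deg == brute_degree(net)
        clo = closeness_centrality(net)
        ref = brute_closeness(net)
        for v in net.nodes:
            assert clo[v] == pytest.approx(ref[v], abs=1e-12)
        bet = betweenness_centrality(net)
        refb = brute_betweenness(net)
        for v in net.nodes:
            assert bet[v] == pytest.approx(refb[v], abs=1e-10)


def test_centralities_match_networkx(rng):
    nx = pytest.importorskip("networkx")
    for _ in range(15):
        net = random_tripartite_net(rng, max_side=7, p_edge=0.35)
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        g.add_edges_from(net.edges)
        assert degree_centrality(net) == dict(g.degree())
        ref_clo = nx.closeness_centrality(g, wf_improved=True)
        clo = closeness_centrality(net)
        for v in net.nodes:
            assert clo[v] == pytest.approx(ref_clo[v], abs=1e-12)
        ref_bet = nx.betweenness_centrality(g, normalized=True, endpoints=False)
        bet = betweenness_centrality(net)
        for v in net.nodes:
            assert bet[v] == pytest.approx(ref_bet[v], abs=1e-10)


def test_raw_betweenness_conservation(rng):
    """Total raw betweenness equals the accumulated count of intermediate
    vertices over all shortest paths (fractional credit sums to d-1 per
    connected pair)."""
    for _ in range(20):
        net = random_tripartite_net(rng, max_side=6, p_edge=0.4)
        raw = betweenness_raw(net)
        assert sum(raw.values()) == pytest.approx(
            total_intermediate_visits(net), abs=1e-9
        )


def test_centrality_invariant_under_relabeling(rng):
    net = random_tripartite_net(rng, max_side=6, p_edge=0.4)
    mapping = {v: f"X{i}" for i, v in enumerate(net.nodes)}
    relabeled = CeRNANetwork(
        lnc_nodes={mapping[v] for v in net.lnc_nodes},
        mi_nodes={mapping[v] for v in net.mi_nodes},
        mrna_nodes={mapping[v] for v in net.mrna_nodes},
        edges={tuple(sorted((mapping[a], mapping[b]))) for a, b in net.edges},
    )
    for fn in (degree_centrality, closeness_centrality, betweenness_centrality):
        orig = fn(net)
        new = fn(relabeled)
        for v in net.nodes:
            assert new[mapping[v]] == pytest.approx(orig[v], abs=1e-12)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kruskal_wallis_hand_case():
    h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert h == pytest.approx(7.2)
    assert p == pytest.approx(float(sps.chi2.sf(7.2, 2)))


def test_kruskal_wallis_all_ties_gives_zero():
    h, p = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
    assert h == 0.0 and p == 1.0


def test_kruskal_wallis_matches_scipy(rng):
    for _ in range(100):
        k = int(rng.integers(2, 5))
        groups = [
            rng.integers(0, 8, size=int(rng.integers(2, 12))).astype(float)
            for _ in range(k)
        ]
        if all(np.all(np.concatenate(groups) == groups[0][0]) for _ in [0]):
            continue
        try:
            ref = sps.kruskal(*groups)
        except ValueError:  # scipy rejects all-identical data
            continue
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)
        assert h >= 0 and 0 < p <= 1


def test_compare_by_class_requires_two_classes(rng):
    net = random_tripartite_net(rng, max_side=5, p_edge=0.5)
    records = centrality_table(net)
    out = compare_centrality_by_class(records)
    assert set(out) == {"degree", "closeness", "betweenness"}
    single = records[records["node_class"] == "miRNA"]
    with pytest.raises(ContractError):
        compare_centrality_by_class(single)


# ---------------------------------------------------------------------------
# hub consensus
# ---------------------------------------------------------------------------

def test_k_at_least_n_returns_all_nodes(rng):
    net = random_tripartite_net(rng, max_side=4, p_edge=0.5)
    records = centrality_table(net)
    hubs = consensus_hubs(records, k=len(records) + 5)
    assert hubs.hubs == set(records["node_id"])


def test_strict_maximum_is_sole_hub():
    net = CeRNANetwork(
        lnc_nodes={"H"}, mi_nodes={"a", "b", "c"}, mrna_nodes={"g1", "g2"},
        edges={("H", "a"), ("H", "b"), ("H", "c"), ("a", "g1"), ("b", "g2")},
    )
    records = centrality_table(net)
    hubs = consensus_hubs(records, k=1)
    assert hubs.hubs == {"H"}


def test_ties_at_rank_k_are_included():
    import pandas as pd

    records = pd.DataFrame(
        {
            "node_id": ["a", "b", "c", "d"],
            "node_class": ["miRNA"] * 4,
            "degree": [5, 3, 3, 1],
            "closeness": [0.9, 0.5, 0.5, 0.1],
            "betweenness": [0.8, 0.4, 0.4, 0.0],
        }
    )
    hubs = consensus_hubs(records, k=2)
    # b and c tie at the k-th value in every metric: both kept
    assert hubs.hubs == {"a", "b", "c"}
    assert hubs.per_metric_topk["degree"] == {"a", "b", "c"}


def test_planted_hubs_dominate(small_params):
    """lncRNAs planted with far-above-background connectivity are called."""
    lnc_mi, cats, truth = generate_interactions(small_params)
    de = DESets(
        de_lnc_up={p[0] for p in lnc_mi.pairs},
        de_mrna_up={p[1] for p in intersect_catalogues(cats).pairs},
    )
    net = assemble(*restrict_to_de(lnc_mi, intersect_catalogues(cats), de))
    records = centrality_table(net)
    hubs = consensus_hubs(records, k=40)
    assert truth.hub_lnc <= hubs.hubs
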