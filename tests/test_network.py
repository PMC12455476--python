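"""Interaction graphs, betweenness, hubs, cliques, small-world estimators."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from condnet import network as net
from condnet.forcefield import thermal_energy
from condnet.synthetic import generate_planted_droplet, generate_reference_graph


# ---------------------------------------------------------------------------
# oracles (independent of networkx's centrality/clique routines)


def _all_shortest_paths_bruteforce(g, s, t):
    """Enumerate shortest s-t paths by depth-first enumeration of simple paths."""
    best: list[list] = []
    best_len = [np.inf]

    def walk(node, path):
        if len(path) - 1 > best_len[0]:
            return
        if node == t:
            if len(path) - 1 < best_len[0]:
                best_len[0] = len(path) - 1
                best.clear()
            if len(path) - 1 == best_len[0]:
                best.append(list(path))
            return
        for nb in g[node]:
            if nb not in path:
                path.append(nb)
                walk(nb, path)
                path.pop()

    walk(s, [s])
    return best


def _betweenness_bruteforce(g):
    n = g.number_of_nodes()
    norm = (n - 1) * (n - 2) / 2
    out = {}
    for i in g.nodes():
        total = 0.0
        for s, t in combinations([v for v in g.nodes() if v != i], 2):
            paths = _all_shortest_paths_bruteforce(g, s, t)
            if not paths:
                continue
            total += sum(i in p for p in paths) / len(paths)
        out[i] = total / norm
    return out


def _maximal_cliques_bruteforce(g):
    nodes = list(g.nodes())
    cliques = []
    for k in range(1, len(nodes) + 1):
        for sub in combinations(nodes, k):
            if all(g.has_edge(a, b) for a, b in combinations(sub, 2)):
                cliques.append(set(sub))
    return [c for c in cliques
            if not any(c < other for other in cliques)]


# ---------------------------------------------------------------------------


def test_betweenness_star_and_path():
    star = nx.star_graph(4)
    cb = net.betweenness(star)
    assert cb[0] == pytest.approx(1.0)
    assert all(cb[v] == 0.0 for v in range(1, 5))
    path = nx.path_graph(3)
    assert net.betweenness(path)[1] == pytest.approx(1.0)


def test_betweenness_requires_three_nodes():
    with pytest.raises(ValueError):
        net.betweenness(nx.path_graph(2))


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_betweenness_matches_exhaustive_enumeration(seed):
    g = nx.gnp_random_graph(8, 0.35, seed=seed)
    cb = net.betweenness(g)
    oracle = _betweenness_bruteforce(g)
    for v in g.nodes():
        assert cb[v] == pytest.approx(oracle[v], abs=1e-12)


def test_tree_betweenness_pair_separation():
    # interior node k of a path with n nodes separates k*(n-1-k) pairs
    n = 7
    g = nx.path_graph(n)
    cb = net.betweenness(g)
    norm = (n - 1) * (n - 2) / 2
    for k in range(n):
        assert cb[k] == pytest.approx(k * (n - 1 - k) / norm)


def test_identify_hubs():
    star = nx.star_graph(6)
    assert net.identify_hubs(star, n_hubs=1).hubs == (0,)
    # all-equal centralities: tie-break by ascending id
    ring = nx.cycle_graph(8)
    assert net.identify_hubs(ring, n_hubs=3).hubs == (0, 1, 2)
    small = net.identify_hubs(nx.path_graph(4), n_hubs=10)
    assert small.truncated and len(small.hubs) == 4


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_hubs_match_sort_then_slice(seed):
    g = nx.gnp_random_graph(20, 0.2, seed=seed)
    cb = net.betweenness(g)
    oracle = sorted(cb, key=lambda v: (-cb[v], v))[:5]
    assert list(net.identify_hubs(g, cb, n_hubs=5).hubs) == oracle


def test_cliques_disjoint_and_overlapping():
    g = nx.Graph()
    g.add_edges_from(combinations(range(5), 2))          # K5
    g.add_edges_from(combinations(range(10, 14), 2))     # K4
    g.add_nodes_from([100, 101])
    cs = net.identify_cliques(g, n_cliques=10)
    assert cs.cliques[0] == (0, 1, 2, 3, 4)
    assert cs.cliques[1] == (10, 11, 12, 13)
    # two K6 sharing 3 vertices: only the first is reported
    h = nx.Graph()
    h.add_edges_from(combinations(range(6), 2))
    h.add_edges_from(combinations([3, 4, 5, 6, 7, 8], 2))
    cs = net.identify_cliques(h, n_cliques=10, max_shared=2)
    assert len([c for c in cs.cliques if len(c) == 6]) == 1


@pytest.mark.parametrize("seed", [20, 21, 22])
def test_maximal_cliques_match_subset_enumeration(seed):
    g = nx.gnp_random_graph(11, 0.45, seed=seed)
    oracle = {frozenset(c) for c in _maximal_cliques_bruteforce(g)}
    found = {frozenset(c) for c in nx.find_cliques(g)}
    assert found == oracle
    # accepted cliques are pairwise <= max_shared overlapping
    cs = net.identify_cliques(g, n_cliques=10, max_shared=2)
    for a, b in combinations(cs.cliques, 2):
        assert len(set(a) & set(b)) <= 2


def test_igraph_backed_metrics_match_networkx():
    for seed in (1, 2):
        g = nx.gnp_random_graph(60, 0.1, seed=seed)
        assert net.average_clustering(g) == pytest.approx(nx.average_clustering(g))
        comp = g.subgraph(max(nx.connected_components(g), key=len))
        assert net.average_path_length(comp) == pytest.approx(
            nx.average_shortest_path_length(comp))


def test_interaction_graph_threshold_monotone(y12, model):
    pd = generate_planted_droplet(y12, model, seed=3)
    frame = pd.trajectory[0]
    edge_counts = []
    for m in (1.0, 3.0, 5.0, 10.0, 30.0):
        ig = net.build_interaction_graph(frame, model, 300.0, m)
        edge_counts.append(ig.graph.number_of_edges())
        assert ig.threshold_multiple == m
    assert all(a >= b for a, b in zip(edge_counts, edge_counts[1:]))


def test_interaction_graph_matches_threshold_arithmetic(y12, model):
    """Edges appear exactly where the pair energy crosses -m k_B T."""
    pd = generate_planted_droplet(y12, model, seed=4)
    frame = pd.trajectory[0]
    ig = net.build_interaction_graph(frame, model, 300.0, 5.0)
    thr = -5.0 * thermal_energy(300.0)
    labels = frame.chain_labels
    for a, b in combinations(range(len(labels)), 2):
        expected = ig.energies[a, b] < thr
        assert ig.graph.has_edge(labels[a], labels[b]) == expected


def test_small_world_stats_errors():
    with pytest.raises(ValueError):
        net.small_world_stats(nx.path_graph(5))
    with pytest.raises(ValueError):
        net.small_world_stats(nx.empty_graph(20))


def test_small_world_ordering_medium_graphs():
    """omega ordering: ring lattice < Watts-Strogatz < ER (n = 400)."""
    ring = generate_reference_graph("ring_lattice", 400, degree=8)
    ws = generate_reference_graph("watts_strogatz", 400, seed=1, degree=8, rewire_p=0.1)
    er = generate_reference_graph("ER", 400, seed=2, degree=8)
    om = [net.small_world_stats(g, n_ref=5, seed=5).omega_sw for g in (ring, ws, er)]
    assert om[0] < om[1] < om[2]
    assert om[0] < -0.6
    assert om[2] > 0.6


def test_banded_latticization_preserves_degrees_and_raises_clustering():
    g = generate_reference_graph("ER", 300, seed=7, degree=8)
    latt = net.lattice_reference_banded(g, seed=0)
    assert abs(latt.number_of_edges() - g.number_of_edges()) <= 3
    assert net.average_clustering(latt) > 10 * net.average_clustering(g)
    deg_in = sorted(d for _, d in g.degree)
    deg_out = sorted(d for _, d in latt.degree)
    assert sum(abs(a - b) for a, b in zip(deg_in, deg_out)) <= 6
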