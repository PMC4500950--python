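import itertools

import networkx as nx
import numpy as np
import pytest

from chromnet.motifs import (
    FFL_CODE,
    all_connected_structures,
    canonical_colored_code,
    canonical_structure,
    enumerate_triads,
    extract_ffl_instances,
    find_significant_motifs,
    per_tf_target_state_counts,
    randomize_network,
)
from chromnet.network import network_from_edges

from conftest import random_colored_digraph
from oracles import census_key_of, colored_census_bruteforce

PAIRS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]


def adj_from_edges(edges):
    adj = [[False] * 3 for _ in range(3)]
    for i, j in edges:
        adj[i][j] = True
    return adj


def labeled(edges, states):
    """Small colored digraph; arbitrary state labels, set directly."""
    net = network_from_edges(edges)
    for n, s in states.items():
        net.nodes[n]["broad_state"] = s
    return net


class TestCanonicalization:
    def test_thirteen_connected_structures(self):
        assert len(all_connected_structures()) == 13

    def test_structures_agree_with_isomorphism_grouping(self):
        """Brute-force grouping of all 64 edge configurations by digraph
        isomorphism gives the same 13 connected classes."""
        reps = []
        for bits in range(64):
            g = nx.DiGraph()
            g.add_nodes_from(range(3))
            g.add_edges_from(p for k, p in enumerate(PAIRS) if bits >> k & 1)
            if nx.number_weakly_connected_components(g) != 1:
                continue
            code = canonical_structure(adj_from_edges(g.edges))
            for other, other_code in reps:
                if nx.is_isomorphic(g, other):
                    assert code == other_code
                    break
            else:
                reps.append((g, code))
        assert len(reps) == 13
        assert len({c for _, c in reps}) == 13

    def test_node_relabeling_preserves_colored_class(self):
        ffl = [(0, 1), (0, 2), (1, 2)]
        colors = ("S", "P", "W")
        base = canonical_colored_code(adj_from_edges(ffl), colors)
        for perm in itertools.permutations(range(3)):
            inv = {perm[i]: i for i in range(3)}
            redges = [(perm[a], perm[b]) for a, b in ffl]
            rcolors = tuple(colors[inv[i]] for i in range(3))
            assert canonical_colored_code(adj_from_edges(redges), rcolors) == base

    def test_ffl_positions_are_distinguishable(self):
        """The FFL has no nontrivial automorphism, so swapping top and
        intermediate states yields a different class."""
        ffl = adj_from_edges([(0, 1), (0, 2), (1, 2)])
        a = canonical_colored_code(ffl, ("Strong", "Poised", "Weak"))
        b = canonical_colored_code(ffl, ("Poised", "Strong", "Weak"))
        assert a != b

    def test_symmetric_structure_merges_equivalent_colorings(self):
        # mutual dyad plus a common source: positions 1 and 2 swap
        edges = [(0, 1), (0, 2), (1, 2), (2, 1)]
        a = canonical_colored_code(adj_from_edges(edges), ("X", "S", "P"))
        b = canonical_colored_code(adj_from_edges(edges), ("X", "P", "S"))
        assert a == b

    def test_disconnected_input_rejected(self):
        with pytest.raises(ValueError):
            canonical_colored_code(adj_from_edges([(0, 1)]), ("A", "B", "C"))

    def test_orbit_count_matches_burnside(self):
        """Total distinct colored classes over all connected structures and
        4^3 colorings equals the Burnside orbit count per structure."""
        colors = ["A", "B", "C", "D"]
        observed = set()
        by_structure_aut = {}
        for bits in range(64):
            edges = [p for k, p in enumerate(PAIRS) if bits >> k & 1]
            adj = adj_from_edges(edges)
            und = {frozenset(e) for e in edges}
            if len(und) < 2:
                continue
            # automorphisms found independently by permutation check
            auts = []
            for perm in itertools.permutations(range(3)):
                if all(
                    adj[perm[i]][perm[j]] == adj[i][j]
                    for i in range(3)
                    for j in range(3)
                    if i != j
                ):
                    auts.append(perm)
            code = canonical_structure(adj)
            by_structure_aut.setdefault(code, auts)
            for coloring in itertools.product(colors, repeat=3):
                observed.add(canonical_colored_code(adj, coloring))

        def cycles(perm):
            seen, n = set(), 0
            for i in range(3):
                if i not in seen:
                    n += 1
                    j = i
                    while j not in seen:
                        seen.add(j)
                        j = perm[j]
            return n

        expected = sum(
            sum(4 ** cycles(p) for p in auts) // len(auts)
            for auts in by_structure_aut.values()
        )
        assert len(observed) == expected


class TestEnumerateTriads:
    def test_single_ffl_counted_once(self):
        net = labeled(
            [("A", "B"), ("A", "C"), ("B", "C")],
            {"A": "Strong", "B": "Strong", "C": "Strong"},
        )
        census = enumerate_triads(net)
        assert len(census) == 1
        ((cls, (count, _)),) = census.items()
        assert cls.structure == FFL_CODE
        assert count == 1

    def test_class_key_invariant_under_renaming(self):
        net1 = labeled(
            [("A", "B"), ("A", "C"), ("B", "C")],
            {"A": "S1", "B": "S2", "C": "S3"},
        )
        net2 = labeled(
            [("X", "Y"), ("X", "Z"), ("Y", "Z")],
            {"X": "S1", "Y": "S2", "Z": "S3"},
        )
        assert set(enumerate_triads(net1)) == set(enumerate_triads(net2))

    def test_self_loops_ignored(self):
        net = labeled(
            [("A", "A"), ("A", "B"), ("A", "C"), ("B", "C")],
            {"A": "S", "B": "S", "C": "S"},
        )
        census = enumerate_triads(net)
        assert sum(c for c, _ in census.values()) == 1

    @pytest.mark.parametrize("n,p", [(12, 0.15), (30, 0.1), (25, 0.2)])
    def test_matches_bruteforce_census(self, n, p, rng):
        """Per-class counts equal an independent O(n^3) census."""
        g = random_colored_digraph(n, p, rng)
        impl = enumerate_triads(g, collect_instances=True)
        oracle = colored_census_bruteforce(g)
        assert sum(c for c, _ in impl.values()) == sum(oracle.values())
        mapped = {}
        for cls, (count, instances) in impl.items():
            key = census_key_of(g, instances[0])
            assert key not in mapped, "two impl classes map to one oracle class"
            mapped[key] = count
        assert mapped == oracle

    def test_uncolored_marginal_matches_triadic_census(self, rng):
        """Summing colored counts per structure equals networkx's triad
        census restricted to connected triad types."""
        g = random_colored_digraph(25, 0.15, rng)
        impl = enumerate_triads(g, collect_instances=True)
        by_structure = {}
        struct_name = {}
        for cls, (count, instances) in impl.items():
            by_structure[cls.structure] = by_structure.get(cls.structure, 0) + count
            if cls.structure not in struct_name:
                sub = g.subgraph(instances[0])
                struct_name[cls.structure] = nx.triad_type(sub)
        expected = nx.triadic_census(g)
        for code, total in by_structure.items():
            assert total == expected[struct_name[code]]

    def test_extract_ffl_instances_orders_positions(self):
        net = labeled(
            [("T", "M"), ("T", "G"), ("M", "G")],
            {"T": "Strong", "M": "Weak", "G": "Poised"},
        )
        (inst,) = extract_ffl_instances(net)
        assert (inst.top, inst.mid, inst.target) == ("T", "M", "G")
        assert inst.states == ("Strong", "Weak", "Poised")


class TestRandomizeNetwork:
    def test_two_matched_edges_can_swap(self, rng):
        net = labeled(
            [("A", "B"), ("C", "D")],
            {"A": "S", "B": "P", "C": "S", "D": "P"},
        )
        swapped = False
        for seed in range(20):
            rnd = randomize_network(net, 10, np.random.default_rng(seed))
            if set(rnd.edges()) == {("A", "D"), ("C", "B")}:
                swapped = True
        assert swapped

    def test_no_legal_swap_returns_identical_network(self, rng):
        # no two edges share a target state -> nothing can move
        net = labeled(
            [("A", "B"), ("C", "D"), ("E", "F")],
            {"A": "S", "B": "S1", "C": "S", "D": "S2", "E": "S", "F": "S3"},
        )
        rnd = randomize_network(net, 100, rng)
        assert set(rnd.edges()) == set(net.edges())

    def test_exact_invariants_on_every_replicate(self, planted_network, rng):
        """Each replicate preserves in/out degrees, per-TF target-state
        counts, node states, and the mutual-dyad census, exactly."""
        net = planted_network
        in_deg = dict(net.in_degree())
        out_deg = dict(net.out_degree())
        tstate = per_tf_target_state_counts(net)
        n_mutual = sum(net.has_edge(v, u) for u, v in net.edges())
        for seed in range(10):
            rnd = randomize_network(
                net, 10 * net.number_of_edges(), np.random.default_rng(seed)
            )
            assert dict(rnd.in_degree()) == in_deg
            assert dict(rnd.out_degree()) == out_deg
            assert per_tf_target_state_counts(rnd) == tstate
            assert sum(rnd.has_edge(v, u) for u, v in rnd.edges()) == n_mutual
            assert all(
                rnd.nodes[n]["broad_state"] == net.nodes[n]["broad_state"]
                for n in net.nodes
            )

    def test_mixing_actually_moves_edges(self, planted_network, rng):
        rnd = randomize_network(
            planted_network, 10 * planted_network.number_of_edges(), rng
        )
        moved = len(set(planted_network.edges()) - set(rnd.edges()))
        assert moved > 0.3 * planted_network.number_of_edges()


class TestSignificance:
    def test_planted_class_flagged_significant(self, planted_network, rng):
        stats = find_significant_motifs(planted_network, n_random=50, rng=rng)
        cls = [
            s
            for s in stats
            if s.cls.structure == FFL_CODE
            and s.cls.coloring == ("StrongActivity", "StrongActivity", "Poised")
        ]
        assert len(cls) == 1
        assert cls[0].n_real >= 12  # at least the planted copies
        assert cls[0].significant

    def test_unsurprising_class_not_significant(self):
        # a class reproduced exactly by every randomization: p_emp = 1
        net = labeled(
            [("A", "B"), ("C", "D")], {"A": "S", "B": "T", "C": "S", "D": "T"}
        )
        stats = find_significant_motifs(net, n_random=25, rng=np.random.default_rng(0))
        assert stats == []  # no connected triads at all

    def test_p_emp_counts_ties_against_significance(self, rng):
        net = labeled(
            [("T", "M"), ("T", "G"), ("M", "G")],
            {"T": "S", "M": "S", "G": "S"},
        )
        # the single FFL has no legal swap partner: every replicate
        # reproduces it, so p_emp = 1
        (stat,) = find_significant_motifs(net, n_random=25, rng=rng)
        assert stat.p_emp == 1.0
        assert not stat.significant

    def test_null_calibration(self):
        """Without planting, the fraction of classes reaching p < alpha
        stays near alpha (binomial tolerance)."""
        rng = np.random.default_rng(77)
        hits, total = 0, 0
        for rep in range(4):
            g = random_colored_digraph(28, 0.12, rng)
            stats = find_significant_motifs(g, n_random=60, rng=rng)
            hits += sum(s.p_emp < 0.05 for s in stats)
            total += len(stats)
        assert total > 60
        # binomial upper bound at ~4 sigma around alpha
        assert hits / total < 0.05 + 4 * np.sqrt(0.05 * 0.95 / total)
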