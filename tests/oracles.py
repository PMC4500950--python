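"""Independent brute-force oracles used only by the test suite.

These share no code paths with the package: triples are enumerated
exhaustively, canonicalization is recomputed from scratch, and the
hypergeometric tail is obtained by enumerating draws.
"""

import itertools
from math import comb


def colored_census_bruteforce(g):
    """O(n^3) colored census over every node triple of a digraph.

    Canonical key: minimum over the six node orderings of the pair
    (edge-bit string, color tuple).  Counts only weakly connected
    induced triples.
    """
    states = {n: g.nodes[n]["broad_state"] for n in g.nodes}
    census = {}
    for trio in itertools.combinations(sorted(g.nodes), 3):
        # weak connectivity: of the three undirected node pairs, one
        # linked pair touches only two nodes; any two link all three
        und = {
            frozenset((u, v))
            for u, v in itertools.permutations(trio, 2)
            if g.has_edge(u, v)
        }
        if len(und) < 2:
            continue
        best = None
        for order in itertools.permutations(trio):
            bits = "".join(
                "1" if g.has_edge(order[i], order[j]) else "0"
                for i, j in [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
            )
            key = (bits, tuple(states[n] for n in order))
            if best is None or key < best:
                best = key
        census[best] = census.get(best, 0) + 1
    return census


def census_key_of(g, trio):
    """Canonical oracle key of one specific triple (for cross-matching)."""
    sub = g.subgraph(trio)
    return next(iter(colored_census_bruteforce(sub)))


def hypergeom_tail_bruteforce(N, n, M, k):
    """P(X >= k) by exact enumeration: X = |draw of size M intersect term|.

    Counts draws with combinatorial weights; exact rational arithmetic
    via Python integers, returned as a float at the end.
    """
    total = comb(N, M)
    favorable = sum(
        comb(n, x) * comb(N - n, M - x) for x in range(k, min(n, M) + 1)
    )
    return favorable / total
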