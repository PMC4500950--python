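"""Chromatin-state-colored three-node motif census and significance.

A *colored triad class* is a weakly connected 3-node directed structure
(13 exist, up to isomorphism; no self-loops, antiparallel pairs allowed)
together with an assignment of broad chromatin states to its positions,
canonical under the structure's automorphisms.  Significance of each
class observed in the real network is assessed against randomized
networks produced by constrained double-edge swaps that preserve every
node's in- and out-degree, every TF's per-state target counts, and the
two-node (mutual-dyad) census.

A class is called significant when (i) its empirical P — the fraction
of randomized networks containing the class at least as often as the
real one — is below alpha, and (ii) the real count exceeds the
randomized mean by more than 5%: N_real - N_rand > 0.05 * N_rand.
"""

from __future__ import annotations

import functools
import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np

from .states import BroadState

logger = logging.getLogger("chromnet")

_PERMS = list(itertools.permutations(range(3)))


class ColoredTriadClass(NamedTuple):
    """Canonical (structure, coloring) key for a colored 3-node subgraph."""

    structure: int  # canonical 6-bit adjacency code
    coloring: tuple[str, str, str]  # broad-state values by canonical position


class FFLInstance(NamedTuple):
    """A feedforward loop: top→mid, top→target, mid→target."""

    top: str
    mid: str
    target: str
    states: tuple[str, str, str]


@dataclass
class MotifStats:
    """Census result for one colored class against the randomized null."""

    cls: ColoredTriadClass
    n_real: int
    n_rand: np.ndarray
    n_rand_mean: float
    p_emp: float
    significant: bool


# ---------------------------------------------------------------------------
# canonical codes

_PAIR_INDEX = {  # ordered node pair -> bit position
    (0, 1): 0, (0, 2): 1, (1, 0): 2, (1, 2): 3, (2, 0): 4, (2, 1): 5,
}


def _struct_code(adj: Sequence[Sequence[bool]]) -> int:
    code = 0
    for (i, j), bit in _PAIR_INDEX.items():
        if adj[i][j]:
            code |= 1 << bit
    return code


def _permute(adj, colors, perm):
    """Relabel so new position x holds old node perm[x]."""
    padj = [[adj[perm[x]][perm[y]] for y in range(3)] for x in range(3)]
    pcol = tuple(colors[perm[x]] for x in range(3))
    return padj, pcol


def _weakly_connected(adj) -> bool:
    und = [
        adj[0][1] or adj[1][0],
        adj[0][2] or adj[2][0],
        adj[1][2] or adj[2][1],
    ]
    return sum(und) >= 2  # any two of the three undirected pairs link 3 nodes


def canonical_structure(adj: Sequence[Sequence[bool]]) -> int:
    """Isomorphism-invariant code of a 3-node directed structure."""
    return min(_struct_code(_permute(adj, ("", "", ""), p)[0]) for p in _PERMS)


def canonical_colored_code(
    adj: Sequence[Sequence[bool]], colors: Sequence[str]
) -> ColoredTriadClass:
    """Canonical class of a colored, weakly connected 3-node digraph.

    Minimizes (structure code, coloring) jointly over all node
    permutations; for a pre-canonical structure only its automorphisms
    can change the coloring, so the result is exactly the orbit
    representative under the automorphism group.
    """
    if not _weakly_connected(adj):
        raise ValueError("triad is not weakly connected")
    best = None
    for p in _PERMS:
        padj, pcol = _permute(adj, colors, p)
        key = (_struct_code(padj), pcol)
        if best is None or key < best:
            best = key
    return ColoredTriadClass(best[0], best[1])


def all_connected_structures() -> list[int]:
    """Canonical codes of all weakly connected 3-node structures (13)."""
    codes = set()
    for bits in range(64):
        adj = [[False] * 3 for _ in range(3)]
        for pair, bit in _PAIR_INDEX.items():
            if bits >> bit & 1:
                adj[pair[0]][pair[1]] = True
        if _weakly_connected(adj):
            codes.add(canonical_structure(adj))
    return sorted(codes)


#: Canonical structure code of the feedforward loop (top→mid, top→target,
#: mid→target).
FFL_CODE = canonical_structure(
    [[False, True, True], [False, False, True], [False, False, False]]
)


def _adj_from_bits(bits: int):
    adj = [[False] * 3 for _ in range(3)]
    for pair, bit in _PAIR_INDEX.items():
        if bits >> bit & 1:
            adj[pair[0]][pair[1]] = True
    return adj


@functools.lru_cache(maxsize=8)
def _canonical_table(n_colors: int) -> dict[tuple[int, int, int, int], tuple]:
    """Precomputed canonical (structure, coloring-index) for every connected
    6-bit structure x color-index triple.  Color indices must follow the
    lexicographic order of the color values for the table to agree with
    direct string minimization."""
    table = {}
    for bits in range(64):
        adj = _adj_from_bits(bits)
        if not _weakly_connected(adj):
            continue
        for c0 in range(n_colors):
            for c1 in range(n_colors):
                for c2 in range(n_colors):
                    colors = (c0, c1, c2)
                    best = None
                    for p in _PERMS:
                        padj, pcol = _permute(adj, colors, p)
                        key = (_struct_code(padj), pcol)
                        if best is None or key < best:
                            best = key
                    table[(bits, c0, c1, c2)] = best
    return table


# ---------------------------------------------------------------------------
# census


def _node_states(net: nx.DiGraph) -> dict[str, str]:
    out = {}
    for n, data in net.nodes(data=True):
        st = data.get("broad_state")
        if st is None:
            raise KeyError(f"node {n!r} has no broad_state attribute")
        out[n] = st.value if isinstance(st, BroadState) else str(st)
    return out


def _connected_triples(net: nx.DiGraph) -> Iterable[tuple]:
    """All node triples whose induced subgraph is weakly connected.

    Walks undirected edges and unions endpoint neighborhoods; each
    triple is yielded exactly once via a seen-set.
    """
    nbrs: dict = {
        n: set(net.predecessors(n)) | set(net.successors(n)) - {n}
        for n in net.nodes
    }
    for n in nbrs:
        nbrs[n].discard(n)
    seen: set[tuple] = set()
    for u, v in {tuple(sorted((a, b))) for a, b in net.edges() if a != b}:
        for w in (nbrs[u] | nbrs[v]) - {u, v}:
            key = tuple(sorted((u, v, w)))
            if key not in seen:
                seen.add(key)
                yield key


def enumerate_triads(
    net: nx.DiGraph, collect_instances: bool = False
) -> dict[ColoredTriadClass, tuple[int, list[tuple]]]:
    """Census of induced, weakly connected, colored 3-node subgraphs.

    Self-loops are ignored.  Returns per-class counts and (optionally)
    the node triples realizing each class, each triple counted once.
    """
    states = _node_states(net)
    # color indices in lexicographic value order, so table lookups agree
    # with direct string minimization
    values = sorted(set(states.values()))
    vidx = {v: i for i, v in enumerate(values)}
    cidx = {n: vidx[s] for n, s in states.items()}
    table = _canonical_table(len(values))
    edge_bits: dict[tuple, int] = {}
    for u, v in net.edges():
        if u != v:
            edge_bits[(u, v)] = 1

    census: dict[ColoredTriadClass, tuple[int, list[tuple]]] = {}
    raw: dict[tuple, tuple[int, list[tuple]]] = {}
    get_bit = edge_bits.get
    for triple in _connected_triples(net):
        a, b, c = triple
        bits = (
            (get_bit((a, b), 0))
            | (get_bit((a, c), 0) << 1)
            | (get_bit((b, a), 0) << 2)
            | (get_bit((b, c), 0) << 3)
            | (get_bit((c, a), 0) << 4)
            | (get_bit((c, b), 0) << 5)
        )
        key = table[(bits, cidx[a], cidx[b], cidx[c])]
        count, inst = raw.get(key, (0, []))
        if collect_instances:
            inst.append(triple)
        raw[key] = (count + 1, inst)
    for (struct, color_idx), payload in raw.items():
        cls = ColoredTriadClass(struct, tuple(values[i] for i in color_idx))
        census[cls] = payload
    return census


def extract_ffl_instances(net: nx.DiGraph) -> list[FFLInstance]:
    """All induced feedforward-loop instances with per-position states.

    In an induced FFL (exactly three edges, no mutual pair) the top TF
    has out-degree 2 and the target in-degree 2 within the triple.
    """
    states = _node_states(net)
    out = []
    census = enumerate_triads(net, collect_instances=True)
    for cls, (_, triples) in census.items():
        if cls.structure != FFL_CODE:
            continue
        for triple in triples:
            sub = [
                (u, v)
                for u, v in itertools.permutations(triple, 2)
                if net.has_edge(u, v)
            ]
            outd = {n: 0 for n in triple}
            ind = {n: 0 for n in triple}
            for u, v in sub:
                outd[u] += 1
                ind[v] += 1
            top = next(n for n in triple if outd[n] == 2)
            target = next(n for n in triple if ind[n] == 2)
            mid = next(n for n in triple if n not in (top, target))
            out.append(
                FFLInstance(
                    top, mid, target,
                    (states[top], states[mid], states[target]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# state-preserving randomization


def randomize_network(
    net: nx.DiGraph, n_swaps: int, rng: np.random.Generator
) -> nx.DiGraph:
    """Degree- and target-state-preserving edge randomization.

    Constrained double-edge swaps (u→v, x→y) → (u→y, x→v) are accepted
    only when the two targets share a chromatin state, so every TF keeps
    its exact per-state target counts.  Mutual (antiparallel) edge pairs
    are swapped only as units against other mutual pairs, and simple
    edges never acquire a reverse partner, so the two-node-subgraph
    census is preserved exactly.  Node states and degrees never change.
    """
    states = _node_states(net)
    edges = set((u, v) for u, v in net.edges() if u != v)
    self_loops = [(u, v) for u, v in net.edges() if u == v]

    mutual_pairs = sorted({tuple(sorted(e)) for e in edges if e[::-1] in edges})
    singles = sorted(e for e in edges if e[::-1] not in edges)
    n_s, n_m = len(singles), len(mutual_pairs)

    def rebuild():
        out = nx.DiGraph()
        out.add_nodes_from(net.nodes(data=True))
        out.add_edges_from(edges)
        out.add_edges_from(self_loops)  # kept aside from swapping
        return out

    if n_s + n_m < 2 or n_swaps <= 0:
        return rebuild()

    # swap types never change, so all randomness can be drawn up front
    pools = rng.integers(0, n_s + n_m, size=n_swaps)
    s_pick = rng.integers(0, max(n_s, 1), size=(n_swaps, 2))
    m_pick = rng.integers(0, max(n_m, 1), size=(n_swaps, 2))
    coin = rng.random(n_swaps)

    for k in range(n_swaps):
        if pools[k] < n_s:
            if n_s < 2:
                continue
            i, j = s_pick[k]
            if i == j:
                continue
            (a, b), (c, d) = singles[i], singles[j]
            # (a→b, c→d) → (a→d, c→b): state match, 4 distinct nodes, no
            # self-loops/duplicates, and no mutual dyad created
            if states[b] != states[d] or len({a, b, c, d}) < 4:
                continue
            if (
                (a, d) in edges or (d, a) in edges
                or (c, b) in edges or (b, c) in edges
            ):
                continue
            edges.discard((a, b))
            edges.discard((c, d))
            edges.add((a, d))
            edges.add((c, b))
            singles[i], singles[j] = (a, d), (c, b)
        else:
            if n_m < 2:
                continue
            i, j = m_pick[k]
            if i == j:
                continue
            (u, v), (x, y) = mutual_pairs[i], mutual_pairs[j]
            if len({u, v, x, y}) < 4:
                continue
            # two repairings conserve degrees; keep those that also
            # conserve per-state target counts
            options = []
            if states[u] == states[x] and states[v] == states[y]:
                options.append(((u, y), (x, v)))
            if states[u] == states[y] and states[v] == states[x]:
                options.append(((u, x), (y, v)))
            if len(options) == 2 and coin[k] < 0.5:
                options.reverse()
            for (p1, p2) in options:
                new_edges = {p1, p1[::-1], p2, p2[::-1]}
                if any(e in edges for e in new_edges):
                    continue
                edges -= {(u, v), (v, u), (x, y), (y, x)}
                edges |= new_edges
                mutual_pairs[i] = tuple(sorted(p1))
                mutual_pairs[j] = tuple(sorted(p2))
                break

    return rebuild()


def per_tf_target_state_counts(net: nx.DiGraph) -> dict[str, dict[str, int]]:
    """For each TF, how many of its targets carry each broad state."""
    states = _node_states(net)
    out: dict[str, dict[str, int]] = {}
    for u, v in net.edges():
        if u == v:
            continue
        out.setdefault(u, {})
        out[u][states[v]] = out[u].get(states[v], 0) + 1
    return out


# ---------------------------------------------------------------------------
# significance


def find_significant_motifs(
    net: nx.DiGraph,
    n_random: int = 500,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    swap_factor: int = 10,
) -> list[MotifStats]:
    """Test every colored class observed in the real network.

    ``n_random`` randomized replicates are generated with
    ``swap_factor * |E|`` attempted swaps each.  Only classes present in
    the real network are tested (enumeration-then-test).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_random < 20:
        logger.warning(
            "n_random=%d gives empirical-P resolution of only %.3g",
            n_random, 1 / max(n_random, 1),
        )
    real = enumerate_triads(net)
    classes = sorted(real)
    n_real = {cls: real[cls][0] for cls in classes}
    rand_counts = {cls: np.zeros(n_random, dtype=int) for cls in classes}
    n_swaps = swap_factor * net.number_of_edges()
    for r in range(n_random):
        rnd_net = randomize_network(net, n_swaps, rng)
        rnd_census = enumerate_triads(rnd_net)
        for cls in classes:
            if cls in rnd_census:
                rand_counts[cls][r] = rnd_census[cls][0]
    out = []
    for cls in classes:
        nr = n_real[cls]
        dist = rand_counts[cls]
        mean = float(dist.mean())
        p = float((dist >= nr).mean())
        sig = p < alpha and (nr - mean) > 0.05 * mean
        out.append(MotifStats(cls, nr, dist, mean, p, sig))
    return out


def motif_stats_table(stats: Iterable[MotifStats]):
    """Flatten MotifStats into a data frame for TSV output."""
    import pandas as pd

    rows = []
    for s in stats:
        rows.append(
            {
                "structure": s.cls.structure,
                "coloring": ",".join(s.cls.coloring),
                "n_real": s.n_real,
                "n_rand_mean": s.n_rand_mean,
                "n_rand_sd": float(np.std(s.n_rand)),
                "p_emp": s.p_emp,
                "significant": s.significant,
            }
        )
    return pd.DataFrame(rows)
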