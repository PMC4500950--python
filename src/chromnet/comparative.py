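"""Between-condition comparison of feedforward loops.

FFL instances defined in the source condition are classified by how
many of their three edges survive in the end condition (3 = no change,
<3 = edge loss); FFLs of the end condition whose edges are not all
present in the source are edge gains.  Chromatin states are promoter
properties, so a gene absent from one condition's network still takes
its state from that condition's gene-state table.

The state-transition permutation test asks, per structural-change group
and FFL position, whether a given state transition occurs in more real
instances than in artificial instance sets assembled from randomly
chosen TFs (top and intermediate positions) and targets (bottom), with
set sizes matching the real group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .motifs import extract_ffl_instances
from .states import BroadState

logger = logging.getLogger("chromnet")

POSITIONS = ("top", "intermediate", "bottom")
_STATES = [s.value for s in BroadState]
_STATE_IDX = {s: i for i, s in enumerate(_STATES)}


@dataclass(frozen=True)
class FFLComparison:
    """One FFL instance tracked across two conditions."""

    top: str
    mid: str
    target: str
    change_group: str  # no_change | edge_loss | edge_gain
    edges_present_source: int
    edges_present_end: int
    states_source: tuple[str, str, str] | None
    states_end: tuple[str, str, str] | None

    @property
    def has_states(self) -> bool:
        return self.states_source is not None and self.states_end is not None


@dataclass(frozen=True)
class TransitionResult:
    group: str
    position: str
    from_state: str
    to_state: str
    count: int
    frequency: float
    p: float
    p_floor: float  # resolution of the permutation procedure (1 / n_perm)


def _edge_count(net: nx.DiGraph, top, mid, target) -> int:
    return sum(
        net.has_edge(u, v) for u, v in ((top, mid), (top, target), (mid, target))
    )


def _states_of(
    genes: tuple[str, str, str], table: Mapping[str, BroadState | str]
) -> tuple[str, str, str] | None:
    out = []
    for g in genes:
        s = table.get(g)
        if s is None:
            return None
        out.append(s.value if isinstance(s, BroadState) else str(s))
    return tuple(out)


def compare_ffls(
    net_A: nx.DiGraph,
    net_B: nx.DiGraph,
    states_A: Mapping[str, BroadState | str] | None = None,
    states_B: Mapping[str, BroadState | str] | None = None,
) -> list[FFLComparison]:
    """Classify every FFL of either condition by structural change.

    ``states_A`` / ``states_B`` default to the node attributes of the
    respective networks; passing gene-state tables lets genes absent
    from one network still carry that condition's promoter state.
    Instances with a missing state in either condition are kept but
    flagged (``has_states`` False) and excluded from transition counts.
    """
    if states_A is None:
        states_A = {n: d["broad_state"] for n, d in net_A.nodes(data=True)}
    if states_B is None:
        states_B = {n: d["broad_state"] for n, d in net_B.nodes(data=True)}

    def labeled_copy(net, table):
        # FFL extraction needs a state on every node; genes without one
        # get a placeholder and are flagged downstream via the tables
        lab = net.copy()
        for n in lab.nodes:
            s = table.get(n, "?")
            lab.nodes[n]["broad_state"] = (
                s.value if isinstance(s, BroadState) else str(s)
            )
        return lab

    net_A = labeled_copy(net_A, states_A)
    net_B = labeled_copy(net_B, states_B)

    out: list[FFLComparison] = []
    source_keys = set()
    for inst in extract_ffl_instances(net_A):
        genes = (inst.top, inst.mid, inst.target)
        source_keys.add(genes)
        k_end = _edge_count(net_B, *genes)
        out.append(
            FFLComparison(
                *genes,
                change_group="no_change" if k_end == 3 else "edge_loss",
                edges_present_source=3,
                edges_present_end=k_end,
                states_source=_states_of(genes, states_A),
                states_end=_states_of(genes, states_B),
            )
        )
    for inst in extract_ffl_instances(net_B):
        genes = (inst.top, inst.mid, inst.target)
        if genes in source_keys:
            continue  # all three edges in source -> already classified
        k_src = _edge_count(net_A, *genes)
        if k_src == 3:
            # present as a (possibly non-induced) FFL in the source too;
            # source extraction is induced, so count it as unchanged only
            # if it was never emitted there
            continue
        out.append(
            FFLComparison(
                *genes,
                change_group="edge_gain",
                edges_present_source=k_src,
                edges_present_end=3,
                states_source=_states_of(genes, states_A),
                states_end=_states_of(genes, states_B),
            )
        )
    n_flagged = sum(not c.has_states for c in out)
    if n_flagged:
        logger.warning(
            "%d FFL instances lack a state in one condition; excluded from "
            "transition counts", n_flagged,
        )
    return out


def architecture_change_fraction(comparisons: Sequence[FFLComparison]) -> float:
    """Fraction of source-condition FFLs whose structure changed."""
    src = [c for c in comparisons if c.change_group in ("no_change", "edge_loss")]
    if not src:
        return 0.0
    return sum(c.change_group == "edge_loss" for c in src) / len(src)


def _pair_indices(comparisons, position: int) -> np.ndarray:
    """(from_state, to_state) index per instance at one FFL position."""
    idx = []
    for c in comparisons:
        a = _STATE_IDX[c.states_source[position]]
        b = _STATE_IDX[c.states_end[position]]
        idx.append(a * len(_STATES) + b)
    return np.asarray(idx, dtype=int)


def _sample_distinct_triples(
    tf_pool: np.ndarray, target_pool: np.ndarray, size: int,
    n_perm: int, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (top, mid, target) index triples, three distinct genes each."""
    tops = rng.choice(tf_pool, size=(n_perm, size))
    mids = rng.choice(tf_pool, size=(n_perm, size))
    targets = rng.choice(target_pool, size=(n_perm, size))
    for _ in range(200):
        bad = (tops == mids) | (tops == targets) | (mids == targets)
        if not bad.any():
            break
        n_bad = int(bad.sum())
        tops[bad] = rng.choice(tf_pool, size=n_bad)
        mids[bad] = rng.choice(tf_pool, size=n_bad)
        targets[bad] = rng.choice(target_pool, size=n_bad)
    else:
        raise RuntimeError("could not sample distinct artificial FFL triples")
    return tops, mids, targets


def transition_test(
    comparisons: Sequence[FFLComparison],
    net_A: nx.DiGraph,
    states_A: Mapping[str, BroadState | str],
    states_B: Mapping[str, BroadState | str],
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[TransitionResult]:
    """Permutation test of per-position state transitions per change group.

    Artificial FFL instance sets draw top/intermediate genes from the TF
    pool and bottom genes from the target pool of the source network,
    uniformly, without requiring edges; each set matches the real group
    size.  P is the fraction of artificial sets whose transition
    frequency is >= the real one (ties count against significance); the
    reported floor 1/n_perm is the resolution of the procedure.
    """
    if rng is None:
        rng = np.random.default_rng()
    tf_pool = sorted(
        n for n in net_A.nodes
        if net_A.out_degree(n) > 0 and n in states_A and n in states_B
    )
    target_pool = sorted(
        n for n in net_A.nodes
        if net_A.in_degree(n) > 0 and n in states_A and n in states_B
    )
    if not tf_pool or not target_pool:
        raise ValueError("empty TF or target pool in the source network")

    def pair_of(g):
        a = states_A[g]
        b = states_B[g]
        a = a.value if isinstance(a, BroadState) else str(a)
        b = b.value if isinstance(b, BroadState) else str(b)
        return _STATE_IDX[a] * len(_STATES) + _STATE_IDX[b]

    tf_pairs = np.asarray([pair_of(g) for g in tf_pool])
    tgt_pairs = np.asarray([pair_of(g) for g in target_pool])

    results: list[TransitionResult] = []
    n_cells = len(_STATES) ** 2
    groups = sorted({c.change_group for c in comparisons})
    for group in groups:
        members = [
            c for c in comparisons if c.change_group == group and c.has_states
        ]
        size = len(members)
        if size == 0:
            continue
        tops, mids, targets = _sample_distinct_triples(
            np.arange(len(tf_pool)), np.arange(len(target_pool)),
            size, n_perm, rng,
        )
        art_pairs = {
            "top": tf_pairs[tops],
            "intermediate": tf_pairs[mids],
            "bottom": tgt_pairs[targets],
        }
        for pos_name, pos_idx in zip(POSITIONS, range(3)):
            real = _pair_indices(members, pos_idx)
            art = art_pairs[pos_name]  # (n_perm, size) of pair indices
            for cell in range(n_cells):
                count = int((real == cell).sum())
                freq = count / size
                art_freq = (art == cell).mean(axis=1)
                p = float((art_freq >= freq).mean()) if count else 1.0
                if count == 0 and cell // len(_STATES) != cell % len(_STATES):
                    continue  # unobserved cross-state cells are not reported
                results.append(
                    TransitionResult(
                        group=group,
                        position=pos_name,
                        from_state=_STATES[cell // len(_STATES)],
                        to_state=_STATES[cell % len(_STATES)],
                        count=count,
                        frequency=freq,
                        p=p,
                        p_floor=1.0 / n_perm,
                    )
                )
    return results


def transitions_table(results: Iterable[TransitionResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def comparisons_table(comparisons: Iterable[FFLComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "top": c.top,
                "mid": c.mid,
                "target": c.target,
                "change_group": c.change_group,
                "edges_present_source": c.edges_present_source,
                "edges_present_end": c.edges_present_end,
                "states_source": ",".join(c.states_source) if c.states_source else "",
                "states_end": ",".join(c.states_end) if c.states_end else "",
            }
        )
    return pd.DataFrame(rows)
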