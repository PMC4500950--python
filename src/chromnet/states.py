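"""Broad chromatin-state annotation of gene promoters.

A genome segmentation (15-state vocabulary or broad labels directly) is
collapsed to four broad classes — strong activity, weak activity, poised
and repressed — and each promoter is assigned the broad state with the
maximum fold enrichment relative to the genome-wide abundance of that
state:

    enrichment(s) = (a_s / b) / (c_s / d)

where ``a_s`` is the number of promoter bases in state ``s``, ``b`` the
promoter length, ``c_s`` the genome-wide bases in state ``s`` and ``d``
the total state-marked bases.  Normalizing by genome-wide abundance
keeps rare but informative states (e.g. poised) competitive with
blanket-abundant ones.
"""

from __future__ import annotations

import logging
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx

from .io_core import GenomicInterval, StateSegment

logger = logging.getLogger("chromnet")


class BroadState(str, Enum):
    STRONG = "StrongActivity"
    WEAK = "WeakActivity"
    POISED = "Poised"
    REPRESSED = "Repressed"


#: Deterministic tie-break priority: most informative labels first.
TIE_PRIORITY = (
    BroadState.STRONG,
    BroadState.POISED,
    BroadState.WEAK,
    BroadState.REPRESSED,
)

#: Default collapse of the 15-state vocabulary into the four broad classes.
#: Active promoter and strong enhancers carry full active-mark signatures;
#: weak promoter/enhancers carry moderate ones; the poised (bivalent)
#: promoter keeps its own class; everything else — Polycomb-repressed,
#: heterochromatin/low signal, insulator, the transcription-associated
#: states and repetitive/CNV — lacks promoter-activity marks and is
#: grouped as repressed.  Override via a YAML map where needed.
DEFAULT_STATE_MAP: dict[str, str] = {
    "Active promoter": BroadState.STRONG.value,
    "Strong enhancer": BroadState.STRONG.value,
    "Weak promoter": BroadState.WEAK.value,
    "Weak enhancer": BroadState.WEAK.value,
    "Poised promoter": BroadState.POISED.value,
    "Insulator": BroadState.REPRESSED.value,
    "Txn transition": BroadState.REPRESSED.value,
    "Txn elongation": BroadState.REPRESSED.value,
    "Weak txn": BroadState.REPRESSED.value,
    "Polycomb repressed": BroadState.REPRESSED.value,
    "Heterochromatin/low signal": BroadState.REPRESSED.value,
    "Repetitive/CNV": BroadState.REPRESSED.value,
    # identity entries so broad-label segmentations pass through unchanged
    BroadState.STRONG.value: BroadState.STRONG.value,
    BroadState.WEAK.value: BroadState.WEAK.value,
    BroadState.POISED.value: BroadState.POISED.value,
    BroadState.REPRESSED.value: BroadState.REPRESSED.value,
}


def fold_enrichment(a_s: int, b: int, c_s: int, d: int) -> float:
    """Base-level fold enrichment ``(a_s/b) / (c_s/d)``.

    Returns 0 when the promoter carries no bases of the state.  Scale
    invariant: multiplying (a_s, b) or (c_s, d) by a common factor does
    not change the value.
    """
    if b <= 0:
        raise ValueError("promoter length b must be positive")
    if c_s <= 0:
        raise ValueError("genome-wide state total c_s must be positive")
    if a_s == 0:
        return 0.0
    return (a_s / b) / (c_s / d)


def genome_state_totals(segments: Iterable[StateSegment]) -> dict[BroadState, int]:
    """Genome-wide base counts per broad state over a segmentation."""
    totals = {s: 0 for s in BroadState}
    for seg in segments:
        totals[BroadState(seg.broad_label)] += len(seg.interval)
    return totals


def promoter_state_bases(
    promoter: GenomicInterval, segments: Iterable[StateSegment]
) -> dict[BroadState, int]:
    """Per-broad-state overlap (in bases) between a promoter and segments."""
    bases = {s: 0 for s in BroadState}
    for seg in segments:
        iv = seg.interval
        if iv.chrom != promoter.chrom:
            continue
        ov = min(iv.end, promoter.end) - max(iv.start, promoter.start)
        if ov > 0:
            bases[BroadState(seg.broad_label)] += ov
    return bases


def assign_gene_state(
    promoter: GenomicInterval,
    segments: Iterable[StateSegment],
    genome_totals: Mapping[BroadState, int],
) -> BroadState:
    """Assign a promoter the broad state with maximum fold enrichment.

    Ties are broken by a fixed priority (strong > poised > weak >
    repressed).  A promoter overlapping no segment is labeled repressed
    (low signal) with a warning.  States with a zero genome-wide total
    are skipped (enrichment undefined).
    """
    bases = promoter_state_bases(promoter, segments)
    b = len(promoter)
    d = sum(genome_totals.values())
    best: BroadState | None = None
    best_fe = 0.0
    for state in TIE_PRIORITY:
        c_s = genome_totals.get(state, 0)
        if c_s <= 0:
            if bases[state]:
                logger.warning(
                    "state %s has zero genome-wide bases; skipped", state.value
                )
            continue
        fe = fold_enrichment(bases[state], b, c_s, d)
        if best is None or fe > best_fe:
            best, best_fe = state, fe
    if best is None or best_fe == 0.0:
        logger.warning(
            "promoter %s:%d-%d overlaps no segment; labeled Repressed",
            promoter.chrom, promoter.start, promoter.end,
        )
        return BroadState.REPRESSED
    return best


def annotate_genes(
    promoters: Mapping[str, GenomicInterval],
    segments: Iterable[StateSegment],
    genome_totals: Mapping[BroadState, int] | None = None,
) -> dict[str, BroadState]:
    """Assign a broad state to every promoter in one pass.

    Segments are bucketed by chromosome once so the per-promoter scan
    stays linear in local segment count.
    """
    segs = list(segments)
    if genome_totals is None:
        genome_totals = genome_state_totals(segs)
    by_chrom: dict[str, list[StateSegment]] = {}
    for s in segs:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    out = {}
    for gid, prom in promoters.items():
        out[gid] = assign_gene_state(
            prom, by_chrom.get(prom.chrom, ()), genome_totals
        )
    return out


def annotate_network(
    net: nx.DiGraph,
    gene_states: Mapping[str, BroadState | str],
    missing_policy: str = "error",
) -> nx.DiGraph:
    """Attach ``broad_state`` to every node of a regulatory network.

    ``missing_policy``: 'error' raises listing the unlabeled nodes;
    'drop' removes them (and incident edges) with a log message.
    """
    labeled = net.copy()
    missing = [n for n in labeled.nodes if n not in gene_states]
    if missing:
        if missing_policy == "drop":
            logger.info("dropping %d unlabeled nodes", len(missing))
            labeled.remove_nodes_from(missing)
        else:
            raise KeyError(f"nodes without a chromatin state: {sorted(missing)[:20]}")
    for n in labeled.nodes:
        labeled.nodes[n]["broad_state"] = BroadState(gene_states[n])
    return labeled
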