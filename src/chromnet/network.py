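"""Build a directed TF→target regulatory network from ChIP-seq peaks.

The pipeline: 40-bp windows centered on peak summits become candidate
binding sites; sites are kept only where they fall in open chromatin
(DNase I hypersensitive sites); a TF gains an edge to a gene when at
least one of its retained sites overlaps the gene's promoter (1 kb
around the TSS by default).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
from intervaltree import IntervalTree

from .io_core import GeneModel, GenomicInterval, PeakRecord

logger = logging.getLogger("chromnet")


def peaks_to_tfbs(
    peaks: Iterable[PeakRecord], width: int = 40
) -> list[GenomicInterval]:
    """Binding sites as ``width``-bp windows centered on peak summits.

    Each window is ``[summit - width/2, summit + width/2)``, clipped at
    the chromosome origin.
    """
    if width < 2 or width % 2:
        raise ValueError("width must be an even integer >= 2")
    half = width // 2
    out = []
    for p in peaks:
        start = max(0, p.summit - half)
        out.append(GenomicInterval(p.interval.chrom, start, p.summit + half))
    return out


def _build_trees(
    intervals: Iterable[GenomicInterval],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def filter_by_dhs(
    tfbs: Sequence[GenomicInterval],
    dhs: Iterable[GenomicInterval],
    containment: bool = False,
) -> list[GenomicInterval]:
    """Keep binding sites lying in open chromatin.

    Default rule: >= 1 bp overlap with any DHS; with ``containment`` the
    site must fall entirely inside one DHS.  Input order is preserved.
    """
    trees = _build_trees(dhs)
    kept = []
    for iv in tfbs:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = tree.overlap(iv.start, iv.end)
        if not hits:
            continue
        if containment and not any(
            h.begin <= iv.start and iv.end <= h.end for h in hits
        ):
            continue
        kept.append(iv)
    return kept


def promoter_of(
    gene: GeneModel, up: int = 500, down: int = 500
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at 0.

    '+' strand: ``[tss - up, tss + down)``; '-' strand the roles of up
    and down are mirrored.
    """
    tss = gene.tss.start
    if gene.tss.strand == "-":
        start, end = tss - down, tss + up
    else:
        start, end = tss - up, tss + down
    return GenomicInterval(gene.tss.chrom, max(0, start), end)


def build_network(
    tfbs_by_tf: Mapping[str, Sequence[GenomicInterval]],
    genes: Sequence[GeneModel],
    up: int = 500,
    down: int = 500,
    containment: bool = False,
) -> nx.DiGraph:
    """Directed TF→target graph from DHS-filtered binding sites.

    An edge (tf, g) exists iff >= 1 binding site of the TF overlaps the
    promoter of g by >= 1 bp (full containment with ``containment``).
    Node attribute ``is_tf`` marks sources; a TF absent from the
    annotation is still emitted with a warning.
    """
    known = {g.gene_id for g in genes}
    net = nx.DiGraph()
    prom_trees: dict[str, IntervalTree] = {}
    prom_span: dict[str, tuple[int, int]] = {}
    for g in genes:
        prom = promoter_of(g, up, down)
        prom_trees.setdefault(prom.chrom, IntervalTree()).addi(
            prom.start, prom.end, g.gene_id
        )
        prom_span[g.gene_id] = (prom.start, prom.end)

    for tf, sites in tfbs_by_tf.items():
        if tf not in known:
            logger.warning("TF %s not in gene annotation; edges still emitted", tf)
        for iv in sites:
            tree = prom_trees.get(iv.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(iv.start, iv.end):
                if containment and not (
                    hit.begin <= iv.start and iv.end <= hit.end
                ):
                    continue
                target = hit.data
                if not net.has_node(target):
                    net.add_node(target, is_tf=False)
                net.add_edge(tf, target)
                net.nodes[tf]["is_tf"] = True

    for g in genes:
        if net.has_node(g.gene_id) and g.is_tf:
            net.nodes[g.gene_id]["is_tf"] = True
    for n in net.nodes:
        net.nodes[n].setdefault("is_tf", False)
    return net


def network_from_edges(
    edges: Iterable[tuple[str, str]],
    tf_ids: Iterable[str] | None = None,
) -> nx.DiGraph:
    """Assemble a network directly from an edge list (edge sources are TFs)."""
    net = nx.DiGraph()
    net.add_edges_from(edges)
    tfs = set(tf_ids) if tf_ids is not None else {u for u, _ in net.edges}
    for n in net.nodes:
        net.nodes[n]["is_tf"] = n in tfs or net.out_degree(n) > 0
    return net
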