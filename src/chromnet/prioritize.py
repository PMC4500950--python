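"""Candidate-gene prioritization from FFL state and structure changes.

Each FFL instance tracked between two conditions contributes, for each
of its three components, a state-change score from a 4x4 matrix:
activation (strong/weak activity) <-> repression (poised/repressed)
scores 10; poised <-> repressed scores 5; strong <-> weak scores 3;
unchanged states score 0.  An instance whose structure changed (edge
gain or loss) adds a flat 5.  A gene's summary score sums the scores of
every instance it appears in, at any position; genes are ranked by
summary score, descending.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .comparative import FFLComparison
from .stats import EnrichmentQuery, hypergeom_enrichment
from .states import BroadState

logger = logging.getLogger("chromnet")

_ACTIVATION = {BroadState.STRONG.value, BroadState.WEAK.value}
_REPRESSION = {BroadState.POISED.value, BroadState.REPRESSED.value}


def _default_matrix() -> dict[tuple[str, str], float]:
    m: dict[tuple[str, str], float] = {}
    states = [s.value for s in BroadState]
    for a in states:
        for b in states:
            if a == b:
                score = 0.0
            elif (a in _ACTIVATION) != (b in _ACTIVATION):
                score = 10.0
            elif a in _REPRESSION:  # poised <-> repressed
                score = 5.0
            else:  # strong <-> weak
                score = 3.0
            m[(a, b)] = score
    return m


@dataclass
class StateChangeScoreMatrix:
    """Symmetric 4x4 state-change scores plus the flat structure score."""

    entries: dict[tuple[str, str], float] = field(default_factory=_default_matrix)
    structural_change_score: float = 5.0

    def __post_init__(self):
        for (a, b), v in self.entries.items():
            if self.entries.get((b, a)) != v:
                raise ValueError(f"matrix not symmetric at ({a}, {b})")
            if a == b and v != 0:
                raise ValueError("diagonal entries must be 0")

    def score(self, src: str | BroadState, end: str | BroadState) -> float:
        src = src.value if isinstance(src, BroadState) else str(src)
        end = end.value if isinstance(end, BroadState) else str(end)
        return self.entries[(src, end)]

    def scaled(self, factor: float) -> "StateChangeScoreMatrix":
        return StateChangeScoreMatrix(
            {k: v * factor for k, v in self.entries.items()},
            self.structural_change_score * factor,
        )

    @classmethod
    def from_yaml(cls, path) -> "StateChangeScoreMatrix":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        entries = {}
        for a, row in data["state_change"].items():
            for b, v in row.items():
                entries[(a, b)] = float(v)
        return cls(entries, float(data.get("structural_change_score", 5.0)))


def score_instance(cmp: FFLComparison, mat: StateChangeScoreMatrix) -> float:
    """Score one tracked FFL instance: per-component state change plus a
    flat structure-change term."""
    if not cmp.has_states:
        raise ValueError("instance lacks states in one condition")
    total = sum(
        mat.score(a, b) for a, b in zip(cmp.states_source, cmp.states_end)
    )
    if cmp.change_group != "no_change":
        total += mat.structural_change_score
    return total


@dataclass
class GeneScoreRecord:
    gene_id: str
    n_instances: int
    summary_score: float
    rank: int
    percentile: float
    is_source_node: bool = False


def rank_genes(
    comparisons: Sequence[FFLComparison],
    mat: StateChangeScoreMatrix | None = None,
    source_nodes: set[str] | None = None,
) -> list[GeneScoreRecord]:
    """Summary scores and ranks for every gene appearing in an FFL.

    Instances are deduplicated by (top, mid, target) before summing so a
    triple extracted from both conditions is scored once.  Instances
    without states in both conditions are skipped with a log message.
    Ranks are dense min-ranks over descending scores; ties share a rank
    and are ordered by gene id in the output.
    """
    if mat is None:
        mat = StateChangeScoreMatrix()
    source_nodes = source_nodes or set()
    seen: dict[tuple[str, str, str], FFLComparison] = {}
    for c in comparisons:
        seen.setdefault((c.top, c.mid, c.target), c)

    totals: dict[str, float] = {}
    counts: dict[str, int] = {}
    n_skipped = 0
    for c in seen.values():
        for g in (c.top, c.mid, c.target):
            totals.setdefault(g, 0.0)
            counts.setdefault(g, 0)
        if not c.has_states:
            n_skipped += 1
            continue
        s = score_instance(c, mat)
        for g in (c.top, c.mid, c.target):
            totals[g] += s
            counts[g] += 1
    if n_skipped:
        logger.info("skipped %d instances lacking states", n_skipped)

    genes = sorted(totals, key=lambda g: (-totals[g], g))
    n = len(genes)
    records = []
    rank = 0
    prev_score = None
    for i, g in enumerate(genes):
        if totals[g] != prev_score:
            rank = i + 1
            prev_score = totals[g]
        records.append(
            GeneScoreRecord(
                gene_id=g,
                n_instances=counts[g],
                summary_score=totals[g],
                rank=rank,
                percentile=100.0 * (1.0 - (rank - 1) / n),
                is_source_node=g in source_nodes,
            )
        )
    return records


def top_fraction_enrichment(
    records: Sequence[GeneScoreRecord],
    gene_set: set[str],
    fraction: float = 0.01,
) -> tuple[float, EnrichmentQuery, list[str]]:
    """Hypergeometric enrichment of a gene set in the top-ranked fraction.

    The query is the ceil(fraction * n) top-ranked genes; the background
    is the whole candidate universe.  Returns (P, query setup, top genes).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    ordered = sorted(records, key=lambda r: (r.rank, r.gene_id))
    n = len(ordered)
    top_n = math.ceil(fraction * n)
    top = [r.gene_id for r in ordered[:top_n]]
    universe = {r.gene_id for r in ordered}
    hits = gene_set & universe
    if not hits:
        logger.warning("gene set shares no genes with the candidate universe")
        q = EnrichmentQuery(n, 0, top_n, 0)
        return 1.0, q, top
    k = len(set(top) & hits)
    q = EnrichmentQuery(n, len(hits), top_n, k)
    return hypergeom_enrichment(q), q, top


def gene_scores_table(records: Iterable[GeneScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene_id,
                "n_instances": r.n_instances,
                "summary_score": r.summary_score,
                "rank": r.rank,
                "percentile": r.percentile,
                "is_source_node": r.is_source_node,
            }
            for r in records
        ]
    )
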