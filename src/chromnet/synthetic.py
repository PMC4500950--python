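"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the inputs of a promoter-centric ChIP-seq
regulatory-network study: a directed TF→target graph with heavy-tailed
out-degrees, peaks whose 40-bp summit windows fall inside the target's
promoter and inside a DNase hypersensitive site, a chromatin-state
segmentation that covers each promoter with the gene's planted broad
state, planted over-represented colored feedforward loops on dedicated
nodes, planted state transitions and edge changes between two
conditions, and expression stratified by state (strong > weak > poised
> repressed, as observed for promoter chromatin classes).

Every bundle carries truth tables (planted edges, states, motif
instances, per-condition changes) so downstream recovery is checkable
exactly.  Same seed ⇒ byte-identical bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .io_core import (
    GeneModel,
    GenomicInterval,
    PeakRecord,
    StateSegment,
    write_bed,
    write_genes,
    write_peaks,
    write_segmentation,
)
from .states import BroadState

logger = logging.getLogger("chromnet")

_STATES = [s.value for s in BroadState]

#: feedforward loop: position 0 regulates 1 and 2, 1 regulates 2
FFL_EDGES = ((0, 1), (0, 2), (1, 2))


@dataclass(frozen=True)
class PlantedMotif:
    """Copies of one colored structure embedded on dedicated nodes."""

    states: tuple[str, str, str]
    copies: int
    edges: tuple[tuple[int, int], ...] = FFL_EDGES

    def __post_init__(self):
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        for s in self.states:
            BroadState(s)


@dataclass(frozen=True)
class TransitionRule:
    """Planted state flip at one FFL position between two conditions."""

    position: str  # top | intermediate | bottom
    from_state: str
    to_state: str
    rate: float

    def __post_init__(self):
        if self.position not in ("top", "intermediate", "bottom"):
            raise ValueError(f"bad position {self.position!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate {self.rate} outside [0, 1]")


@dataclass
class SimSpec:
    """Parameters of one synthetic study condition (or condition pair)."""

    n_tfs: int = 60
    n_genes: int = 600  # total genes, TFs included
    degree_exponent: float = 2.0  # power-law target for background out-degrees
    max_out_degree: int = 50
    state_frequencies: tuple[float, float, float, float] = (0.35, 0.25, 0.15, 0.25)
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    transition_rules: list[TransitionRule] = field(default_factory=list)
    edge_loss_rate: float = 0.0  # planted FFLs losing one edge in condition B
    edge_gain_rate: float = 0.0  # planted FFLs missing one edge in condition A
    background_flip_rate: float = 0.0  # background genes changing state in B
    #: per-state (mean, sd) of log2 expression; ordering mirrors the
    #: expression gradient across promoter chromatin classes
    expression_by_state: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "StrongActivity": (8.0, 1.0),
            "WeakActivity": (6.0, 1.0),
            "Poised": (4.0, 1.0),
            "Repressed": (3.0, 1.0),
        }
    )
    n_decoy_peaks: int = 20  # peaks outside open chromatin, per condition
    gene_spacing_bp: int = 2000
    promoter_half_bp: int = 500
    genome_length: int | None = None  # default: computed to fit all promoters
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.state_frequencies) - 1.0) > 1e-9:
            raise ValueError("state_frequencies must sum to 1")
        n_planted = sum(m.copies for m in self.planted_motifs)
        if self.n_tfs < 2 * n_planted + 1:
            raise ValueError(
                f"n_tfs={self.n_tfs} too small for {n_planted} planted motifs"
            )
        if self.n_genes < self.n_tfs + n_planted + 5:
            raise ValueError("n_genes too small for the requested layout")
        needed = self.n_genes * self.gene_spacing_bp + self.gene_spacing_bp
        if self.genome_length is not None and self.genome_length < needed:
            raise ValueError(
                f"genome_length {self.genome_length} cannot place "
                f"{self.n_genes} disjoint promoters (need {needed})"
            )


@dataclass
class ConditionBundle:
    """In-memory synthetic inputs for one condition, plus ground truth."""

    genes: list[GeneModel]
    peaks_by_tf: dict[str, list[PeakRecord]]
    dhs: list[GenomicInterval]
    segments: list[StateSegment]
    expression: pd.Series
    true_edges: set[tuple[str, str]]
    true_states: dict[str, str]
    true_motifs: list[dict]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genes(self.genes, outdir / "genes.tsv")
        write_bed(self.dhs, outdir / "dhs.bed")
        write_segmentation(self.segments, outdir / "segmentation.bed")
        for tf, peaks in sorted(self.peaks_by_tf.items()):
            write_peaks(peaks, outdir / f"peaks_{tf}.narrowPeak")
        self.expression.rename("expression").to_frame().to_csv(
            outdir / "expression.tsv", sep="\t", index_label="gene"
        )
        pd.DataFrame(sorted(self.true_edges), columns=["tf", "target"]).to_csv(
            outdir / "truth_edges.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            sorted(self.true_states.items()), columns=["gene", "state"]
        ).to_csv(outdir / "truth_states.tsv", sep="\t", index=False)
        pd.DataFrame(self.true_motifs).to_csv(
            outdir / "truth_motifs.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# layout helpers


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _tss_of(i: int, spec: SimSpec) -> int:
    return i * spec.gene_spacing_bp + spec.gene_spacing_bp // 2


def _promoter_of(i: int, spec: SimSpec) -> tuple[int, int]:
    tss = _tss_of(i, spec)
    return tss - spec.promoter_half_bp, tss + spec.promoter_half_bp


def _plan_layout(spec: SimSpec, rng: np.random.Generator):
    """Assign roles, planted motif node triples, states and edges."""
    ids = _gene_ids(spec.n_genes)
    n_planted = sum(m.copies for m in spec.planted_motifs)
    tf_ids = set(ids[: spec.n_tfs])

    states: dict[str, str] = {}
    motifs: list[dict] = []
    edges: set[tuple[str, str]] = set()

    # dedicated planted nodes: TFs from the front, targets after the TFs
    tf_cursor = 0
    target_cursor = spec.n_tfs
    for m in spec.planted_motifs:
        for _ in range(m.copies):
            trio = [ids[tf_cursor], ids[tf_cursor + 1], ids[target_cursor]]
            tf_cursor += 2
            target_cursor += 1
            for pos, s in zip(trio, m.states):
                states[pos] = s
            for a, b in m.edges:
                edges.add((trio[a], trio[b]))
            motifs.append(
                {
                    "top": trio[0],
                    "mid": trio[1],
                    "target": trio[2],
                    "states": ",".join(m.states),
                }
            )

    # background states from the configured frequencies
    bg_genes = [g for g in ids if g not in states]
    drawn = rng.choice(len(_STATES), size=len(bg_genes), p=spec.state_frequencies)
    for g, si in zip(bg_genes, drawn):
        states[g] = _STATES[si]

    # background scale-free-ish out-degrees on the remaining TFs
    bg_tfs = [ids[i] for i in range(tf_cursor, spec.n_tfs)]
    bg_targets = [ids[i] for i in range(target_cursor, spec.n_genes)]
    if bg_tfs and bg_targets:
        degrees = np.minimum(
            rng.zipf(spec.degree_exponent, size=len(bg_tfs)),
            min(spec.max_out_degree, len(bg_targets)),
        )
        for tf, d in zip(bg_tfs, degrees):
            targets = rng.choice(len(bg_targets), size=int(d), replace=False)
            for t in targets:
                if bg_targets[t] != tf:
                    edges.add((tf, bg_targets[t]))
    return ids, tf_ids, states, edges, motifs


def _make_bundle(
    spec: SimSpec,
    ids: list[str],
    tf_ids: set[str],
    states: dict[str, str],
    edges: set[tuple[str, str]],
    motifs: list[dict],
    rng: np.random.Generator,
) -> ConditionBundle:
    genes = []
    for i, g in enumerate(ids):
        tss = _tss_of(i, spec)
        genes.append(
            GeneModel(
                g, GenomicInterval(spec.chrom, tss, tss + 1, "+"), g in tf_ids
            )
        )
    idx = {g: i for i, g in enumerate(ids)}

    # one DHS per promoter; decoy peaks fall strictly between them
    dhs = [
        GenomicInterval(spec.chrom, *_promoter_of(i, spec))
        for i in range(len(ids))
    ]

    peaks_by_tf: dict[str, list[PeakRecord]] = {tf: [] for tf in sorted(tf_ids)}
    for tf, target in sorted(edges):
        tss = _tss_of(idx[target], spec)
        peaks_by_tf[tf].append(
            PeakRecord(GenomicInterval(spec.chrom, tss - 100, tss + 100), 100, tf)
        )
    # decoys: summits in the inter-promoter gaps, outside every DHS
    tf_list = sorted(tf_ids)
    for k in range(spec.n_decoy_peaks):
        i = int(rng.integers(0, len(ids) - 1))
        pos = i * spec.gene_spacing_bp + spec.gene_spacing_bp - 200
        tf = tf_list[int(rng.integers(0, len(tf_list)))]
        peaks_by_tf[tf].append(
            PeakRecord(GenomicInterval(spec.chrom, pos - 50, pos + 50), 50, tf)
        )

    # segmentation: promoters covered by the planted state; gaps filled
    # with cycling states so every broad state has genome-wide mass
    segments = []
    for i, g in enumerate(ids):
        lo, hi = _promoter_of(i, spec)
        segments.append(
            StateSegment(
                GenomicInterval(spec.chrom, lo, hi), states[g], states[g]
            )
        )
        gap_lo, gap_hi = hi, lo + spec.gene_spacing_bp
        filler = _STATES[i % len(_STATES)]
        segments.append(
            StateSegment(GenomicInterval(spec.chrom, gap_lo, gap_hi), filler, filler)
        )

    means = {s: spec.expression_by_state[s] for s in _STATES}
    log_expr = np.array(
        [rng.normal(*means[states[g]]) for g in ids], dtype=float
    )
    expression = pd.Series(np.round(log_expr, 4), index=ids, name="expression")

    return ConditionBundle(
        genes=genes,
        peaks_by_tf=peaks_by_tf,
        dhs=dhs,
        segments=segments,
        expression=expression,
        true_edges=set(edges),
        true_states=dict(states),
        true_motifs=list(motifs),
    )


def simulate_condition(spec: SimSpec) -> ConditionBundle:
    """One synthetic condition: files' worth of inputs plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    ids, tf_ids, states, edges, motifs = _plan_layout(spec, rng)
    return _make_bundle(spec, ids, tf_ids, states, edges, motifs, rng)


def simulate_pair(
    spec: SimSpec,
) -> tuple[ConditionBundle, ConditionBundle, pd.DataFrame]:
    """Two conditions differing by planted state flips and edge changes.

    Per planted FFL, at most one structural change is drawn: with
    ``edge_loss_rate`` one random edge is absent in condition B; with
    ``edge_gain_rate`` one random edge is absent in condition A (so the
    full FFL appears only in B).  Each transition rule flips the state
    of the gene at its FFL position (when it carries ``from_state`` in
    A) with the given rate; background genes flip to a random other
    state with ``background_flip_rate``.  The returned table records
    every planted change.
    """
    if spec.edge_loss_rate + spec.edge_gain_rate > 1.0:
        raise ValueError("edge_loss_rate + edge_gain_rate must be <= 1")
    rng = np.random.default_rng(spec.seed)
    ids, tf_ids, states_A, edges_full, motifs = _plan_layout(spec, rng)

    pos_key = {"top": "top", "intermediate": "mid", "bottom": "target"}
    changes: list[dict] = []

    # structural changes per planted FFL
    edges_A = set(edges_full)
    edges_B = set(edges_full)
    motif_edges = lambda m: [  # noqa: E731 - local shorthand
        (m["top"], m["mid"]), (m["top"], m["target"]), (m["mid"], m["target"])
    ]
    for m in motifs:
        u = rng.random()
        removed = motif_edges(m)[int(rng.integers(0, 3))]
        if u < spec.edge_loss_rate:
            edges_B.discard(removed)
            m["structure_change"] = "edge_loss"
            changes.append(
                {"kind": "edge_loss", "gene": "", "ffl_top": m["top"],
                 "detail": f"{removed[0]}->{removed[1]}"}
            )
        elif u < spec.edge_loss_rate + spec.edge_gain_rate:
            edges_A.discard(removed)
            m["structure_change"] = "edge_gain"
            changes.append(
                {"kind": "edge_gain", "gene": "", "ffl_top": m["top"],
                 "detail": f"{removed[0]}->{removed[1]}"}
            )
        else:
            m["structure_change"] = "no_change"

    # state flips
    states_B = dict(states_A)
    ruled_genes = set()
    for rule in spec.transition_rules:
        key = pos_key[rule.position]
        for m in motifs:
            g = m[key]
            if states_A[g] == rule.from_state and g not in ruled_genes:
                if rng.random() < rule.rate:
                    states_B[g] = rule.to_state
                    ruled_genes.add(g)
                    changes.append(
                        {"kind": "state_flip", "gene": g, "ffl_top": m["top"],
                         "detail": f"{rule.from_state}->{rule.to_state}"}
                    )
    if spec.background_flip_rate > 0:
        motif_genes = {
            g for m in motifs for g in (m["top"], m["mid"], m["target"])
        }
        for g in ids:
            if g in motif_genes or g in ruled_genes:
                continue
            if rng.random() < spec.background_flip_rate:
                others = [s for s in _STATES if s != states_A[g]]
                states_B[g] = others[int(rng.integers(0, len(others)))]
                changes.append(
                    {"kind": "state_flip", "gene": g, "ffl_top": "",
                     "detail": f"{states_A[g]}->{states_B[g]}"}
                )

    bundle_A = _make_bundle(
        spec, ids, tf_ids, states_A, edges_A, motifs, np.random.default_rng(rng.integers(2**31))
    )
    bundle_B = _make_bundle(
        spec, ids, tf_ids, states_B, edges_B, motifs, np.random.default_rng(rng.integers(2**31))
    )
    truth = pd.DataFrame(changes, columns=["kind", "gene", "ffl_top", "detail"])
    return bundle_A, bundle_B, truth
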