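"""Stage orchestration: run the whole analysis from a manifest of inputs.

A manifest names, per cell condition, the peak files (one per TF), the
DHS intervals, the genome segmentation, the gene annotation and the
expression table.  With one condition the pipeline stops after motif
discovery; with two it also runs the between-condition comparison, the
state-transition test and gene prioritization.  All stage outputs are
tab-delimited tables with headers; the log records the seed, parameter
values and per-stage record counts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import comparative as cmp_mod
from . import motifs as motif_mod
from . import network as net_mod
from . import prioritize as prio_mod
from .io_core import (
    PipelineConfig,
    read_dhs,
    read_expression,
    read_genes,
    read_peaks,
    read_segmentation,
    write_edge_list,
    write_gene_states,
    write_table,
)
from .states import (
    DEFAULT_STATE_MAP,
    annotate_genes,
    annotate_network,
)

logger = logging.getLogger("chromnet")


def load_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if "conditions" not in manifest or not manifest["conditions"]:
        raise ValueError("manifest must name at least one condition")
    return manifest


def _check_inputs(manifest: Mapping) -> None:
    """Fail on any missing file before any compute starts."""
    missing = []
    for name, cond in manifest["conditions"].items():
        for key in ("dhs", "segmentation", "genes", "expression"):
            p = cond.get(key)
            if p is None or not Path(p).exists():
                missing.append(f"{name}.{key}: {p}")
        for tf, p in (cond.get("peaks") or {}).items():
            if not Path(p).exists():
                missing.append(f"{name}.peaks.{tf}: {p}")
    if missing:
        raise FileNotFoundError("missing inputs:\n  " + "\n  ".join(missing))


def _condition_stage(name, cond, config, outdir, rng):
    vocab = config.state_vocabulary_map or DEFAULT_STATE_MAP
    genes = read_genes(cond["genes"])
    dhs = read_dhs(cond["dhs"])
    segments = read_segmentation(cond["segmentation"], vocab)

    tfbs_by_tf = {}
    for tf, path in sorted((cond.get("peaks") or {}).items()):
        peaks = read_peaks(path, tf)
        tfbs = net_mod.peaks_to_tfbs(peaks, config.tfbs_width_bp)
        tfbs_by_tf[tf] = net_mod.filter_by_dhs(tfbs, dhs)
    net = net_mod.build_network(
        tfbs_by_tf, genes, config.promoter_up_bp, config.promoter_down_bp
    )
    logger.info("[%s] network: %d nodes, %d edges", name,
                net.number_of_nodes(), net.number_of_edges())
    write_edge_list(net.edges(), outdir / f"{name}.edges.tsv")

    promoters = {
        g.gene_id: net_mod.promoter_of(
            g, config.promoter_up_bp, config.promoter_down_bp
        )
        for g in genes
    }
    gene_states = annotate_genes(promoters, segments)
    write_gene_states(
        {g: s.value for g, s in gene_states.items()},
        outdir / f"{name}.gene_states.tsv",
    )
    labeled = annotate_network(net, gene_states)

    stats = motif_mod.find_significant_motifs(
        labeled,
        n_random=config.n_random_networks,
        alpha=config.significance_alpha,
        rng=rng,
        swap_factor=config.swap_factor,
    )
    table = motif_mod.motif_stats_table(stats)
    write_table(table, outdir / f"{name}.motif_stats.tsv")
    logger.info("[%s] %d colored classes, %d significant", name,
                len(table), int(table["significant"].sum()) if len(table) else 0)
    return labeled, gene_states, read_expression(cond["expression"])


def run_pipeline(
    config: PipelineConfig, manifest: Mapping, outdir: str | Path
) -> Path:
    """Run every applicable stage; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_inputs(manifest)
    logger.info("seed=%d promoter=%d+%d tfbs=%d n_random=%d",
                config.rng_seed, config.promoter_up_bp,
                config.promoter_down_bp, config.tfbs_width_bp,
                config.n_random_networks)
    root = np.random.default_rng(config.rng_seed)
    # one independent child stream per stochastic stage
    streams = {k: np.random.default_rng(s) for k, s in zip(
        ("motifs", "transitions", "exclusivity"),
        root.integers(0, 2**31, size=3),
    )}

    results = {}
    for name, cond in manifest["conditions"].items():
        results[name] = _condition_stage(
            name, cond, config, outdir, streams["motifs"]
        )

    names = list(results)
    if len(names) < 2:
        logger.info("single condition: comparative and prioritizer stages skipped")
        return outdir

    (net_A, states_A, _), (net_B, states_B, _) = results[names[0]], results[names[1]]
    comparisons = cmp_mod.compare_ffls(net_A, net_B, states_A, states_B)
    write_table(
        cmp_mod.comparisons_table(comparisons),
        outdir / f"{names[0]}_vs_{names[1]}.comparisons.tsv",
    )
    transitions = cmp_mod.transition_test(
        comparisons, net_A, states_A, states_B,
        n_perm=config.n_transition_perms, rng=streams["transitions"],
    )
    write_table(
        cmp_mod.transitions_table(transitions),
        outdir / f"{names[0]}_vs_{names[1]}.transitions.tsv",
    )
    source_nodes = {n for n in net_A.nodes if net_A.out_degree(n) > 0} | {
        n for n in net_B.nodes if net_B.out_degree(n) > 0
    }
    records = prio_mod.rank_genes(comparisons, source_nodes=source_nodes)
    write_table(
        prio_mod.gene_scores_table(records),
        outdir / f"{names[0]}_vs_{names[1]}.gene_scores.tsv",
    )
    logger.info("comparative: %d FFL comparisons, %d ranked genes",
                len(comparisons), len(records))
    return outdir
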