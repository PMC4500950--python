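# chromnet

Chromatin-state-modified transcriptional regulatory network analysis.

Transcription-factor (TF) regulatory networks are usually studied as bare
directed graphs, but the genes inside them sit in very different chromatin
environments: an active promoter, a weakly active one, a bivalent (poised)
promoter carrying both H3K4me3 and H3K27me3, or repressed/low-signal
chromatin. `chromnet` treats the chromatin state of each gene's promoter as
a *color* on the network node and asks which colored wiring patterns —
especially feedforward loops (FFLs) — are over-represented, how their colors
and wiring change between two cell conditions, and which genes concentrate
those changes. It is aimed at computational biologists working with
ChIP-seq-derived regulatory networks and genome chromatin-state
segmentations.

## What it computes

**Network construction.** Peaks are reduced to 40-bp windows centered on
their summits, kept only where they fall in DNase I hypersensitive sites,
and a TF gains an edge to a gene when a retained window overlaps the gene's
promoter (1 kb around the TSS: 0.5 kb upstream, 0.5 kb downstream).

**Promoter state by fold enrichment.** A genome segmentation (a 15-state
vocabulary collapsed to 4 broad classes, or broad labels directly) gives,
for each broad state *s*, the promoter base count *aₛ*, promoter length
*b*, genome-wide state total *cₛ*, and total marked bases *d*. Each gene
gets the state maximizing

    FE(s) = (aₛ / b) / (cₛ / d)

so rare-but-informative states (e.g. poised) are not swamped by blanket
abundance.

**Colored motif discovery.** All weakly connected induced 3-node subgraphs
(13 structures up to isomorphism) are counted jointly with their state
coloring, canonical under the structure's automorphisms. Significance of
each colored class is assessed against randomized networks built by
constrained double-edge swaps that preserve every node's in-/out-degree,
every TF's per-state target counts, and the mutual-dyad census. A class is
significant when its empirical P (fraction of randomized networks with at
least the real count, 500 replicates by default) is below 0.05 **and**
N_real − N_rand > 0.05 · N_rand.

**Cross-cutting statistics.** Mutual exclusivity of state compositions
across structures (S_M = fraction of compositions coupled to exactly one
structure, tested by 10,000 within-column permutations), Wilcoxon rank-sum
comparisons of target expression between colored FFL classes,
hypergeometric gene-set enrichment with Benjamini–Hochberg FDR, and a
cell-type specificity score (expression fraction, specific when > 0.85).

**Two-condition comparison and prioritization.** FFLs of a source condition
are classified by surviving edges (no change / edge loss, with edge gain
from the end condition); per-position state transitions are tested against
1,000 artificial instance sets sampled from the TF and target pools.
Finally each gene is ranked by a summary score over its FFL instances:
activation↔repression state changes score 10, poised↔repressed 5,
strong↔weak 3, plus a flat 5 per structurally changed instance.

## Worked example

The synthetic generator plants ground truth so every stage can be checked
end to end. Here 50 (Strong, Strong, Poised) FFLs are planted on a
heavy-tailed random background, the network is rebuilt from the generated
peak/DHS/annotation inputs, promoters are re-annotated from the
segmentation, and the colored census is tested against 100 randomized
networks:

```python
import numpy as np
import chromnet as cn

spec = cn.SimSpec(
    n_tfs=120, n_genes=400,
    planted_motifs=[cn.PlantedMotif(("StrongActivity", "StrongActivity", "Poised"), 50)],
    seed=7,
)
bundle = cn.simulate_condition(spec)

tfbs = {tf: cn.filter_by_dhs(cn.peaks_to_tfbs(p), bundle.dhs)
        for tf, p in bundle.peaks_by_tf.items()}
net = cn.build_network(tfbs, bundle.genes)
print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")

promoters = {g.gene_id: cn.promoter_of(g) for g in bundle.genes}
states = cn.annotate_genes(promoters, bundle.segments)
labeled = cn.annotate_network(net, states)

stats = cn.find_significant_motifs(labeled, n_random=100,
                                   rng=np.random.default_rng(7))
for s in sorted(stats, key=lambda s: s.p_emp)[:3]:
    print(f"structure={s.cls.structure} coloring={s.cls.coloring} "
          f"n_real={s.n_real} n_rand_mean={s.n_rand_mean:.2f} "
          f"p_emp={s.p_emp:.3f} significant={s.significant}")
```

Output:

```
network: 205 nodes, 189 edges
structure=11 coloring=('StrongActivity', 'StrongActivity', 'Poised') n_real=50 n_rand_mean=0.34 p_emp=0.000 significant=True
structure=10 coloring=('Repressed', 'Repressed', 'StrongActivity') n_real=1 n_rand_mean=0.06 p_emp=0.060 significant=False
structure=10 coloring=('Repressed', 'StrongActivity', 'StrongActivity') n_real=1 n_rand_mean=0.44 p_emp=0.380 significant=False
```

The planted class (structure 11 is the FFL) is recovered at its exact
planted count, appears essentially never in the state-preserving null, and
passes both significance criteria; background classes do not.

A command-line interface mirrors the library
(`chromnet build-net | annotate-states | find-motifs | exclusivity |
transitions | prioritize | simulate | run-all`), e.g.:

```bash
chromnet --seed 7 --outdir out simulate
chromnet --seed 7 --outdir out run-all --manifest manifest.yaml
```

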