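import itertools

import numpy as np
import pytest

from chromnet.comparative import FFLComparison, compare_ffls
from chromnet.network import network_from_edges
from chromnet.prioritize import (
    StateChangeScoreMatrix,
    gene_scores_table,
    rank_genes,
    score_instance,
    top_fraction_enrichment,
)

STRONG, WEAK = "StrongActivity", "WeakActivity"
POISED, REPR = "Poised", "Repressed"
STATES = [STRONG, WEAK, POISED, REPR]


def cmp_of(states_src, states_end, group="no_change", genes=("T", "M", "G")):
    return FFLComparison(
        *genes,
        change_group=group,
        edges_present_source=3,
        edges_present_end=3 if group == "no_change" else 2,
        states_source=states_src,
        states_end=states_end,
    )


def oracle_score(states_src, states_end, changed):
    """Independent lookup-table application of the published scoring rules."""
    activation = {STRONG, WEAK}
    total = 0.0
    for a, b in zip(states_src, states_end):
        if a == b:
            pass
        elif (a in activation) != (b in activation):
            total += 10
        elif {a, b} == {POISED, REPR}:
            total += 5
        else:  # {Strong, Weak}
            total += 3
    return total + (5 if changed else 0)


class TestScoreInstance:
    def test_worked_example(self):
        # top Strong->Poised (10), mid Weak->Weak (0), target Strong->Weak
        # (3), one edge lost (+5) = 18
        c = cmp_of((STRONG, WEAK, STRONG), (POISED, WEAK, WEAK), "edge_loss")
        assert score_instance(c, StateChangeScoreMatrix()) == 18

    def test_inert_instance_scores_zero(self):
        c = cmp_of((STRONG, WEAK, POISED), (STRONG, WEAK, POISED))
        assert score_instance(c, StateChangeScoreMatrix()) == 0

    def test_three_poised_repressed_transitions(self):
        c = cmp_of((POISED, POISED, POISED), (REPR, REPR, REPR))
        assert score_instance(c, StateChangeScoreMatrix()) == 15

    def test_exhaustive_lookup_oracle(self):
        """Every (state pair)^3 x {changed, unchanged} configuration matches
        an independent application of the scoring rules."""
        mat = StateChangeScoreMatrix()
        pairs = list(itertools.product(STATES, repeat=2))
        for p_top, p_mid, p_tgt in itertools.product(pairs, repeat=3):
            src = (p_top[0], p_mid[0], p_tgt[0])
            end = (p_top[1], p_mid[1], p_tgt[1])
            for group in ("no_change", "edge_loss"):
                c = cmp_of(src, end, group)
                assert score_instance(c, mat) == oracle_score(
                    src, end, group != "no_change"
                )

    def test_matrix_must_be_symmetric(self):
        bad = StateChangeScoreMatrix().entries | {(STRONG, WEAK): 7.0}
        with pytest.raises(ValueError):
            StateChangeScoreMatrix(bad)

    def test_instance_without_states_rejected(self):
        c = cmp_of(None, None)
        with pytest.raises(ValueError):
            score_instance(c, StateChangeScoreMatrix())


class TestRankGenes:
    def test_summary_is_additive_over_instances(self):
        c1 = cmp_of((STRONG, WEAK, STRONG), (POISED, WEAK, WEAK), "edge_loss")
        c2 = cmp_of(
            (POISED, POISED, POISED), (REPR, REPR, REPR),
            genes=("T", "M2", "G2"),
        )
        records = {r.gene_id: r for r in rank_genes([c1, c2])}
        assert records["T"].summary_score == 18 + 15
        assert records["M"].summary_score == 18
        assert records["G2"].summary_score == 15

    def test_duplicate_triples_counted_once(self):
        c = cmp_of((STRONG, WEAK, STRONG), (POISED, WEAK, WEAK), "edge_loss")
        once = rank_genes([c])
        twice = rank_genes([c, c])
        assert gene_scores_table(once).equals(gene_scores_table(twice))

    def test_ties_share_min_rank_with_deterministic_order(self):
        c1 = cmp_of((POISED, POISED, POISED), (REPR, REPR, REPR))
        records = rank_genes([c1])
        assert [r.gene_id for r in records] == ["G", "M", "T"]
        assert [r.rank for r in records] == [1, 1, 1]

    def test_uniform_scaling_preserves_ranks(self):
        rng = np.random.default_rng(4)
        comparisons = []
        for i in range(30):
            src = tuple(rng.choice(STATES, 3))
            end = tuple(rng.choice(STATES, 3))
            group = "edge_loss" if rng.random() < 0.3 else "no_change"
            comparisons.append(
                cmp_of(src, end, group, genes=(f"T{i}", f"M{i}", f"G{i}"))
            )
        base = rank_genes(comparisons, StateChangeScoreMatrix())
        doubled = rank_genes(comparisons, StateChangeScoreMatrix().scaled(2.0))
        assert [r.gene_id for r in base] == [r.gene_id for r in doubled]
        assert [r.rank for r in base] == [r.rank for r in doubled]
        assert all(
            d.summary_score == 2 * b.summary_score
            for b, d in zip(base, doubled)
        )

    def test_empty_comparisons_empty_output(self):
        assert rank_genes([]) == []


class TestTopFractionEnrichment:
    def _records(self, n=300, n_drivers=6, seed=0):
        """Drivers concentrate state+structure changes; background is inert
        apart from occasional mild changes."""
        rng = np.random.default_rng(seed)
        comparisons = []
        drivers = [f"drv{i}" for i in range(n_drivers)]
        for i, d in enumerate(drivers):
            for j in range(4):  # several strongly-changed instances each
                comparisons.append(
                    cmp_of(
                        (STRONG, STRONG, STRONG), (REPR, POISED, REPR),
                        "edge_loss", genes=(d, f"bgm{i}_{j}", f"bgt{i}_{j}"),
                    )
                )
        k = 0
        while len({g for c in comparisons for g in (c.top, c.mid, c.target)}) < n:
            src = tuple(rng.choice(STATES, 3))
            end = src if rng.random() < 0.7 else (src[0], src[1], rng.choice(STATES))
            comparisons.append(
                cmp_of(src, end, genes=(f"x{k}", f"y{k}", f"z{k}"))
            )
            k += 1
        return rank_genes(comparisons), set(drivers)

    def test_planted_drivers_enriched_in_top_fraction(self):
        records, drivers = self._records()
        p, q, top = top_fraction_enrichment(records, drivers, fraction=0.02)
        assert q.k >= len(drivers) - 1
        assert p < 0.01

    def test_query_of_top_genes_is_maximal(self):
        from math import comb

        records, _ = self._records()
        _, _, top = top_fraction_enrichment(records, set(), fraction=0.01)
        p, q, _ = top_fraction_enrichment(records, set(top), fraction=0.01)
        assert q.k == q.M == q.n
        assert p == pytest.approx(1 / comb(q.N, q.M), rel=1e-9)

    def test_fraction_one_rejected(self):
        records, drivers = self._records(n=50)
        with pytest.raises(ValueError):
            top_fraction_enrichment(records, drivers, fraction=1.0)

    def test_disjoint_gene_set_gives_p_one(self, caplog):
        records, _ = self._records(n=50)
        with caplog.at_level("WARNING", logger="chromnet"):
            p, _, _ = top_fraction_enrichment(records, {"absent"}, 0.05)
        assert p == 1.0

    def test_null_calibration_of_enrichment_p(self):
        """Random scores and random gene sets: P(p <= alpha) <= alpha plus
        discreteness, over repetitions."""
        rng = np.random.default_rng(8)
        hits = 0
        reps = 200
        genes = [f"g{i}" for i in range(120)]
        for _ in range(reps):
            comparisons = []
            for i in range(0, 117, 3):
                src = tuple(rng.choice(STATES, 3))
                end = tuple(rng.choice(STATES, 3))
                comparisons.append(
                    cmp_of(src, end, genes=tuple(genes[i:i + 3]))
                )
            records = rank_genes(comparisons)
            gene_set = set(rng.choice(genes, 12, replace=False))
            p, _, _ = top_fraction_enrichment(records, gene_set, 0.05)
            hits += p <= 0.05
        # hypergeometric p is discrete and conservative near the floor
        assert hits / reps <= 0.05 + 4 * np.sqrt(0.05 * 0.95 / reps)


def test_end_to_end_with_compare_ffls():
    """Scores computed on comparisons produced by the comparative stage."""
    edges_a = [("T", "M"), ("T", "G"), ("M", "G")]
    edges_b = [("T", "M"), ("M", "G")]
    st_a = {"T": STRONG, "M": STRONG, "G": STRONG}
    st_b = {"T": STRONG, "M": STRONG, "G": POISED}
    comparisons = compare_ffls(
        network_from_edges(edges_a), network_from_edges(edges_b), st_a, st_b
    )
    records = {r.gene_id: r for r in rank_genes(comparisons)}
    # G: Strong->Poised (10) + structure change (5)
    assert records["G"].summary_score == 15
    assert records["T"].summary_score == 15  # same instance, pooled positions
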