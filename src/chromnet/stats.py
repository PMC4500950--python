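"""Cross-cutting statistics.

- mutual-exclusivity permutation test on binary composition x structure
  matrices (column-wise permutation null),
- Wilcoxon rank-sum comparisons of target expression between colored
  FFL classes within one activator/repressor FFL type,
- hypergeometric gene-set enrichment with Benjamini-Hochberg FDR,
- the cell-type specificity score (expression fraction across cell
  lines, specific when > 0.85).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .motifs import ColoredTriadClass, FFLInstance

logger = logging.getLogger("chromnet")


# ---------------------------------------------------------------------------
# mutual exclusivity


def exclusivity_score(M: np.ndarray) -> float:
    """S_M: fraction of rows coupled to exactly one column.

    Rows are chromatin-state compositions, columns motif structures (or
    cell types); S_i = 1 iff row i has a single 1.  Rows that are all
    zero (possible after permutation) contribute 0.
    """
    M = np.asarray(M)
    if M.size == 0:
        raise ValueError("empty matrix")
    row_sums = M.sum(axis=1)
    return float((row_sums == 1).mean())


def exclusivity_test(
    M: np.ndarray, n_perm: int = 10_000, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Permutation test of mutual exclusivity.

    Each permutation independently shuffles the entries within every
    column (column sums are preserved exactly).  P is the fraction of
    permutations whose S_M is >= the observed score.
    """
    if rng is None:
        rng = np.random.default_rng()
    M = np.asarray(M, dtype=int)
    if M.size == 0 or not M.any():
        raise ValueError("matrix must contain at least one 1")
    observed = exclusivity_score(M)
    n_rows, n_cols = M.shape
    perm = M.copy()
    exceed = 0
    for _ in range(n_perm):
        for j in range(n_cols):
            perm[:, j] = M[rng.permutation(n_rows), j]
        if exclusivity_score(perm) >= observed:
            exceed += 1
    return observed, exceed / n_perm


def composition_matrix(
    classes: Iterable[ColoredTriadClass],
) -> tuple[np.ndarray, list[tuple[str, ...]], list[int]]:
    """Binary composition x structure incidence matrix from colored classes.

    Rows are distinct state compositions, columns distinct structures;
    entry 1 when that composition appears with that structure.
    """
    classes = list(classes)
    comps = sorted({c.coloring for c in classes})
    structs = sorted({c.structure for c in classes})
    M = np.zeros((len(comps), len(structs)), dtype=int)
    ci = {c: i for i, c in enumerate(comps)}
    si = {s: j for j, s in enumerate(structs)}
    for c in classes:
        M[ci[c.coloring], si[c.structure]] = 1
    return M, comps, structs


# ---------------------------------------------------------------------------
# expression comparisons between colored FFL classes


FFL_TYPES = {
    # (top effect, intermediate effect) -> type
    ("repressor", "repressor"): "I",
    ("activator", "activator"): "II",
    ("activator", "repressor"): "III",
    ("repressor", "activator"): "IV",
}


def classify_ffl_type(
    inst: FFLInstance, tf_effects: Mapping[str, str]
) -> str | None:
    """Type I–IV by the activator/repressor roles of the two TFs."""
    key = (tf_effects.get(inst.top, "unknown"), tf_effects.get(inst.mid, "unknown"))
    return FFL_TYPES.get(key)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact null distribution for small tie-free samples, normal
    approximation with tie correction otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def composition_expression_test(
    instances: Sequence[FFLInstance],
    expression: Mapping[str, float] | pd.Series,
    tf_effects: Mapping[str, str],
    ffl_type: str,
    min_group: int = 3,
) -> pd.DataFrame:
    """Pairwise expression comparisons between colored classes of one FFL type.

    Targets appearing in more than one colored class are removed first
    so every comparison uses disjoint target sets.  Returns one row per
    class pair with the rank-sum statistic, P and group sizes.
    """
    groups: dict[tuple[str, str, str], set[str]] = {}
    for inst in instances:
        if classify_ffl_type(inst, tf_effects) != ffl_type:
            continue
        groups.setdefault(inst.states, set()).add(inst.target)

    seen: dict[str, int] = {}
    for targets in groups.values():
        for t in targets:
            seen[t] = seen.get(t, 0) + 1
    shared = {t for t, k in seen.items() if k > 1}
    groups = {c: {t for t in ts if t not in shared} for c, ts in groups.items()}

    rows = []
    comps = sorted(groups)
    for i, ca in enumerate(comps):
        for cb in comps[i + 1:]:
            xa = [expression[t] for t in sorted(groups[ca]) if t in expression]
            xb = [expression[t] for t in sorted(groups[cb]) if t in expression]
            if len(xa) < min_group or len(xb) < min_group:
                logger.info("skipping %s vs %s: group too small", ca, cb)
                continue
            stat, p = wilcoxon_rank_sum(xa, xb)
            rows.append(
                {
                    "composition_a": ",".join(ca),
                    "composition_b": ",".join(cb),
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "statistic": stat,
                    "p": p,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["composition_a", "composition_b", "n_a", "n_b", "statistic", "p"],
    )


# ---------------------------------------------------------------------------
# gene-set enrichment


@dataclass(frozen=True)
class EnrichmentQuery:
    """Hypergeometric 2x2 setup: background N, term n, query M, overlap k."""

    N: int
    n: int
    M: int
    k: int

    def __post_init__(self):
        if not (0 <= self.n <= self.N and 0 <= self.M <= self.N):
            raise ValueError("term and query sizes must be within the background")
        if self.k > min(self.n, self.M) or self.k < 0:
            raise ValueError(f"overlap k={self.k} impossible for n={self.n}, M={self.M}")


def hypergeom_enrichment(q: EnrichmentQuery) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, n, M)."""
    return float(sps.hypergeom.sf(q.k - 1, q.N, q.n, q.M))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted P-values."""
    return multipletests(pvalues, method="fdr_bh")[1]


def gene_set_enrichment(
    query: set[str],
    gene_sets: Mapping[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query set across flat gene sets,
    with BH FDR across terms."""
    rows = []
    q = query & background
    for term, members in sorted(gene_sets.items()):
        m = members & background
        k = len(q & m)
        p = hypergeom_enrichment(
            EnrichmentQuery(len(background), len(m), len(q), k)
        )
        rows.append({"term": term, "n_term": len(m), "overlap": k, "p": p})
    df = pd.DataFrame(rows, columns=["term", "n_term", "overlap", "p"])
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["fdr"] < alpha
    return df


# ---------------------------------------------------------------------------
# cell-type specificity


def cell_specificity(
    expr_row: Sequence[float], threshold: float = 0.85
) -> tuple[np.ndarray, list[int]]:
    """Expression fraction per cell line, and which cells exceed threshold.

    S_ij = exp_ij / sum_j exp_ij; a gene is specific to cell j when
    S_ij > 0.85 (default).  All-zero rows are rejected.
    """
    x = np.asarray(expr_row, dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be >= 0")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero expression row")
    scores = x / total
    return scores, [int(j) for j in np.flatnonzero(scores > threshold)]
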