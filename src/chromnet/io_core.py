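"""Domain types, file readers/writers and pipeline configuration.

All genomic coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  Converting a 1-based inclusive coordinate therefore
shifts the start by -1 exactly once, at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger("chromnet")

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 bp (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class PeakRecord:
    """A ChIP-seq peak with the offset of its summit from the peak start."""

    interval: GenomicInterval
    summit_offset: int
    tf_name: str

    def __post_init__(self) -> None:
        if not 0 <= self.summit_offset < len(self.interval):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak of length "
                f"{len(self.interval)}"
            )

    @property
    def summit(self) -> int:
        """Absolute genomic position of the summit."""
        return self.interval.start + self.summit_offset


@dataclass(frozen=True)
class StateSegment:
    """One segment of a genome chromatin-state segmentation.

    Carries both the raw label from the input file (e.g. one of the
    15-state vocabulary) and the broad 4-class label it maps to.
    """

    interval: GenomicInterval
    label: str
    broad_label: str


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS, strand, and regulatory role."""

    gene_id: str
    tss: GenomicInterval  # length-1 interval with strand
    is_tf: bool = False
    tf_effect: str = "unknown"  # activator | repressor | unknown

    def __post_init__(self) -> None:
        if len(self.tss) != 1:
            raise ValueError("tss must be a length-1 interval")
        if self.tf_effect not in {"activator", "repressor", "unknown"}:
            raise ValueError(f"bad tf_effect {self.tf_effect!r}")


@dataclass
class PipelineConfig:
    """Parameters of the whole pipeline.

    Defaults follow the published procedure: 1-kb promoters (0.5 kb up-
    and downstream of the TSS), 40-bp binding-site windows centered on
    peak summits, 500 randomized networks for motif significance, 10,000
    permutations for the mutual-exclusivity test, 1,000 permutations for
    the state-transition test, and alpha = 0.05.
    """

    promoter_up_bp: int = 500
    promoter_down_bp: int = 500
    tfbs_width_bp: int = 40
    n_random_networks: int = 500
    n_excl_perms: int = 10_000
    n_transition_perms: int = 1_000
    rng_seed: int = 0
    significance_alpha: float = 0.05
    swap_factor: int = 10
    state_vocabulary_map: dict[str, str] = field(default_factory=dict)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, rng_seed=seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# readers


def _bed_fields(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def _parse_coords(fields: list[str], path, lineno) -> tuple[str, int, int]:
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if end <= start or start < 0:
        raise ValueError(f"{path}:{lineno}: bad interval [{start}, {end})")
    return chrom, start, end


def read_peaks(path: str | Path, tf_name: str) -> list[PeakRecord]:
    """Read a BED / narrowPeak file of ChIP-seq peaks for one TF.

    The narrowPeak dialect stores the summit offset in column 10; when
    that column is absent or negative (narrowPeak uses -1 for "not
    called") the interval midpoint is used instead.
    """
    out: list[PeakRecord] = []
    for lineno, f in _bed_fields(path):
        chrom, start, end = _parse_coords(f, path, lineno)
        summit = (end - start) // 2
        if len(f) >= 10:
            try:
                cand = int(f[9])
            except ValueError:
                cand = -1
            if 0 <= cand < end - start:
                summit = cand
        out.append(
            PeakRecord(GenomicInterval(chrom, start, end), summit, tf_name)
        )
    if not out:
        logger.warning("peak file %s is empty", path)
    return out


def read_dhs(path: str | Path) -> list[GenomicInterval]:
    """Read DNase I hypersensitive sites from a BED-like file (first 3 cols)."""
    out = []
    for lineno, f in _bed_fields(path):
        chrom, start, end = _parse_coords(f, path, lineno)
        out.append(GenomicInterval(chrom, start, end))
    return out


def read_segmentation(
    path: str | Path, vocab_map: Mapping[str, str]
) -> list[StateSegment]:
    """Read a BED4 chromatin-state segmentation (col 4 = state label).

    ``vocab_map`` maps each raw label to a broad label; the identity map
    is allowed when the file already uses broad labels.  Unknown labels
    raise with the offending label named.
    """
    out = []
    for lineno, f in _bed_fields(path):
        chrom, start, end = _parse_coords(f, path, lineno)
        if len(f) < 4:
            raise ValueError(f"{path}:{lineno}: segmentation needs a 4th (label) column")
        label = f[3]
        if label not in vocab_map:
            raise ValueError(
                f"{path}:{lineno}: unknown state label {label!r} "
                f"(not in vocabulary map)"
            )
        out.append(
            StateSegment(GenomicInterval(chrom, start, end), label, vocab_map[label])
        )
    return out


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read a gene annotation TSV: gene_id, chrom, tss, strand, is_tf, tf_effect.

    ``tss`` is the 0-based TSS coordinate.  Genes without a strand are
    treated as '+' with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    genes = []
    for row in df.itertuples(index=False):
        strand = getattr(row, "strand", ".")
        if strand not in {"+", "-"}:
            logger.warning("gene %s lacks a strand; assuming '+'", row.gene_id)
            strand = "+"
        tss = int(row.tss)
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                tss=GenomicInterval(str(row.chrom), tss, tss + 1, strand),
                is_tf=bool(getattr(row, "is_tf", False)),
                tf_effect=str(getattr(row, "tf_effect", "unknown")),
            )
        )
    return genes


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x condition expression TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids in expression table")
    return df


# ---------------------------------------------------------------------------
# writers (tab-delimited tables with headers; round-trip exact)


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    df = pd.DataFrame(sorted(edges), columns=["tf", "target"])
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [(t.tf, t.target) for t in df.itertuples(index=False)]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_gene_states(states: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(sorted(states.items()), columns=["gene", "state"])
    df.to_csv(path, sep="\t", index=False)


def read_gene_states(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["gene"], df["state"]))


def write_peaks(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    """Write peaks as 10-column narrowPeak (summit in column 10)."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.tf_name}\t0\t.\t0\t-1\t-1\t"
                f"{p.summit_offset}\n"
            )


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_segmentation(segments: Iterable[StateSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            iv = s.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.label}\n")


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.tss.chrom,
            "tss": g.tss.start,
            "strand": g.tss.strand,
            "is_tf": g.is_tf,
            "tf_effect": g.tf_effect,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
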