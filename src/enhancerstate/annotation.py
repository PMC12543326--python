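"""Promoter-window gene assignment and the gene-set overlap chi-squared test.

Each gene is reduced to a single transcription start site (TSS, 0-based):
the 5'-most transcript start on the + strand, the 3'-most transcript end on
the - strand. The promoter window spans a configurable range around the TSS
(default 5000 bp upstream to 100 bp downstream, strand-aware). Regions
overlapping a promoter window are assigned to that gene; all others fall
back to the nearest TSS, so every region receives exactly one assignment.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "GeneModel",
    "GeneAssignment",
    "read_gene_models",
    "promoter_window",
    "annotate_regions",
    "gene_sets_from_dbrs",
    "overlap_chi_squared",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its representative TSS (0-based) and strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass
class GeneAssignment:
    """region -> gene link; ``tss_distance`` is signed and strand-aware
    (negative = upstream of the TSS), measured from the region midpoint."""

    region: GenomicInterval
    gene_id: str
    in_promoter: bool
    tss_distance: int


_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_models(path, fmt: str = "auto") -> list[GeneModel]:
    """Read gene models from an Ensembl-style GTF or a 4-column TSV.

    GTF coordinates are 1-based inclusive and converted to 0-based: the TSS
    of a + strand gene is ``min(transcript start) - 1``, of a - strand gene
    ``max(transcript end) - 1``. Genes without any ``transcript`` feature
    line are skipped with a warning. The TSV format has a header line
    ``gene_id  chrom  tss  strand`` with 0-based TSS positions.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "tsv"
    if fmt == "tsv":
        return _read_tss_table(path)
    if fmt != "gtf":
        raise ValueError(f"unknown gene-model format {fmt!r}")

    spans: dict[str, tuple[str, str, int, int]] = {}  # gene -> chrom,strand,min1,max1
    seen_genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            feature = cols[2]
            m = _GENE_ID_RE.search(cols[8])
            if m is None:
                continue
            gid = m.group(1)
            if feature == "gene" and gid not in spans:
                seen_genes.append(gid)
                continue
            if feature != "transcript":
                continue
            chrom, start1, end1, strand = cols[0], int(cols[3]), int(cols[4]), cols[6]
            if gid in spans:
                c, s, lo, hi = spans[gid]
                spans[gid] = (c, s, min(lo, start1), max(hi, end1))
            else:
                spans[gid] = (chrom, strand, start1, end1)
    for gid in seen_genes:
        if gid not in spans:
            warnings.warn(f"gene {gid!r} has no transcript lines; skipped")
    genes = []
    for gid, (chrom, strand, lo1, hi1) in spans.items():
        tss = lo1 - 1 if strand == "+" else hi1 - 1
        genes.append(GeneModel(gid, chrom, tss, strand))
    genes.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    return genes


def _read_tss_table(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0] == "gene_id":
                continue
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
            genes.append(GeneModel(cols[0], cols[1], int(cols[2]), cols[3]))
    genes.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


def promoter_window(
    gene: GeneModel, upstream: int = 5000, downstream: int = 100
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, 0-based half-open.

    + strand: [tss - upstream, tss + downstream); - strand mirrors it:
    [tss - downstream + 1, tss + upstream + 1). Clamped at 0.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream + 1, gene.tss + upstream + 1
    return GenomicInterval(gene.chrom, max(0, start), end, name=gene.gene_id,
                           strand=gene.strand)


def _signed_distance(region: GenomicInterval, gene: GeneModel) -> int:
    mid = (region.start + region.end) // 2
    d = mid - gene.tss
    return d if gene.strand == "+" else -d


def annotate_regions(
    regions: IntervalSet,
    genes: Sequence[GeneModel],
    upstream: int = 5000,
    downstream: int = 100,
) -> list[GeneAssignment]:
    """Assign every region to exactly one gene.

    A region overlapping one or more promoter windows is assigned to the
    overlapped gene with the smallest absolute TSS distance (ties broken by
    lexicographic gene_id) with ``in_promoter=True``; otherwise it goes to
    the nearest TSS on its chromosome with ``in_promoter=False``. Regions on
    chromosomes without genes are skipped with a warning.
    """
    if not genes:
        raise ValueError("no gene models supplied")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)
    windows = {g: promoter_window(g, upstream, downstream) for g in genes}

    out: list[GeneAssignment] = []
    skipped = 0
    for iv in regions:
        cands = by_chrom.get(iv.chrom)
        if not cands:
            skipped += 1
            continue
        hits = [
            g for g in cands
            if windows[g].start < iv.end and iv.start < windows[g].end
        ]
        pool = hits if hits else cands
        best = min(pool, key=lambda g: (abs(_signed_distance(iv, g)), g.gene_id))
        out.append(
            GeneAssignment(iv, best.gene_id, bool(hits and best in hits),
                           _signed_distance(iv, best))
        )
    if skipped:
        warnings.warn(f"{skipped} region(s) on chromosomes without gene models")
    return out


def gene_sets_from_dbrs(
    assignments: Iterable[GeneAssignment], promoter_only: bool = False
) -> set[str]:
    """Unique gene ids hit by a DBR set; optionally promoter overlaps only."""
    return {
        a.gene_id for a in assignments if a.in_promoter or not promoter_only
    }


def overlap_chi_squared(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
    yates: bool = False,
) -> tuple[int, float, float]:
    """Pearson chi-squared (1 df) for the overlap of two gene sets.

    Builds the 2x2 table (in both, A only, B only, neither) over ``universe``
    and returns (|A ∩ B|, statistic, upper-tail p). No continuity correction
    by default; enable Yates with ``yates=True``. Requires non-empty sets,
    a universe containing both, and strictly positive expected counts.
    """
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("gene sets must be subsets of the universe")
    n = len(universe)
    if n < 4:
        raise ValueError("universe too small for a 2x2 table")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = n - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    expected = np.outer(table.sum(1), table.sum(0)) / n
    if np.any(expected <= 0):
        raise ValueError("all four expected counts must be positive")
    stat, p, _, _ = chi2_contingency(table, correction=yates)
    return a, float(stat), float(p)
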