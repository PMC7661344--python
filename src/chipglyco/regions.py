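"""Genomic region classification and ChIP-peak filtering.

Peaks from a transcription-factor ChIP experiment are classified into five
region classes relative to an annotated gene set -- the 2 kb immediately
upstream of the transcription start site (UP2K), the 2 kb downstream of the
transcript end (DOWN2K), exons, introns, and everything else (intergenic) --
then filtered by fold enrichment against two independent controls
(M1 = ChIP vs. IgG, M2 = ChIP vs. input chromatin) and intersected.

Coordinates on the public dataclasses are 1-based fully closed, matching how
genome browsers and the ``assembly:chrom:start:end:strand`` notation print
intervals; the interval index converts to 0-based half-open internally.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

from intervaltree import IntervalTree

FLANK_BP = 2000


class RegionClass(enum.IntEnum):
    """Region classes in decreasing assignment priority.

    When a position falls inside regions of more than one gene, the class
    with the smallest value wins; promoter-proximal assignment dominates
    because the promoter is the biological object of interest.
    """

    UP2K = 0
    DOWN2K = 1
    EXON = 2
    INTRON = 3
    INTERGENIC = 4


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene model with TSS/TES anchors and exon structure.

    ``tss`` and ``tes`` are 1-based; for a minus-strand gene the TSS is the
    larger coordinate. ``exons`` are 1-based closed intervals, sorted,
    non-overlapping, and contained in the gene body.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError(f"{self.gene_id}: tss == tes")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have at least one exon")
        lo, hi = self.body
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end ({s}, {e})")
            if s < lo or e > hi:
                raise ValueError(f"{self.gene_id}: exon ({s}, {e}) outside gene body")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def body(self) -> tuple[int, int]:
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    def upstream_2k(self, chrom_length: int | None = None) -> tuple[int, int] | None:
        """The 2000 bp strictly upstream of the TSS on the gene's strand."""
        if self.strand == "+":
            lo, hi = self.tss - FLANK_BP, self.tss - 1
        else:
            lo, hi = self.tss + 1, self.tss + FLANK_BP
        return _clip(lo, hi, chrom_length)

    def downstream_2k(self, chrom_length: int | None = None) -> tuple[int, int] | None:
        """The 2000 bp strictly downstream of the transcript end."""
        if self.strand == "+":
            lo, hi = self.tes + 1, self.tes + FLANK_BP
        else:
            lo, hi = self.tes - FLANK_BP, self.tes - 1
        return _clip(lo, hi, chrom_length)

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


def _clip(lo: int, hi: int, chrom_length: int | None) -> tuple[int, int] | None:
    lo = max(lo, 1)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    if lo > hi:
        return None
    return (lo, hi)


@dataclass(frozen=True)
class Peak:
    """A ChIP peak interval with fold enrichments against the two controls."""

    peak_id: str
    chrom: str
    start: int
    end: int
    fold_m1: float
    fold_m2: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.peak_id}: start > end")
        if self.fold_m1 < 0 or self.fold_m2 < 0:
            raise ValueError(f"{self.peak_id}: negative fold enrichment")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "Peak") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


class RegionIndex:
    """Point-queryable map position -> RegionClass for a gene set.

    Built once per gene set; lookups resolve multi-gene overlap by the
    RegionClass priority order.
    """

    def __init__(self, genes: list[GeneModel], chrom_lengths: dict[str, int]):
        self.chrom_lengths = dict(chrom_lengths)
        self._trees: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_lengths}
        for g in genes:
            if g.chrom not in chrom_lengths:
                raise ValueError(f"{g.gene_id}: chromosome {g.chrom!r} not in chrom_lengths")
            clen = chrom_lengths[g.chrom]
            lo, hi = g.body
            if lo < 1 or hi > clen:
                raise ValueError(f"{g.gene_id}: gene body outside chromosome bounds")
            tree = self._trees[g.chrom]
            up = g.upstream_2k(clen)
            if up:
                _add(tree, up, RegionClass.UP2K)
            down = g.downstream_2k(clen)
            if down:
                _add(tree, down, RegionClass.DOWN2K)
            for ex in g.exons:
                _add(tree, ex, RegionClass.EXON)
            for intr in g.introns():
                _add(tree, intr, RegionClass.INTRON)

    def class_at(self, chrom: str, pos: int) -> RegionClass:
        """Class of a single 1-based position under the priority rule."""
        if chrom not in self._trees:
            raise KeyError(f"unknown chromosome {chrom!r}")
        hits = self._trees[chrom][pos]
        if not hits:
            return RegionClass.INTERGENIC
        return min(h.data for h in hits)


def _add(tree: IntervalTree, closed: tuple[int, int], cls: RegionClass) -> None:
    tree.addi(closed[0], closed[1] + 1, cls)


def classify_peak(peak: Peak, index: RegionIndex) -> RegionClass:
    """Classify a peak by the region class of its midpoint."""
    return index.class_at(peak.chrom, peak.midpoint)


def compute_fold_enrichment(
    treat_count: float,
    ctrl_count: float,
    treat_depth: float,
    ctrl_depth: float,
    pseudocount: float = 1.0,
) -> float:
    """Depth-normalised fold enrichment of treatment over control counts.

    Returns ``((treat + pc) / treat_depth) / ((ctrl + pc) / ctrl_depth)``.
    The pseudocount (default 1) keeps the ratio finite when the control
    count is zero.
    """
    if treat_depth <= 0 or ctrl_depth <= 0:
        raise ValueError("sequencing depths must be positive")
    if treat_count < 0 or ctrl_count < 0:
        raise ValueError("read counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    return ((treat_count + pseudocount) / treat_depth) / (
        (ctrl_count + pseudocount) / ctrl_depth
    )


@dataclass
class PeakSetComparison:
    """Result of dual-control fold filtering and set intersection."""

    m1_pass: list[str]
    m2_pass: list[str]
    common: list[tuple[str, str]]
    per_chrom: dict[str, tuple[int, int]]
    m1_peaks: dict[str, Peak] = field(default_factory=dict, repr=False)
    m2_peaks: dict[str, Peak] = field(default_factory=dict, repr=False)


def filter_and_intersect(
    m1: list[Peak],
    m2: list[Peak],
    threshold: float = 2.0,
    min_overlap: int = 1,
    inclusive: bool = False,
) -> PeakSetComparison:
    """Apply the fold-enrichment filter to both contrasts and intersect.

    A peak passes when its fold against the matching control exceeds
    ``threshold`` (strictly, unless ``inclusive``). Passing peaks from the
    two contrasts are paired greedily when they overlap by at least
    ``min_overlap`` bp on the same chromosome: largest overlap first, ties
    broken by leftmost start, and each peak joins at most one pair.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep = (lambda f: f >= threshold) if inclusive else (lambda f: f > threshold)
    m1_pass = [p for p in m1 if keep(p.fold_m1)]
    m2_pass = [p for p in m2 if keep(p.fold_m2)]

    candidates = []
    for a in m1_pass:
        for b in m2_pass:
            ov = a.overlap_bp(b)
            if ov >= min_overlap:
                candidates.append((ov, a, b))
    candidates.sort(key=lambda t: (-t[0], t[1].start, t[2].start, t[1].peak_id, t[2].peak_id))
    used_m1: set[str] = set()
    used_m2: set[str] = set()
    common: list[tuple[str, str]] = []
    for _, a, b in candidates:
        if a.peak_id in used_m1 or b.peak_id in used_m2:
            continue
        used_m1.add(a.peak_id)
        used_m2.add(b.peak_id)
        common.append((a.peak_id, b.peak_id))

    per_chrom: dict[str, tuple[int, int]] = {}
    for chrom in sorted({p.chrom for p in m1_pass} | {p.chrom for p in m2_pass}):
        n1 = sum(1 for p in m1_pass if p.chrom == chrom)
        n2 = sum(1 for p in m2_pass if p.chrom == chrom)
        per_chrom[chrom] = (n1, n2)

    return PeakSetComparison(
        m1_pass=[p.peak_id for p in m1_pass],
        m2_pass=[p.peak_id for p in m2_pass],
        common=common,
        per_chrom=per_chrom,
        m1_peaks={p.peak_id: p for p in m1_pass},
        m2_peaks={p.peak_id: p for p in m2_pass},
    )


def chromosome_distribution(
    comparison: PeakSetComparison, chroms: list[str] | None = None
) -> dict[str, tuple[int, int]]:
    """Per-chromosome (M1, M2) pass counts; listed chromosomes with no
    peaks are reported as (0, 0), never omitted."""
    out: dict[str, tuple[int, int]] = {}
    for chrom in chroms or []:
        out[chrom] = (0, 0)
    out.update(comparison.per_chrom)
    return out


_SPEC_RE = re.compile(r"^([^:]+):([^:]+):(\d+):(\d+):(-?1)$")


def interval_length(chrom_spec: str) -> int:
    """Length in bp of an ``assembly:chrom:start:end:strand`` interval,
    read under the 1-based fully-closed convention.

    >>> interval_length("GRCh38:11:94541840:94543879:1")
    2040
    """
    m = _SPEC_RE.match(chrom_spec.strip())
    if not m:
        raise ValueError(f"malformed interval spec: {chrom_spec!r}")
    start, end = int(m.group(3)), int(m.group(4))
    if start > end:
        raise ValueError(f"interval spec has start > end: {chrom_spec!r}")
    return end - start + 1
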