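"""Region classification, fold filtering, intersection, coordinate arithmetic."""

import numpy as np
import pytest

from chipglyco import (
    GeneModel,
    Peak,
    RegionClass,
    RegionIndex,
    chromosome_distribution,
    classify_peak,
    compute_fold_enrichment,
    filter_and_intersect,
    interval_length,
)

CL = {"chr1": 100_000}


def _plus_gene(tss=10_000, tes=15_000, exons=None, gene_id="g1"):
    return GeneModel(gene_id, "chr1", "+", tss, tes, exons or ((tss, tes),))


class TestRegionIndex:
    def test_up2k_boundaries_plus_strand(self):
        idx = RegionIndex([_plus_gene()], CL)
        assert idx.class_at("chr1", 9500) == RegionClass.UP2K
        assert idx.class_at("chr1", 8000) == RegionClass.UP2K  # tss - 2000
        assert idx.class_at("chr1", 7999) == RegionClass.INTERGENIC
        assert idx.class_at("chr1", 9999) == RegionClass.UP2K
        assert idx.class_at("chr1", 10_000) == RegionClass.EXON  # the TSS itself

    def test_up2k_minus_strand(self):
        g = GeneModel("g1", "chr1", "-", 10_000, 5_000, ((5_000, 10_000),))
        idx = RegionIndex([g], CL)
        assert idx.class_at("chr1", 10_500) == RegionClass.UP2K
        assert idx.class_at("chr1", 12_000) == RegionClass.UP2K
        assert idx.class_at("chr1", 12_001) == RegionClass.INTERGENIC
        assert idx.class_at("chr1", 4_500) == RegionClass.DOWN2K

    def test_exon_intron_structure(self):
        g = _plus_gene(exons=((10_000, 11_000), (12_000, 13_000), (14_000, 15_000)))
        idx = RegionIndex([g], CL)
        assert idx.class_at("chr1", 10_500) == RegionClass.EXON
        assert idx.class_at("chr1", 11_500) == RegionClass.INTRON
        assert idx.class_at("chr1", 14_000) == RegionClass.EXON

    def test_gene_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside chromosome"):
            RegionIndex([_plus_gene(tss=99_000, tes=101_000, exons=((99_000, 101_000),))], CL)

    def test_unknown_chromosome_lookup(self, region_index):
        with pytest.raises(KeyError):
            region_index.class_at("chrUn", 100)

    def test_priority_promoter_wins(self):
        # gene B's UP2K overlaps gene A's gene body: UP2K must win
        a = _plus_gene(tss=10_000, tes=15_000, gene_id="a")
        b = GeneModel("b", "chr1", "+", 16_000, 20_000, ((16_000, 20_000),))
        idx = RegionIndex([a, b], CL)
        assert idx.class_at("chr1", 14_500) == RegionClass.UP2K

    def test_matches_exhaustive_position_oracle(self, genes, chrom_lengths, region_index):
        """Index lookups agree with a brute-force scan over every gene's
        feature intervals at 10,000 random positions."""
        rng = np.random.default_rng(5)
        chroms = sorted(chrom_lengths)
        for _ in range(10_000):
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
            assert region_index.class_at(chrom, pos) == _oracle_class(
                genes, chrom_lengths, chrom, pos
            )


def _oracle_class(genes, chrom_lengths, chrom, pos):
    """Independent per-position classification: test the position against
    every feature interval of every gene, then take the priority minimum."""
    hits = []
    for g in genes:
        if g.chrom != chrom:
            continue
        clen = chrom_lengths[chrom]
        up = g.upstream_2k(clen)
        if up and up[0] <= pos <= up[1]:
            hits.append(RegionClass.UP2K)
        down = g.downstream_2k(clen)
        if down and down[0] <= pos <= down[1]:
            hits.append(RegionClass.DOWN2K)
        lo, hi = g.body
        if lo <= pos <= hi:
            if any(s <= pos <= e for s, e in g.exons):
                hits.append(RegionClass.EXON)
            else:
                hits.append(RegionClass.INTRON)
    return min(hits) if hits else RegionClass.INTERGENIC


class TestClassifyPeak:
    def test_midpoint_rule(self):
        idx = RegionIndex([_plus_gene()], CL)
        # midpoint (8500+9200)//2 = 8850 lies in [8000, 9999]
        pk = Peak("p", "chr1", 8500, 9200, 3.0, 3.0)
        assert classify_peak(pk, idx) == RegionClass.UP2K

    def test_intergenic_peak(self):
        idx = RegionIndex([_plus_gene()], CL)
        assert classify_peak(Peak("p", "chr1", 50_000, 50_400, 3.0, 3.0), idx) \
            == RegionClass.INTERGENIC


class TestFoldEnrichment:
    @pytest.mark.parametrize(
        "treat,ctrl,pc,expected",
        [(73, 10, 0, 7.3), (50, 50, 5, 1.0), (9, 0, 1, 10.0)],
    )
    def test_equal_depths(self, treat, ctrl, pc, expected):
        assert compute_fold_enrichment(treat, ctrl, 1e6, 1e6, pc) == pytest.approx(expected)

    def test_depth_normalization(self):
        # same counts at double treatment depth halve the fold
        assert compute_fold_enrichment(100, 100, 2e6, 1e6, 0) == pytest.approx(0.5)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            compute_fold_enrichment(1, 1, 0, 1e6)


def _pk(pid, start, end, f1, f2, chrom="chr1"):
    return Peak(pid, chrom, start, end, f1, f2)


class TestFilterAndIntersect:
    def test_threshold_and_pairing(self):
        m1 = [_pk("a", 100, 200, 2.5, 1.0), _pk("b", 300, 400, 1.8, 1.0),
              _pk("c", 500, 600, 4.0, 1.0)]
        m2 = [_pk("x", 150, 250, 1.0, 3.0), _pk("y", 550, 620, 1.0, 2.6)]
        cmp_ = filter_and_intersect(m1, m2)
        assert cmp_.m1_pass == ["a", "c"]
        assert cmp_.m2_pass == ["x", "y"]
        assert sorted(cmp_.common) == [("a", "x"), ("c", "y")]

    def test_identical_lists_fully_paired(self):
        peaks = [_pk(f"p{i}", 1000 * i, 1000 * i + 200, 3.0, 3.0) for i in range(1, 6)]
        cmp_ = filter_and_intersect(peaks, peaks)
        assert len(cmp_.common) == len(cmp_.m1_pass) == 5

    def test_each_peak_in_at_most_one_pair(self):
        # one wide m1 peak overlapping two m2 peaks: only one pair allowed
        m1 = [_pk("w", 100, 1000, 3.0, 3.0)]
        m2 = [_pk("x", 100, 500, 3.0, 3.0), _pk("y", 600, 1000, 3.0, 3.0)]
        cmp_ = filter_and_intersect(m1, m2)
        assert cmp_.common == [("w", "x")]  # larger overlap wins (401 vs 400)

    def test_strictly_greater_by_default(self):
        m1 = [_pk("edge", 1, 10, 2.0, 2.0)]
        assert filter_and_intersect(m1, []).m1_pass == []
        assert filter_and_intersect(m1, [], inclusive=True).m1_pass == ["edge"]

    def test_filter_monotonicity(self):
        rng = np.random.default_rng(17)
        peaks = [
            _pk(f"p{i}", int(s), int(s) + 300, float(f1), float(f2))
            for i, (s, f1, f2) in enumerate(
                zip(rng.integers(1, 90_000, 60), rng.uniform(0, 6, 60), rng.uniform(0, 6, 60))
            )
        ]
        sizes = []
        for thr in (1.0, 2.0, 3.0, 4.0):
            c = filter_and_intersect(peaks, peaks, threshold=thr)
            sizes.append((len(c.m1_pass), len(c.m2_pass), len(c.common)))
        for lo, hi in zip(sizes[1:], sizes[:-1]):
            assert all(a <= b for a, b in zip(lo, hi))

    def test_per_chrom_sums_to_totals(self):
        m1 = [_pk("a", 1, 9, 3, 3), _pk("b", 1, 9, 3, 3, "chr2")]
        cmp_ = filter_and_intersect(m1, m1)
        assert sum(v[0] for v in cmp_.per_chrom.values()) == len(cmp_.m1_pass)
        dist = chromosome_distribution(cmp_, chroms=["chr1", "chr2", "chr3"])
        assert dist["chr3"] == (0, 0)
        assert dist["chr1"] == (1, 1)

    def test_empty_inputs(self):
        cmp_ = filter_and_intersect([], [])
        assert cmp_.m1_pass == [] and cmp_.common == []
        assert chromosome_distribution(cmp_) == {}


class TestIntervalLength:
    @pytest.mark.parametrize(
        "spec,expected",
        [
            ("GRCh38:11:94541840:94543879:1", 2040),
            ("GRCh38:11:94543285:94543815:1", 531),
            ("GRCh38:1:500:500:1", 1),
        ],
    )
    def test_closed_convention(self, spec, expected):
        assert interval_length(spec) == expected

    @pytest.mark.parametrize("bad", ["GRCh38:11:10:5:1", "no-colons", "a:b:c:d:e", ""])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            interval_length(bad)


def test_strand_mirror_symmetry():
    """Reflecting a gene about a point swaps UP2K and DOWN2K footprints."""
    pivot = 50_000
    g = GeneModel("g", "chr1", "+", 20_000, 26_000, ((20_000, 26_000),))
    mirrored = GeneModel(
        "g", "chr1", "-",
        tss=2 * pivot - 20_000, tes=2 * pivot - 26_000,
        exons=((2 * pivot - 26_000, 2 * pivot - 20_000),),
    )
    i1 = RegionIndex([g], CL)
    i2 = RegionIndex([mirrored], CL)
    for pos in range(15_000, 31_000, 7):
        c1 = i1.class_at("chr1", pos)
        c2 = i2.class_at("chr1", 2 * pivot - pos)
        assert c1 == c2
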