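"""Synthetic-data generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here with a
known, fully recorded truth: gene models on synthetic chromosomes, ChIP
peak lists with planted region classes and planted fold enrichments
against the two controls, promoter-like sequences with planted degenerate
motif occurrences on either strand, lectin-array spot grids with planted
NFI fold changes, and qPCR Ct tables with planted expression ratios.

Conventions:

* every generator is deterministic in (parameters, seed);
* each generator draws from its own independent stream (seeded from the
  user seed plus a per-generator tag), so adding a call to one generator
  never perturbs another's output;
* in the zero-noise limit every downstream stage recovers the planted
  truth exactly.

The lectin spot model plants each block's realised mean measured
background into every foreground of that block, so that averaged-background
subtraction is exact and the zero-noise limit recovers planted signals to
machine precision; spot noise is multiplicative Gaussian with a given CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lectin import SpotMeasurement
from .motifs import DegeneratePattern, parse_pattern, reverse_complement
from .quant import CtRecord
from .regions import FLANK_BP, GeneModel, Peak, RegionClass


class CapacityError(ValueError):
    """The genome cannot hold the requested genes at the requested spacing."""


class PlacementError(ValueError):
    """A requested region class has no available area to place a peak in."""


class ParameterError(ValueError):
    """A generator parameter is outside its valid range."""


# Lectins commonly printed on 37-lectin glycomics arrays (N- and O-glycan
# binders); WFA, SBA, UEA-I and PHA-E+L are the biologically loaded ones here.
DEFAULT_LECTINS: tuple[str, ...] = (
    "ConA", "WGA", "PNA", "SBA", "DBA", "UEA-I", "RCA120", "PHA-E+L",
    "LCA", "PSA", "GNA", "SNA", "MAL-I", "MAL-II", "Jacalin", "ECA",
    "STL", "LTL", "AAL", "ACA", "BPL", "CSA", "DSA", "EEL", "GSL-I",
    "GSL-II", "HHL", "LEL", "MPL", "NPA", "PTL-I", "PTL-II", "SJA",
    "VVA", "WFA", "PWM", "MNA-M",
)

_TAGS = {"genes": 11, "peaks": 23, "lectin": 37, "ct": 41, "motif": 53}


def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng([_TAGS[tag], int(seed)])


@dataclass
class SyntheticTruth:
    """Planted parameters recorded for recovery tests.

    Only the sections relevant to the generator that produced the truth
    are populated; the rest stay empty.
    """

    seed: int
    planted_region_counts: dict[RegionClass, int] = field(default_factory=dict)
    planted_motifs: list[tuple[str, int, str, str]] = field(default_factory=list)
    true_lectin_folds: dict[str, float] = field(default_factory=dict)
    true_expression_ratios: dict[str, float] = field(default_factory=dict)
    # per planted peak: (peak_id, chrom, region class, membership in
    # {"both", "m1", "m2"})
    peak_records: list[tuple[str, str, RegionClass, str]] = field(default_factory=list)
    # noise-free expected NFI per condition and the NFI-scale fold change
    # (planting a raw fold perturbs the block sum, so the NFI fold differs
    # from the raw fold by the compositional factor)
    expected_nfi: dict[str, dict[str, float]] = field(default_factory=dict)
    expected_nfi_fold: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.planted_region_counts.values()):
            raise ParameterError("planted counts must be >= 0")
        if any(f <= 0 for f in self.true_lectin_folds.values()):
            raise ParameterError("true lectin folds must be > 0")
        if any(r <= 0 for r in self.true_expression_ratios.values()):
            raise ParameterError("true expression ratios must be > 0")


# ---------------------------------------------------------------------------
# gene models

_END_MARGIN = FLANK_BP + 100  # keep flanks inside the chromosome


def gen_gene_models(
    n_genes: int,
    chrom_lengths: dict[str, int],
    min_gap: int = 4000,
    seed: int = 0,
) -> list[GeneModel]:
    """Place non-overlapping stranded gene models on synthetic chromosomes.

    ``min_gap`` is the minimum distance between adjacent gene bodies; at
    the default 4000 bp the 2 kb upstream/downstream flanks of neighbouring
    genes can never overlap, so planted region classes are unambiguous.
    """
    if n_genes < 0:
        raise ParameterError("n_genes must be >= 0")
    if min_gap < 0:
        raise ParameterError("min_gap must be >= 0")
    for c, ln in chrom_lengths.items():
        if ln <= 10_000:
            raise ParameterError(f"chromosome {c} must be longer than 10 kb")
    rng = _rng(seed, "genes")
    if n_genes == 0:
        return []

    lengths = rng.integers(3000, 9001, size=n_genes)
    chroms = sorted(chrom_lengths)
    usable = {c: chrom_lengths[c] - 2 * _END_MARGIN for c in chroms}
    assigned: dict[str, list[int]] = {c: [] for c in chroms}

    for gi in range(n_genes):
        glen = int(lengths[gi])
        feasible = [
            c
            for c in chroms
            if sum(lengths[j] for j in assigned[c]) + len(assigned[c]) * min_gap + glen
            <= usable[c]
        ]
        if not feasible:
            raise CapacityError(
                f"cannot place {n_genes} genes with min_gap={min_gap} "
                f"in the given chromosome lengths"
            )
        weights = np.array([usable[c] for c in feasible], dtype=float)
        assigned[str(rng.choice(feasible, p=weights / weights.sum()))].append(gi)

    genes: list[GeneModel] = []
    for c in chroms:
        idx = assigned[c]
        if not idx:
            continue
        k = len(idx)
        total = sum(int(lengths[j]) for j in idx)
        slack = usable[c] - total - (k - 1) * min_gap
        cuts = np.sort(rng.uniform(0, slack, size=k)) if slack > 0 else np.zeros(k)
        pos = _END_MARGIN + 1
        prev_cut = 0.0
        for j, gi in enumerate(idx):
            pos += int(cuts[j] - prev_cut)
            prev_cut = float(cuts[j])
            glen = int(lengths[gi])
            lo, hi = pos, pos + glen - 1
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _random_exons(lo, hi, rng)
            tss, tes = (lo, hi) if strand == "+" else (hi, lo)
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gi:04d}",
                    chrom=c,
                    strand=strand,
                    tss=tss,
                    tes=tes,
                    exons=exons,
                )
            )
            pos = hi + 1 + min_gap
    genes.sort(key=lambda g: g.gene_id)
    return genes


def _random_exons(
    lo: int, hi: int, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    """1 to 4 exons spanning [lo, hi]; intron segments of >= ~200 bp."""
    n_ex = int(rng.integers(1, 5))
    glen = hi - lo + 1
    n_seg = 2 * n_ex - 1
    if n_ex == 1 or glen < n_seg * 200:
        return ((lo, hi),)
    w = rng.random(n_seg) + 0.25
    seg = np.maximum((w / w.sum() * glen).astype(int), 150)
    seg[-1] = glen - int(seg[:-1].sum())
    if seg[-1] < 150:
        return ((lo, hi),)
    exons = []
    pos = lo
    for i, s in enumerate(seg):
        if i % 2 == 0:
            exons.append((pos, pos + int(s) - 1))
        pos += int(s)
    exons[-1] = (exons[-1][0], hi)
    return tuple(exons)


# ---------------------------------------------------------------------------
# peak experiments

ClassCount = int | tuple[int, int, int]


def gen_peak_experiment(
    genes: list[GeneModel],
    counts_per_class: dict[RegionClass, ClassCount],
    chrom_lengths: dict[str, int],
    fold_range_signal: tuple[float, float] = (2.5, 8.0),
    fold_range_noise: tuple[float, float] = (0.5, 1.9),
    frac_common: float = 1.0,
    n_noise: int = 0,
    peak_len_range: tuple[int, int] = (100, 400),
    seed: int = 0,
) -> tuple[list[Peak], list[Peak], SyntheticTruth]:
    """Plant ChIP peaks of known region class and fold enrichment.

    Each requested count is a number of peak loci placed wholly inside
    regions of that class. A count may be a plain int -- ``frac_common`` of
    the loci (rounded) appear in both the M1 and M2 lists with passing
    folds, the rest split between M1-only and M2-only -- or an explicit
    ``(common, m1_only, m2_only)`` triple. An "M1-only" locus still appears
    in the M2 list, but with a sub-threshold fold there (and vice versa),
    which is how a real peak fails one contrast's filter. ``n_noise``
    additional peaks with sub-threshold folds in both contrasts are added
    to each list. Planted loci never overlap one another.
    """
    if not (fold_range_signal[0] >= 2.0):
        raise ParameterError("signal fold range must start at >= 2.0")
    if not (fold_range_noise[1] < 2.0):
        raise ParameterError("noise fold range must stay below 2.0")
    if not 0.0 <= frac_common <= 1.0:
        raise ParameterError("frac_common must be in [0, 1]")
    rng = _rng(seed, "peaks")
    areas = _class_areas(genes, chrom_lengths)

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    truth = SyntheticTruth(seed=seed)
    m1: list[Peak] = []
    m2: list[Peak] = []
    sig_lo, sig_hi = fold_range_signal
    noi_lo, noi_hi = fold_range_noise

    locus_no = 0
    for cls in sorted(counts_per_class, key=int):
        spec = counts_per_class[cls]
        if isinstance(spec, tuple):
            n_common, n_m1, n_m2 = spec
        else:
            n_common = int(round(frac_common * spec))
            rest = spec - n_common
            n_m1 = (rest + 1) // 2
            n_m2 = rest // 2
        total = n_common + n_m1 + n_m2
        truth.planted_region_counts[cls] = total
        for membership in ["both"] * n_common + ["m1"] * n_m1 + ["m2"] * n_m2:
            locus_no += 1
            pid = f"L{locus_no:05d}"
            chrom, start, end = _place_peak(cls, areas, occupied, peak_len_range, rng)
            f_sig1 = float(rng.uniform(sig_lo, sig_hi))
            f_sig2 = float(rng.uniform(sig_lo, sig_hi))
            f_noi1 = float(rng.uniform(noi_lo, noi_hi))
            f_noi2 = float(rng.uniform(noi_lo, noi_hi))
            fold1 = f_sig1 if membership in ("both", "m1") else f_noi1
            fold2 = f_sig2 if membership in ("both", "m2") else f_noi2
            m1.append(Peak(pid, chrom, start, end, fold1, fold2))
            m2.append(Peak(pid, chrom, start, end, fold1, fold2))
            truth.peak_records.append((pid, chrom, cls, membership))

    for i in range(n_noise):
        chrom = str(rng.choice(sorted(chrom_lengths)))
        length = int(rng.integers(peak_len_range[0], peak_len_range[1] + 1))
        start = int(rng.integers(1, chrom_lengths[chrom] - length))
        pk = Peak(
            f"N{i:05d}",
            chrom,
            start,
            start + length - 1,
            float(rng.uniform(noi_lo, noi_hi)),
            float(rng.uniform(noi_lo, noi_hi)),
        )
        m1.append(pk)
        m2.append(pk)
    return m1, m2, truth


def _class_areas(
    genes: list[GeneModel], chrom_lengths: dict[str, int]
) -> dict[RegionClass, list[tuple[str, int, int]]]:
    areas: dict[RegionClass, list[tuple[str, int, int]]] = {c: [] for c in RegionClass}
    covered: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for g in genes:
        clen = chrom_lengths[g.chrom]
        up = g.upstream_2k(clen)
        if up:
            areas[RegionClass.UP2K].append((g.chrom, *up))
            covered[g.chrom].append(up)
        down = g.downstream_2k(clen)
        if down:
            areas[RegionClass.DOWN2K].append((g.chrom, *down))
            covered[g.chrom].append(down)
        for ex in g.exons:
            areas[RegionClass.EXON].append((g.chrom, *ex))
        for intr in g.introns():
            areas[RegionClass.INTRON].append((g.chrom, *intr))
        covered[g.chrom].append(g.body)
    for chrom, iv in covered.items():
        pos = 1
        for lo, hi in sorted(iv):
            if lo - 1 >= pos:
                areas[RegionClass.INTERGENIC].append((chrom, pos, lo - 1))
            pos = max(pos, hi + 1)
        if pos <= chrom_lengths[chrom]:
            areas[RegionClass.INTERGENIC].append((chrom, pos, chrom_lengths[chrom]))
    return areas


def _place_peak(
    cls: RegionClass,
    areas: dict[RegionClass, list[tuple[str, int, int]]],
    occupied: dict[str, list[tuple[int, int]]],
    peak_len_range: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    candidates = [a for a in areas[cls] if a[2] - a[1] + 1 >= 30]
    if not candidates:
        raise PlacementError(f"no available area to place a peak in class {cls.name}")
    for _ in range(200):
        chrom, lo, hi = candidates[int(rng.integers(len(candidates)))]
        avail = hi - lo + 1
        length = min(avail, int(rng.integers(peak_len_range[0], peak_len_range[1] + 1)))
        start = int(rng.integers(lo, hi - length + 2))
        end = start + length - 1
        if all(end < s or start > e for s, e in occupied[chrom]):
            occupied[chrom].append((start, end))
            return chrom, start, end
    raise PlacementError(f"could not place a non-overlapping peak in class {cls.name}")


# ---------------------------------------------------------------------------
# lectin arrays


def gen_lectin_dataset(
    lectin_ids: tuple[str, ...] = DEFAULT_LECTINS,
    true_folds: dict[str, float] | None = None,
    bg_mean: float = 100.0,
    bg_sd: float = 10.0,
    n_slides: int = 3,
    blocks_per_slide: int = 3,
    spots_per_lectin_per_block: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, list[SpotMeasurement]], SyntheticTruth]:
    """Generate paired control/treatment lectin-array spot grids.

    Treatment signal for each lectin is the control signal scaled by its
    planted fold (default 1.0). Foregrounds carry multiplicative Gaussian
    noise at ``noise_cv``; each spot's foreground additionally contains its
    block's realised mean measured background, so averaged-background
    subtraction recovers the noisy signal exactly and the zero-noise limit
    is exact. Returns spot lists keyed by condition plus the truth.
    """
    if bg_sd < 0:
        raise ParameterError("bg_sd must be >= 0")
    if noise_cv < 0:
        raise ParameterError("noise_cv must be >= 0")
    folds = {lec: 1.0 for lec in lectin_ids}
    for lec, f in (true_folds or {}).items():
        if lec not in folds:
            raise ParameterError(f"unknown lectin {lec!r} in true_folds")
        if f <= 0:
            raise ParameterError("true folds must be > 0")
        folds[lec] = float(f)
    rng = _rng(seed, "lectin")

    # per-lectin base signal, log-uniform over a realistic dynamic range
    base = {lec: float(10 ** rng.uniform(3.0, 4.5)) for lec in lectin_ids}
    signal = {
        "control": {lec: base[lec] for lec in lectin_ids},
        "treatment": {lec: base[lec] * folds[lec] for lec in lectin_ids},
    }

    spots_by_condition: dict[str, list[SpotMeasurement]] = {}
    for cond in ("control", "treatment"):
        spots: list[SpotMeasurement] = []
        for s in range(1, n_slides + 1):
            for b in range(1, blocks_per_slide + 1):
                n_block = len(lectin_ids) * spots_per_lectin_per_block
                bgs = rng.normal(bg_mean, bg_sd, size=n_block).clip(min=0.0)
                bg_block_mean = float(bgs.mean())
                i = 0
                for lec in lectin_ids:
                    for _ in range(spots_per_lectin_per_block):
                        noise = 1.0 + noise_cv * float(rng.standard_normal())
                        fg = max(signal[cond][lec] * max(noise, 1e-6) + bg_block_mean, 0.0)
                        spots.append(
                            SpotMeasurement(
                                slide_id=f"slide{s}",
                                block_id=f"block{b}",
                                lectin_id=lec,
                                foreground=fg,
                                background=float(bgs[i]),
                            )
                        )
                        i += 1
        spots_by_condition[cond] = spots

    truth = SyntheticTruth(seed=seed, true_lectin_folds=folds)
    for cond in ("control", "treatment"):
        total = sum(signal[cond].values())
        truth.expected_nfi[cond] = {lec: signal[cond][lec] / total for lec in lectin_ids}
    truth.expected_nfi_fold = {
        lec: truth.expected_nfi["treatment"][lec] / truth.expected_nfi["control"][lec]
        for lec in lectin_ids
    }
    return spots_by_condition, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables

REFERENCE_GENE = "ACTB"


def gen_ct_dataset(
    true_ratios: dict[str, float],
    ct_ref_base: float = 18.0,
    noise_sd: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
) -> tuple[list[CtRecord], SyntheticTruth]:
    """Generate Ct tables encoding planted expression ratios.

    A planted treated/control ratio r is encoded as a target-gene Ct shift
    of -log2(r) in the treated condition, on top of a per-gene baseline
    offset from the reference gene; Gaussian noise of ``noise_sd`` cycles
    is added per replicate.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    for g, r in true_ratios.items():
        if r <= 0:
            raise ParameterError(f"true ratio for {g} must be > 0")
    rng = _rng(seed, "ct")

    def reps(center: float) -> tuple[float, ...]:
        return tuple(float(center + rng.normal(0.0, noise_sd)) for _ in range(n_reps))

    records: list[CtRecord] = []
    for cond in ("control", "treatment"):
        records.append(
            CtRecord(
                sample_id=cond,
                condition=cond,  # type: ignore[arg-type]
                gene_id=REFERENCE_GENE,
                role="reference",
                ct_replicates=reps(ct_ref_base),
            )
        )
    for gene in sorted(true_ratios):
        target_base = ct_ref_base + float(rng.uniform(2.0, 8.0))
        shift = -float(np.log2(true_ratios[gene]))
        for cond, center in (
            ("control", target_base),
            ("treatment", target_base + shift),
        ):
            records.append(
                CtRecord(
                    sample_id=cond,
                    condition=cond,  # type: ignore[arg-type]
                    gene_id=gene,
                    role="target",
                    ct_replicates=reps(center),
                )
            )
    truth = SyntheticTruth(seed=seed, true_expression_ratios=dict(true_ratios))
    return records, truth


# ---------------------------------------------------------------------------
# sequences with planted motifs

_BASES = np.array(list("ACGT"))


def gen_motif_sequences(
    pattern_texts: list[str],
    n_seqs: int = 10,
    seq_length: int = 500,
    plants_per_seq: int = 1,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Random sequences with planted degenerate-motif occurrences.

    Each sequence receives ``plants_per_seq`` occurrences of randomly
    chosen patterns at non-overlapping random offsets, each on a random
    strand (a minus-strand plant inserts a realisation of the pattern's
    reverse complement). The truth lists every plant as
    (sequence_id, offset, strand, pattern_text). Background bases are
    uniform, so additional chance matches may occur beyond the planted
    ones; the guarantee is that every planted occurrence is present.
    """
    if not pattern_texts:
        raise ParameterError("need at least one pattern")
    patterns = [(t, parse_pattern(t)) for t in pattern_texts]
    max_len = max(len(p) for _, p in patterns)
    if seq_length < max_len:
        raise ParameterError("seq_length shorter than the longest pattern")
    rng = _rng(seed, "motif")
    truth = SyntheticTruth(seed=seed)
    out: list[tuple[str, str]] = []
    for i in range(n_seqs):
        seq_id = f"seq_{i:03d}"
        seq = list(rng.choice(_BASES, size=seq_length))
        taken: list[tuple[int, int]] = []
        for _ in range(plants_per_seq):
            text, pat = patterns[int(rng.integers(len(patterns)))]
            strand = "+" if rng.random() < 0.5 else "-"
            oriented = pat if strand == "+" else reverse_complement(pat)
            for _try in range(100):
                off = int(rng.integers(0, seq_length - len(pat) + 1))
                if all(off + len(pat) <= s or off >= e for s, e in taken):
                    break
            else:
                raise PlacementError(f"could not place motif in {seq_id}")
            taken.append((off, off + len(pat)))
            for j, allowed in enumerate(oriented.positions):
                seq[off + j] = allowed[int(rng.integers(len(allowed)))]
            truth.planted_motifs.append((seq_id, off, strand, text))
        out.append((seq_id, "".join(seq)))
    return out, truth
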