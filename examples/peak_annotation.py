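"""Classify ChIP peaks into promoter/gene-body regions and intersect the
two control contrasts.

Builds a small synthetic genome, plants peaks of known region class with
fold enrichments against the IgG (M1) and input (M2) controls, then runs
the classification -> >2-fold filter -> intersection chain.
"""

from chipglyco import (
    RegionClass,
    RegionIndex,
    chromosome_distribution,
    classify_peak,
    filter_and_intersect,
    gen_gene_models,
    gen_peak_experiment,
    interval_length,
)

chrom_lengths = {"chr1": 2_000_000, "chr2": 2_000_000}
genes = gen_gene_models(60, chrom_lengths, seed=1)
m1, m2, truth = gen_peak_experiment(
    genes,
    {RegionClass.UP2K: (10, 5, 3), RegionClass.EXON: 6, RegionClass.INTERGENIC: 4},
    chrom_lengths,
    n_noise=15,
    seed=1,
)

index = RegionIndex(genes, chrom_lengths)
up1 = [p for p in m1 if classify_peak(p, index) == RegionClass.UP2K]
up2 = [p for p in m2 if classify_peak(p, index) == RegionClass.UP2K]
cmp_ = filter_and_intersect(up1, up2, threshold=2.0)

print(f"Up2k peaks >2-fold vs IgG (M1):   {len(cmp_.m1_pass)}")
print(f"Up2k peaks >2-fold vs input (M2): {len(cmp_.m2_pass)}")
print(f"common to both contrasts:         {len(cmp_.common)}")
print(f"per-chromosome (M1, M2): {chromosome_distribution(cmp_, sorted(chrom_lengths))}")
# The common set is the high-confidence promoter-bound set: peaks enriched
# over BOTH controls in the 2 kb upstream of a TSS. Here it recovers the
# 10 planted dual-passing loci exactly.

print()
print("promoter interval arithmetic, 1-based closed:")
print(f"  GRCh38:11:94541840:94543879:1 -> {interval_length('GRCh38:11:94541840:94543879:1')} bp")
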