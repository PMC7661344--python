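"""Readers and writers for the pipeline's file surfaces.

Gene models travel as GFF3 (full exon structure) or BED6 (body +
strand only); peaks as a BED-like TSV with the two fold columns, or as a
raw-count TSV from which fold enrichments are computed; sequences as
FASTA; lectin spot grids, Ct tables, and luciferase readings as headered
TSV; planted truth as a YAML sidecar.

All genomic coordinates in these files are 1-based fully closed except
BED6, which keeps its native 0-based half-open convention.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .lectin import DifferentialGlycanCall, LectinSummary, SpotMeasurement
from .quant import CtRecord, LuciferaseRecord
from .regions import GeneModel, Peak, RegionClass, compute_fold_enrichment
from .simulate import SyntheticTruth

# --- gene models -----------------------------------------------------------


def write_genes_gff3(genes: list[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lo, hi = g.body
        lines.append(
            "\t".join(
                [g.chrom, "chipglyco", "gene", str(lo), str(hi), ".", g.strand, ".",
                 f"ID={g.gene_id}"]
            )
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                "\t".join(
                    [g.chrom, "chipglyco", "exon", str(s), str(e), ".", g.strand, ".",
                     f"ID={g.gene_id}.exon{i};Parent={g.gene_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        exons = tuple(
            (ex.start, ex.end) for ex in db.children(feat, featuretype="exon", order_by="start")
        ) or ((feat.start, feat.end),)
        if feat.strand == "+":
            tss, tes = feat.start, feat.end
        else:
            tss, tes = feat.end, feat.start
        genes.append(
            GeneModel(
                gene_id=feat.id, chrom=feat.seqid, strand=feat.strand,
                tss=tss, tes=tes, exons=exons,
            )
        )
    genes.sort(key=lambda g: g.gene_id)
    return genes


def write_genes_bed6(genes: list[GeneModel], path: str | Path) -> None:
    """BED6 export: gene bodies only (0-based half-open, score 0)."""
    rows = []
    for g in genes:
        lo, hi = g.body
        rows.append(f"{g.chrom}\t{lo - 1}\t{hi}\t{g.gene_id}\t0\t{g.strand}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_genes_bed6(path: str | Path) -> list[GeneModel]:
    """BED6 genes come back as single-exon models (BED6 has no exon rows)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end, name, _score, strand = line.split("\t")[:6]
        lo, hi = int(start) + 1, int(end)
        tss, tes = (lo, hi) if strand == "+" else (hi, lo)
        genes.append(
            GeneModel(gene_id=name, chrom=chrom, strand=strand, tss=tss, tes=tes,
                      exons=((lo, hi),))
        )
    return genes


# --- peaks -----------------------------------------------------------------

PEAK_COLUMNS = ["peak_id", "chrom", "start", "end", "fold_m1", "fold_m2"]


def write_peaks_tsv(peaks: list[Peak], path: str | Path) -> None:
    pd.DataFrame(
        [(p.peak_id, p.chrom, p.start, p.end, p.fold_m1, p.fold_m2) for p in peaks],
        columns=PEAK_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_peaks_tsv(path: str | Path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak TSV missing columns: {sorted(missing)}")
    return [
        Peak(str(r.peak_id), str(r.chrom), int(r.start), int(r.end),
             float(r.fold_m1), float(r.fold_m2))
        for r in df.itertuples()
    ]


def read_peak_counts_tsv(path: str | Path, pseudocount: float = 1.0) -> list[Peak]:
    """Raw-count peak table -> peaks with computed fold enrichments.

    Expected columns: peak_id, chrom, start, end, treat_count, igg_count,
    input_count, treat_depth, igg_depth, input_depth. fold_m1 is treatment
    vs. IgG, fold_m2 treatment vs. input.
    """
    df = pd.read_csv(path, sep="\t")
    peaks = []
    for r in df.itertuples():
        fold_m1 = compute_fold_enrichment(
            r.treat_count, r.igg_count, r.treat_depth, r.igg_depth, pseudocount
        )
        fold_m2 = compute_fold_enrichment(
            r.treat_count, r.input_count, r.treat_depth, r.input_depth, pseudocount
        )
        peaks.append(
            Peak(str(r.peak_id), str(r.chrom), int(r.start), int(r.end), fold_m1, fold_m2)
        )
    return peaks


# --- sequences -------------------------------------------------------------


def write_fasta(sequences: list[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# --- lectin spots ----------------------------------------------------------

SPOT_COLUMNS = ["slide", "block", "lectin", "foreground", "background"]


def write_spots_tsv(spots: list[SpotMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        [(s.slide_id, s.block_id, s.lectin_id, s.foreground, s.background) for s in spots],
        columns=SPOT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_spots_tsv(path: str | Path) -> list[SpotMeasurement]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spot TSV missing columns: {sorted(missing)}")
    return [
        SpotMeasurement(str(r.slide), str(r.block), str(r.lectin),
                        float(r.foreground), float(r.background))
        for r in df.itertuples()
    ]


def read_spots_gpr(path: str | Path, slide_id: str, block_col: str = "Block",
                   name_col: str = "Name", f_col: str = "F532 Median",
                   b_col: str = "B532 Median") -> list[SpotMeasurement]:
    """Thin GenePix-results adapter: maps the F/B median columns of a
    tab-separated GPR-style table onto SpotMeasurement."""
    df = pd.read_csv(path, sep="\t")
    return [
        SpotMeasurement(slide_id, str(row[block_col]), str(row[name_col]),
                        float(row[f_col]), float(row[b_col]))
        for _, row in df.iterrows()
    ]


# --- Ct and luciferase tables ---------------------------------------------


def write_ct_tsv(records: list[CtRecord], path: str | Path) -> None:
    rows = [
        (r.sample_id, r.condition, r.gene_id, r.role, i + 1, ct)
        for r in records
        for i, ct in enumerate(r.ct_replicates)
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "condition", "gene_id", "role", "replicate", "ct"]
    ).to_csv(path, sep="\t", index=False)


def read_ct_tsv(path: str | Path) -> list[CtRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for (sample, cond, gene, role), grp in df.groupby(
        ["sample_id", "condition", "gene_id", "role"], sort=True
    ):
        cts = tuple(grp.sort_values("replicate")["ct"].astype(float))
        records.append(CtRecord(str(sample), str(cond), str(gene), str(role), cts))
    return records


def write_luciferase_tsv(records: list[LuciferaseRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.construct_id, r.firefly, r.renilla, r.cell_count) for r in records],
        columns=["construct_id", "firefly", "renilla", "cell_count"],
    ).to_csv(path, sep="\t", index=False)


def read_luciferase_tsv(path: str | Path) -> list[LuciferaseRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        LuciferaseRecord(str(r.construct_id), float(r.firefly), float(r.renilla),
                         float(r.cell_count))
        for r in df.itertuples()
    ]


# --- truth sidecar ---------------------------------------------------------


def write_truth_yaml(truth: SyntheticTruth, path: str | Path) -> None:
    doc = {
        "seed": truth.seed,
        "planted_region_counts": {c.name: n for c, n in truth.planted_region_counts.items()},
        "planted_motifs": [list(t) for t in truth.planted_motifs],
        "true_lectin_folds": dict(truth.true_lectin_folds),
        "true_expression_ratios": dict(truth.true_expression_ratios),
        "peak_records": [[pid, chrom, cls.name, mem] for pid, chrom, cls, mem in truth.peak_records],
        "expected_nfi": {c: dict(v) for c, v in truth.expected_nfi.items()},
        "expected_nfi_fold": dict(truth.expected_nfi_fold),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_truth_yaml(path: str | Path) -> SyntheticTruth:
    doc = yaml.safe_load(Path(path).read_text())
    return SyntheticTruth(
        seed=doc["seed"],
        planted_region_counts={
            RegionClass[k]: v for k, v in doc.get("planted_region_counts", {}).items()
        },
        planted_motifs=[tuple(t) for t in doc.get("planted_motifs", [])],
        true_lectin_folds=doc.get("true_lectin_folds", {}),
        true_expression_ratios=doc.get("true_expression_ratios", {}),
        peak_records=[
            (pid, chrom, RegionClass[cls], mem)
            for pid, chrom, cls, mem in doc.get("peak_records", [])
        ],
        expected_nfi=doc.get("expected_nfi", {}),
        expected_nfi_fold=doc.get("expected_nfi_fold", {}),
    )


# --- result tables ---------------------------------------------------------


def summaries_table(summaries: list[LectinSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.lectin_id, s.condition, s.mean_nfi, s.sd_nfi, s.n_blocks) for s in summaries],
        columns=["lectin", "condition", "mean_nfi", "sd_nfi", "n_blocks"],
    )


def differential_table(calls: list[DifferentialGlycanCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.lectin_id, c.fold_change, c.p_value, c.call, c.tier) for c in calls],
        columns=["lectin", "fold_change", "p_value", "call", "tier"],
    )
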