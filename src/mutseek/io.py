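"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython; VCF 4.2 read via cyvcf2 (writing is a small text
emitter — the tables carry only an AD FORMAT field); GFF3 read via
gffutils (1-based inclusive coordinates); variant/marker/panel tables as
TSV and Ct tables as CSV via pandas.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GeneModel
from .mutmap import VARIANT_COLUMNS


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(chromosomes: Mapping[str, str], path: str, width: int = 80) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in chromosomes.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(gene_models: Iterable[GeneModel], path: str, source: str = "mutseek") -> None:
    """Gene models as GFF3 (gene/mRNA/exon/CDS, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in gene_models:
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\t{source}\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            # CDS phase: bases of the previous codon left over, in
            # transcription order
            segs = g.cds if g.strand == "+" else list(reversed(g.cds))
            phase = 0
            rows = []
            for s, e in segs:
                rows.append((s, e, phase))
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for i, (s, e, ph) in enumerate(sorted(rows), 1):
                fh.write(
                    f"{g.chrom}\t{source}\tCDS\t{s}\t{e}\t.\t{g.strand}\t{ph}\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


def read_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = []
        cds = []
        for child in db.children(gene, featuretype="exon"):
            exons.append((child.start, child.end))
        for child in db.children(gene, featuretype="CDS"):
            cds.append((child.start, child.end))
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=sorted(exons),
                cds=sorted(cds) if cds else None,
            )
        )
    return models


# ---------------------------------------------------------------------------
# VCF 4.2 with AD, and the TSV dialect
# ---------------------------------------------------------------------------

def write_vcf(
    variants: pd.DataFrame,
    path: str,
    sample: str = "pool",
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Variant table (chrom, pos, ref, alt, ref_depth, alt_depth) as VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mutseek\n")
        for name, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for row in variants.sort_values(["chrom", "pos"]).itertuples():
            total = row.ref_depth + row.alt_depth
            if row.alt_depth == 0:
                gt = "0/0"
            elif row.ref_depth == 0:
                gt = "1/1"
            else:
                gt = "0/1"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                f"GT:AD\t{gt}:{row.ref_depth},{row.alt_depth}\n"
            )


def read_vcf(path: str) -> pd.DataFrame:
    """First-sample AD depths of a VCF into the standard variant frame."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(path):
        ad = v.format("AD")
        ref_d, alt_d = (int(ad[0][0]), int(ad[0][1])) if ad is not None else (0, 0)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0] if v.ALT else ".", ref_d, alt_d))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_variant_tsv(variants: pd.DataFrame, path: str) -> None:
    variants[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_variant_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant TSV lacks columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Marker, panel and Ct tables
# ---------------------------------------------------------------------------

def write_marker_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index_label="individual")


def read_marker_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual")


def write_panel_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index_label="line")


def read_panel_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="line")


def write_ct_csv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)


def read_ct_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_simulation(outdir: str, genome, mutant: pd.DataFrame, wt: pd.DataFrame,
                     markers: pd.DataFrame, panel: pd.DataFrame, ct: pd.DataFrame) -> None:
    """Write a full simulated dataset into a directory."""
    os.makedirs(outdir, exist_ok=True)
    contigs = {name: len(seq) for name, seq in genome.chromosomes.items()}
    write_fasta(genome.chromosomes, os.path.join(outdir, "genome.fasta"))
    write_gff3(genome.gene_models, os.path.join(outdir, "genes.gff3"))
    write_vcf(mutant, os.path.join(outdir, "mutant_pool.vcf"), sample="mutant_pool",
              contig_lengths=contigs)
    write_vcf(wt, os.path.join(outdir, "wt_parent.vcf"), sample="wt_parent",
              contig_lengths=contigs)
    write_variant_tsv(mutant, os.path.join(outdir, "mutant_pool.tsv"))
    write_variant_tsv(wt, os.path.join(outdir, "wt_parent.tsv"))
    write_marker_tsv(markers, os.path.join(outdir, "markers.tsv"))
    write_panel_tsv(panel, os.path.join(outdir, "panel.tsv"))
    write_ct_csv(ct, os.path.join(outdir, "ct_table.csv"))
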