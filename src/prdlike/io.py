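"""File-format boundaries: FASTA, GFF3 subset, VCF v4.2 subset, TSV, BED.

Internal coordinates are 0-based half-open throughout the package; conversion
to the 1-based inclusive conventions of GFF3 and VCF happens only here.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genemodel import GeneModel


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in records.items()),
        str(path),
        "fasta",
    )


def write_gff3(models: list[GeneModel], path) -> None:
    """Write gene models as a GFF3 subset (gene/mRNA/exon/CDS, phases filled)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, m in enumerate(models):
            if not m.exons:
                continue
            gid = f"gene{i}"
            start, end = m.exons[0][0] + 1, m.exons[-1][1]
            base = f"{m.contig_id}\tprdlike\t"
            fh.write(f"{base}gene\t{start}\t{end}\t.\t{m.strand}\t.\tID={gid};status={m.status}\n")
            fh.write(f"{base}mRNA\t{start}\t{end}\t.\t{m.strand}\t.\tID={gid}.t1;Parent={gid}\n")
            phase = 0
            for j, (a, b) in enumerate(m.exons):
                fh.write(
                    f"{base}exon\t{a + 1}\t{b}\t.\t{m.strand}\t.\tParent={gid}.t1\n"
                )
                fh.write(
                    f"{base}CDS\t{a + 1}\t{b}\t.\t{m.strand}\t{phase}\tParent={gid}.t1\n"
                )
                phase = (3 - ((b - a) - phase) % 3) % 3
    return None


def read_gff3_models(path) -> list[GeneModel]:
    """Read back the GFF3 subset written by :func:`write_gff3`."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            contig, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = fields["ID"]
                order.append(gid)
                genes[gid] = {
                    "contig": contig,
                    "strand": strand,
                    "status": fields.get("status", "intact"),
                    "exons": [],
                }
            elif ftype == "exon":
                gid = fields["Parent"].rsplit(".", 1)[0]
                genes[gid]["exons"].append((int(start) - 1, int(end)))
    out = []
    for gid in order:
        g = genes[gid]
        exons = sorted(g["exons"])
        out.append(GeneModel(g["contig"], g["strand"], exons, status=g["status"]))
    return out


def write_vcf(variants: pd.DataFrame, genotypes, individuals: list[str], path) -> None:
    """Write a VCF v4.2 subset: CHROM POS ID REF ALT QUAL FILTER INFO FORMAT GT.

    ``variants`` needs columns gene_id (used as CHROM), cds_pos (1-based POS),
    ref, alt; ``genotypes`` is individuals x variants with 0/1/2 (-1 missing).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(variants["gene_id"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(individuals) + "\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for k, row in enumerate(variants.itertuples(index=False)):
            gts = "\t".join(gt_strings[int(g)] for g in genotypes[:, k])
            fh.write(f"{row.gene_id}\t{row.cds_pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path):
    """Read the VCF subset via pysam; returns (variants DataFrame, genotype
    matrix individuals x variants, individual ids)."""
    import numpy as np
    import pysam

    rows, gt_cols = [], []
    with pysam.VariantFile(str(path)) as vf:
        individuals = list(vf.header.samples)
        for rec in vf:
            for alt in rec.alts or ():
                rows.append((rec.chrom, rec.pos, rec.ref, alt))
                col = []
                for sample in individuals:
                    gt = rec.samples[sample].get("GT", (None, None))
                    if gt is None or any(a is None for a in gt):
                        col.append(-1)
                    else:
                        col.append(sum(1 for a in gt if a >= 1))
                gt_cols.append(col)
    variants = pd.DataFrame(rows, columns=["gene_id", "cds_pos", "ref", "alt"])
    genotypes = np.array(gt_cols, dtype=np.int8).T if gt_cols else np.zeros((len(individuals), 0), np.int8)
    return variants, genotypes, individuals


def write_bed(hits, chrom: str, path, motif_len: int) -> None:
    """Motif hits as BED (0-based half-open, strand in column 6)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{chrom}\t{h.position}\t{h.position + motif_len}\t{h.motif}\t.\t{h.strand}\n")
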