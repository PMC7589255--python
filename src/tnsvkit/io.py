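"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython SeqIO (60-column wrap), GFF3 read via gffutils, VCF read
via pysam. GFF3 and VCF writing are simple text emission and are done here
directly. Coordinates are 1-based inclusive in both GFF3 and VCF.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variant_effects import EffectAnnotation, GeneModel, VariantRecord, VariantTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_vcf",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "write_annotations",
    "read_key_value_config",
    "write_key_value_config",
]


# -- FASTA ------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(reference: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# -- GFF3 -------------------------------------------------------------------


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Emit a gene -> mRNA -> CDS hierarchy with populated phase column."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chromosome, g.span[0], g.gene_id)):
        lo, hi = g.span
        attrs = f"ID={g.gene_id}"
        if g.family:
            attrs += f";family={g.family}"
        lines.append(
            f"{g.chromosome}\ttnsvkit\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t{attrs}"
        )
        mrna_id = f"{g.gene_id}.t1"
        lines.append(
            f"{g.chromosome}\ttnsvkit\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
            f"ID={mrna_id};Parent={g.gene_id}"
        )
        segs = g.cds_segments if g.strand == "+" else tuple(reversed(g.cds_segments))
        phase = 0
        for i, (a, b) in enumerate(segs, 1):
            lines.append(
                f"{g.chromosome}\ttnsvkit\tCDS\t{a}\t{b}\t.\t{g.strand}\t{phase}\t"
                f"ID={mrna_id}.cds{i};Parent={mrna_id}"
            )
            phase = (3 - ((b - a + 1 - phase) % 3)) % 3
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        segs = tuple(
            (c.start, c.end)
            for c in db.children(feat, featuretype="CDS", order_by="start")
        )
        family = feat.attributes.get("family", [""])[0]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chromosome=feat.seqid,
                strand=feat.strand,
                cds_segments=segs,
                family=family,
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.span[0], g.gene_id))
    return genes


# -- VCF --------------------------------------------------------------------

_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(
    table: VariantTable,
    path: str | os.PathLike,
    reference_name: str = "synthetic",
) -> None:
    """Write a minimal VCF v4.2 with unphased GT-only FORMAT."""
    contigs = sorted({r.chromosome for r in table.records})
    header = [
        "##fileformat=VCFv4.2",
        f"##source=tnsvkit;reference={reference_name}",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples),
    ]
    lines = []
    for r in sorted(table.records, key=lambda r: (r.chromosome, r.pos, r.alt)):
        gts = "\t".join(_GT_STRINGS[int(d)] for d in r.genotypes)
        lines.append(
            f"{r.chromosome}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(header + lines) + "\n")


def read_vcf(path: str | os.PathLike) -> VariantTable:
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        records = []
        for rec in vf:
            alts = rec.alts or ()
            for alt_i, alt in enumerate(alts, start=1):
                dosages = np.empty(len(samples), dtype=np.int8)
                for i, s in enumerate(samples):
                    gt = rec.samples[s].get("GT", (None, None))
                    if gt is None or any(a is None for a in gt):
                        dosages[i] = -1
                    else:
                        dosages[i] = sum(1 for a in gt if a == alt_i)
                records.append(
                    VariantRecord(rec.chrom, rec.pos, rec.ref, alt, dosages)
                )
    return VariantTable(samples=samples, records=records)


# -- tabular ----------------------------------------------------------------


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "accession" in df.columns:
        df = df.set_index("accession")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="accession")


def write_annotations(
    annotations: Sequence[EffectAnnotation], path: str | os.PathLike
) -> None:
    rows = [
        {
            "chrom": a.chromosome,
            "pos": a.pos,
            "ref": a.ref,
            "alt": a.alt,
            "gene": a.gene_id or ".",
            "class": a.effect_class,
            "aa_change": a.aa_change or ".",
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- flat key-value config --------------------------------------------------


def read_key_value_config(path: str | os.PathLike) -> dict[str, str]:
    """Parse ``key = value`` lines; '#' starts a comment; keys are verbatim."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw.rstrip()!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def write_key_value_config(config: Mapping[str, object], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for key, value in config.items():
            fh.write(f"{key} = {value}\n")
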