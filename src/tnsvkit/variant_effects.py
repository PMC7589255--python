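"""Strand-aware functional annotation of variants against gene models.

Classifies SNPs and small indels relative to the coding sequence of a gene
model into the classes used by a candidate-gene burden analysis:
``synonymous``, ``missense``, ``nonsense``, ``stop_loss``, ``start_lost``,
``splice_site``, ``frameshift``, ``inframe_indel``, ``intronic`` and
``intergenic``.

All genomic coordinates are 1-based inclusive, matching both GFF3 and VCF.
The splice-site window is the 2 intronic bp flanking each CDS junction (the
canonical GT/AG positions). The codon table is the standard nuclear code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GeneModel",
    "VariantRecord",
    "VariantTable",
    "EffectAnnotation",
    "DataIntegrityError",
    "CODON_TABLE",
    "STOP_CODONS",
    "extract_cds",
    "translate_cds",
    "annotate_variant",
    "annotate_table",
    "reverse_complement",
    "normalize_indel",
]

# Standard nuclear genetic code, '*' marks stop.
CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DataIntegrityError(ValueError):
    """Raised when a variant's REF allele disagrees with the reference genome."""


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript protein-coding gene model.

    ``cds_segments`` are (start, end) pairs, 1-based inclusive, sorted by
    genomic start and non-overlapping. For minus-strand genes the coding
    sequence is read from the last segment backwards on the reverse
    complement.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    family: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        segs = tuple(sorted((int(a), int(b)) for a, b in self.cds_segments))
        for (a, b) in segs:
            if a > b or a < 1:
                raise ValueError(f"bad CDS segment ({a}, {b}) in {self.gene_id}")
        for (_, b1), (a2, _) in zip(segs, segs[1:]):
            if a2 <= b1:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        object.__setattr__(self, "cds_segments", segs)

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    def validate_cds(self, reference: Mapping[str, str]) -> list[str]:
        """Return a list of gene-model warnings (violations are flagged, not fatal)."""
        problems = []
        if self.cds_length % 3 != 0:
            problems.append("CDS length not divisible by 3")
        cds = extract_cds(self, reference)
        if not cds.startswith("ATG"):
            problems.append("CDS does not start with ATG")
        if len(cds) >= 3 and cds[-3:] not in STOP_CODONS:
            problems.append("CDS does not end with a stop codon")
        body = cds[: len(cds) - len(cds) % 3][:-3]
        for i in range(0, len(body) - 2, 3):
            if body[i : i + 3] in STOP_CODONS:
                problems.append(f"internal stop codon at codon {i // 3 + 1}")
                break
        return problems


@dataclass
class VariantRecord:
    """One biallelic variant with per-accession diploid genotypes.

    ``genotypes`` holds alt-allele dosages: 0 (hom-ref), 1 (het), 2 (hom-alt),
    -1 (missing), aligned with the owning table's sample list.
    """

    chromosome: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.pos, self.ref, self.alt)


@dataclass
class VariantTable:
    """A panel of variants sharing one accession (sample) ordering."""

    samples: list[str]
    records: list[VariantRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def dosage_matrix(self) -> np.ndarray:
        """(n_sites, n_samples) int8 matrix of alt dosages, -1 = missing."""
        if not self.records:
            return np.zeros((0, len(self.samples)), dtype=np.int8)
        return np.vstack([r.genotypes for r in self.records])


@dataclass
class EffectAnnotation:
    """Functional consequence of one variant on one gene (or intergenic)."""

    chromosome: str
    pos: int
    ref: str
    alt: str
    gene_id: Optional[str]
    effect_class: str
    aa_change: Optional[str] = None
    premature_stop: bool = False
    truncated_length: Optional[int] = None

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# CDS extraction and coordinate arithmetic


def extract_cds(gene: GeneModel, reference: Mapping[str, str]) -> str:
    """Spliced, strand-oriented coding sequence of ``gene``.

    Minus-strand genes are reverse-complemented; length equals the sum of
    segment lengths. Raises ``IndexError`` for out-of-bounds segments.
    """
    chrom = reference[gene.chromosome]
    pieces = []
    for a, b in gene.cds_segments:
        if b > len(chrom):
            raise IndexError(
                f"CDS segment ({a}, {b}) of {gene.gene_id} exceeds "
                f"{gene.chromosome} length {len(chrom)}"
            )
        pieces.append(chrom[a - 1 : b])
    cds = "".join(pieces).upper()
    return reverse_complement(cds) if gene.strand == "-" else cds


def translate_cds(cds: str) -> str:
    """Translate codon-by-codon; trailing partial codon ignored; '*' = stop."""
    return "".join(
        CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3)
    )


class _GeneContext:
    """Precomputed coordinate maps for repeated annotation against one gene."""

    def __init__(self, gene: GeneModel, reference: Mapping[str, str]):
        self.gene = gene
        self.cds = extract_cds(gene, reference)
        # genomic position of each CDS index (5'->3' in coding orientation)
        genomic = []
        for a, b in gene.cds_segments:
            genomic.extend(range(a, b + 1))
        if gene.strand == "-":
            genomic.reverse()
        self.genomic_of_ci = genomic
        self.ci_of_genomic = {p: i for i, p in enumerate(genomic)}
        self.splice_positions = self._splice_positions()
        self.ref_protein = translate_cds(self.cds)

    def _splice_positions(self) -> frozenset[int]:
        pos = set()
        segs = self.gene.cds_segments
        for (_, b1), (a2, _) in zip(segs, segs[1:]):
            pos.update((b1 + 1, b1 + 2, a2 - 2, a2 - 1))
        return frozenset(pos)


_CONTEXT_CACHE: dict[tuple[int, str, tuple], _GeneContext] = {}


def _context(gene: GeneModel, reference: Mapping[str, str]) -> _GeneContext:
    key = (id(reference), gene.gene_id, gene.cds_segments, gene.strand)
    ctx = _CONTEXT_CACHE.get(key)
    if ctx is None:
        ctx = _GeneContext(gene, reference)
        if len(_CONTEXT_CACHE) > 4096:
            _CONTEXT_CACHE.clear()
        _CONTEXT_CACHE[key] = ctx
    return ctx


# ---------------------------------------------------------------------------
# Indel normalization


def normalize_indel(
    pos: int, ref: str, alt: str, chrom_seq: str
) -> tuple[int, str, str]:
    """Left-align and minimally represent an indel against the reference.

    Trims shared suffix then shared prefix (keeping VCF's one anchor base for
    pure insertions/deletions), then shifts left while the variant is
    equivalent, i.e. while the base preceding the anchor equals the last base
    of the longer allele.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if len(ref) != len(alt) and (len(ref) == 1 or len(alt) == 1):
        long = ref if len(ref) > len(alt) else alt
        while pos > 1 and long[-1] == chrom_seq[pos - 2]:
            prev = chrom_seq[pos - 2]
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            long = ref if len(ref) > len(alt) else alt
            pos -= 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# Annotation


def _oriented(base: str, strand: str) -> str:
    return reverse_complement(base) if strand == "-" else base


def _annotate_snp(ctx: _GeneContext, pos: int, ref: str, alt: str) -> EffectAnnotation:
    gene = ctx.gene
    ci = ctx.ci_of_genomic.get(pos)
    ann = EffectAnnotation(gene.chromosome, pos, ref, alt, gene.gene_id, "")
    if ci is None:
        if pos in ctx.splice_positions:
            ann.effect_class = "splice_site"
        elif gene.span[0] <= pos <= gene.span[1]:
            ann.effect_class = "intronic"
        else:
            ann.effect_class = "intergenic"
            ann.gene_id = None
        return ann

    codon_i, offset = divmod(ci, 3)
    codon_start = codon_i * 3
    ref_codon = ctx.cds[codon_start : codon_start + 3]
    alt_base = _oriented(alt, gene.strand)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    if len(ref_codon) < 3:  # trailing partial codon in a flagged model
        ann.effect_class = "synonymous" if ref_codon == alt_codon else "missense"
        return ann

    ref_aa = CODON_TABLE[ref_codon]
    alt_aa = CODON_TABLE[alt_codon]
    ann.aa_change = f"{ref_aa}{codon_i + 1}{alt_aa}"
    if ref_aa == alt_aa:
        ann.effect_class = "synonymous"
    elif codon_i == 0 and ref_codon == "ATG":
        ann.effect_class = "start_lost"
    elif ref_aa == "*":
        ann.effect_class = "stop_loss"
    elif alt_aa == "*":
        ann.effect_class = "nonsense"
        ann.premature_stop = True
        ann.truncated_length = codon_i
    else:
        ann.effect_class = "missense"
    return ann


def _segment_containing(gene: GeneModel, lo: int, hi: int) -> Optional[tuple[int, int]]:
    for a, b in gene.cds_segments:
        if a <= lo and hi <= b:
            return (a, b)
    return None


def _annotate_indel(
    ctx: _GeneContext, reference: Mapping[str, str], pos: int, ref: str, alt: str
) -> EffectAnnotation:
    gene = ctx.gene
    ann = EffectAnnotation(gene.chromosome, pos, ref, alt, gene.gene_id, "")
    shift = len(alt) - len(ref)
    if shift > 0 and len(ref) == 1:  # insertion after anchor base at pos
        lo, hi = pos, pos + 1
    else:  # deletion (or complex block): bases pos..pos+len(ref)-1 replaced
        lo, hi = pos, pos + len(ref) - 1

    in_cds = any(p in ctx.ci_of_genomic for p in range(lo, hi + 1))
    if shift > 0 and len(ref) == 1:
        # insertion is coding only if it falls strictly inside a segment
        in_cds = pos in ctx.ci_of_genomic and (pos + 1) in ctx.ci_of_genomic
    if in_cds:
        ann.effect_class = "frameshift" if shift % 3 else "inframe_indel"
        seg = _segment_containing(gene, lo, min(hi, lo + len(ref) - 1))
        if seg is not None:
            chrom = reference[gene.chromosome]
            a, b = seg
            seg_seq = chrom[a - 1 : b]
            off = pos - a
            seg_mut = seg_seq[:off] + alt + seg_seq[off + len(ref) :]
            pieces = [
                seg_mut if (sa, sb) == seg else chrom[sa - 1 : sb]
                for sa, sb in gene.cds_segments
            ]
            cds_mut = "".join(pieces).upper()
            if gene.strand == "-":
                cds_mut = reverse_complement(cds_mut)
            mut_protein = translate_cds(cds_mut)
            stop_idx = mut_protein.find("*")
            ref_core = ctx.ref_protein.rstrip("*")
            if stop_idx != -1 and stop_idx < len(ref_core):
                ann.premature_stop = True
                ann.truncated_length = stop_idx
    elif any(p in ctx.splice_positions for p in range(lo, hi + 1)):
        ann.effect_class = "splice_site"
    elif gene.span[0] <= lo and hi <= gene.span[1]:
        ann.effect_class = "intronic"
    elif hi < gene.span[0] or lo > gene.span[1]:
        ann.effect_class = "intergenic"
        ann.gene_id = None
    else:
        ann.effect_class = "splice_site"  # straddles the gene boundary region
    return ann


def annotate_variant(
    v: VariantRecord, gene: GeneModel, reference: Mapping[str, str]
) -> EffectAnnotation:
    """Classify one variant against one gene model.

    Raises :class:`DataIntegrityError` when the REF allele does not match the
    reference sequence at ``v.pos``, and ``ValueError`` when the variant is on
    a different chromosome than the gene.
    """
    if v.chromosome != gene.chromosome:
        raise ValueError(
            f"variant {v.chromosome}:{v.pos} not on gene chromosome {gene.chromosome}"
        )
    chrom_seq = reference[gene.chromosome]
    observed = chrom_seq[v.pos - 1 : v.pos - 1 + len(v.ref)].upper()
    if observed != v.ref:
        raise DataIntegrityError(
            f"REF mismatch at {v.chromosome}:{v.pos}: VCF says {v.ref!r}, "
            f"reference has {observed!r}"
        )
    ctx = _context(gene, reference)
    if len(v.ref) == 1 and len(v.alt) == 1:
        return _annotate_snp(ctx, v.pos, v.ref, v.alt)
    pos, ref, alt = normalize_indel(v.pos, v.ref, v.alt, chrom_seq)
    if len(ref) == 1 and len(alt) == 1:  # an MNP that reduced to a SNP
        return _annotate_snp(ctx, pos, ref, alt)
    return _annotate_indel(ctx, reference, pos, ref, alt)


def _split_multiallelic(v: VariantRecord) -> list[VariantRecord]:
    if "," not in v.alt:
        return [v]
    out = []
    for alt in v.alt.split(","):
        out.append(VariantRecord(v.chromosome, v.pos, v.ref, alt, v.genotypes.copy()))
    return out


def annotate_table(
    variants: VariantTable | Iterable[VariantRecord],
    genes: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> list[EffectAnnotation]:
    """Annotate every variant against every overlapping gene.

    A variant overlapping no gene yields a single intergenic record. Variants
    overlapping k genes yield k records. Output is sorted by
    (chromosome, pos, gene_id); multi-allelic records are split first.
    """
    records = variants.records if isinstance(variants, VariantTable) else list(variants)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    out: list[EffectAnnotation] = []
    for rec in itertools.chain.from_iterable(_split_multiallelic(r) for r in records):
        hits = []
        for g in by_chrom.get(rec.chromosome, []):
            lo, hi = g.span
            # include the 2 bp splice window and indel reach around the span
            if lo - 2 <= rec.pos + len(rec.ref) - 1 and rec.pos <= hi + 2:
                ann = annotate_variant(rec, g, reference)
                if ann.effect_class != "intergenic":
                    hits.append(ann)
        if not hits:
            out.append(
                EffectAnnotation(
                    rec.chromosome, rec.pos, rec.ref, rec.alt, None, "intergenic"
                )
            )
        else:
            out.extend(hits)
    out.sort(key=lambda a: (a.chromosome, a.pos, a.gene_id or ""))
    return out
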