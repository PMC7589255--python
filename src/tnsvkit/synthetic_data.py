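"""Synthetic inputs for the burden pipeline.

Generates every artefact the analysis consumes: a reference sequence with
multi-exon gene models on both strands, a diploid genotype panel whose
phenotypes are linearly coupled to the planted non-synonymous burden, an EMS
mutation screen with the canonical G:C -> A:T spectrum, and selfed progeny of
multi-locus heterozygotes.

The panel emulates a resequenced crop diversity panel: a dozen candidate
paralogs in five gene families, biallelic SNPs segregating at intermediate
frequencies, Hardy-Weinberg genotypes, and an additive burden -> phenotype
model in which a higher non-synonymous dosage raises seed oil content and
lowers oleic acid. All generators are bitwise reproducible under a fixed
master seed; sub-generators derive child seeds deterministically by stage
name.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .mutagenesis_genetics import MutationScreen
from .variant_effects import (
    CODON_TABLE,
    STOP_CODONS,
    GeneModel,
    VariantRecord,
    VariantTable,
    extract_cds,
    reverse_complement,
)

__all__ = [
    "GeneSpec",
    "GeneSites",
    "PanelSimConfig",
    "EmsSimConfig",
    "PanelSim",
    "EmsScreenSim",
    "SelfingResult",
    "child_rng",
    "default_gene_specs",
    "default_gene_sites",
    "generate_reference",
    "simulate_panel",
    "simulate_ems_screen",
    "simulate_selfed_progeny",
]

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = sorted(c for c in CODON_TABLE if c not in STOP_CODONS)
_STOPS = sorted(STOP_CODONS)


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


# ---------------------------------------------------------------------------
# Reference + gene models


@dataclass(frozen=True)
class GeneSpec:
    """Blueprint for one generated gene."""

    gene_id: str
    family: str
    strand: str = "+"
    n_exons: int = 2
    cds_length: int = 450

    def __post_init__(self) -> None:
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )
        if self.n_exons < 1:
            raise ValueError(f"{self.gene_id}: need at least one exon")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


def default_gene_specs() -> tuple[GeneSpec, ...]:
    """Twelve candidate paralogs in five families (family 4 has four members),
    mirroring the structure of the oil-content candidate panel."""
    layout = {
        "SFAR1": ["a", "b"],
        "SFAR2": ["a", "b"],
        "SFAR3": ["a", "b"],
        "SFAR4": ["a", "b", "c", "d"],
        "SFAR5": ["a", "b"],
    }
    specs = []
    i = 0
    for family, members in layout.items():
        for m in members:
            specs.append(
                GeneSpec(
                    gene_id=f"Bn{family}.{m}",
                    family=family,
                    strand="+" if i % 2 == 0 else "-",
                    n_exons=2 + i % 2,
                    cds_length=450,
                )
            )
            i += 1
    return tuple(specs)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _random_cds(rng: np.random.Generator, length: int) -> str:
    n_codons = length // 3
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(_STOPS)
    return "ATG" + "".join(body) + stop


def _split_exons(
    rng: np.random.Generator, cds_len: int, n_exons: int, min_exon: int = 12
) -> list[int]:
    """Exon lengths summing to cds_len, each >= min_exon."""
    if n_exons == 1:
        return [cds_len]
    if cds_len < n_exons * min_exon:
        raise ValueError("CDS too short for requested exon count")
    for _ in range(1000):
        cuts = np.sort(rng.integers(min_exon, cds_len - min_exon + 1, n_exons - 1))
        bounds = [0, *cuts.tolist(), cds_len]
        lengths = [b - a for a, b in zip(bounds, bounds[1:])]
        if min(lengths) >= min_exon:
            return lengths
    raise RuntimeError("could not partition CDS into exons")


def generate_reference(
    genes_spec: Sequence[GeneSpec] | None = None,
    seed: int = 0,
    chromosome: str = "chrSim",
    spacer: int = 300,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Build a FASTA-ready reference and GFF3-ready gene models.

    Every CDS starts with ATG, ends with a stop codon and has no internal
    stop; introns carry GT..AG boundaries on the coding strand; minus-strand
    genes are laid down as the reverse complement of their sense sequence.
    """
    specs = tuple(genes_spec) if genes_spec is not None else default_gene_specs()
    rng = child_rng(seed, "reference")
    chrom_parts: list[str] = [_random_seq(rng, spacer)]
    cursor = spacer  # 0-based length so far
    genes: list[GeneModel] = []

    for spec in specs:
        cds = _random_cds(rng, spec.cds_length)
        exon_lengths = _split_exons(rng, spec.cds_length, spec.n_exons)
        sense_parts: list[str] = []
        exon_intervals: list[tuple[int, int]] = []  # 0-based half-open, sense
        off = 0
        pos = 0
        for i, el in enumerate(exon_lengths):
            sense_parts.append(cds[off : off + el])
            exon_intervals.append((pos, pos + el))
            pos += el
            off += el
            if i < len(exon_lengths) - 1:
                intron = "GT" + _random_seq(rng, int(rng.integers(60, 120))) + "AG"
                sense_parts.append(intron)
                pos += len(intron)
        block = "".join(sense_parts)
        L = len(block)
        if spec.strand == "-":
            block = reverse_complement(block)
            segs = tuple(
                sorted(
                    (cursor + (L - e) + 1, cursor + (L - s))
                    for s, e in exon_intervals
                )
            )
        else:
            segs = tuple((cursor + s + 1, cursor + e) for s, e in exon_intervals)
        chrom_parts.append(block)
        cursor += L
        chrom_parts.append(_random_seq(rng, spacer))
        cursor += spacer
        genes.append(
            GeneModel(
                gene_id=spec.gene_id,
                chromosome=chromosome,
                strand=spec.strand,
                cds_segments=segs,
                family=spec.family,
            )
        )

    reference = {chromosome: "".join(chrom_parts)}
    return reference, genes


# ---------------------------------------------------------------------------
# Genotype/phenotype panel


@dataclass(frozen=True)
class GeneSites:
    """Per-gene counts of segregating sites to plant."""

    gene_id: str
    n_nonsyn: int = 3
    n_syn: int = 2


def default_gene_sites(
    specs: Sequence[GeneSpec] | None = None,
) -> tuple[GeneSites, ...]:
    specs = tuple(specs) if specs is not None else default_gene_specs()
    return tuple(GeneSites(s.gene_id) for s in specs)


@dataclass(frozen=True)
class PanelSimConfig:
    """Study conditions for the genotype -> phenotype panel.

    ``beta_soc`` (% dry weight per burden unit) and ``beta_oac`` (% of total
    fatty acids per unit, typically negative) couple the aggregate burden to
    the two traits; ``mu``/``sigma`` are trait baselines and residual SDs.
    """

    n_accessions: int = 870
    genes: tuple[GeneSites, ...] = field(default_factory=default_gene_sites)
    allele_freq_range: tuple[float, float] = (0.10, 0.40)
    beta_soc: float = 0.2
    beta_oac: float = -0.3
    mu_soc: float = 43.0
    mu_oac: float = 62.0
    sigma_soc: float = 2.0
    sigma_oac: float = 3.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if self.n_accessions < 2:
            raise ValueError("need at least 2 accessions")
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"allele_freq_range {self.allele_freq_range} outside (0,1)")
        if self.sigma_soc < 0 or self.sigma_oac < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0,1)")


@dataclass
class PanelSim:
    """Simulated panel: genotypes, phenotypes and the planted ground truth."""

    variants: VariantTable
    phenotypes: pd.DataFrame  # index accession; columns soc, oac
    true_tnsv: pd.Series  # planted aggregate burden per accession
    site_truth: pd.DataFrame  # chrom,pos,ref,alt,gene,planted_class,allele_freq


def _codon_edits(codon: str) -> dict[str, list[tuple[int, str]]]:
    """Single-base edits of a codon, grouped into missense/synonymous."""
    out: dict[str, list[tuple[int, str]]] = {"missense": [], "synonymous": []}
    ref_aa = CODON_TABLE[codon]
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt_aa = CODON_TABLE[codon[:pos] + b + codon[pos + 1 :]]
            if alt_aa == ref_aa:
                out["synonymous"].append((pos, b))
            elif alt_aa != "*":
                out["missense"].append((pos, b))
    return out


def _genomic_map(gene: GeneModel) -> list[int]:
    genomic: list[int] = []
    for a, b in gene.cds_segments:
        genomic.extend(range(a, b + 1))
    if gene.strand == "-":
        genomic.reverse()
    return genomic


def simulate_panel(
    config: PanelSimConfig,
    gene_models: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> PanelSim:
    """Plant segregating sites, draw Hardy-Weinberg genotypes and phenotypes.

    Non-synonymous sites are constructed by codon substitution so the
    annotator classifies them as missense; synonymous sites preserve the
    amino acid. Per trait, phenotype_i = mu + beta * TNSV_i + Normal(0, sigma)
    with TNSV_i the planted aggregate dosage over non-synonymous sites.
    """
    rng = child_rng(config.seed, "panel")
    models = {g.gene_id: g for g in gene_models}
    lo, hi = config.allele_freq_range
    n = config.n_accessions
    accessions = [f"ACC{i:04d}" for i in range(1, n + 1)]

    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    true_tnsv = np.zeros(n, dtype=np.int64)

    for gs in config.genes:
        gene = models[gs.gene_id]
        cds = extract_cds(gene, reference)
        n_codons = len(cds) // 3
        genomic = _genomic_map(gene)
        # internal codons only: never touch the start or stop codon
        candidates = list(range(1, n_codons - 1))
        rng.shuffle(candidates)
        need = {"missense": gs.n_nonsyn, "synonymous": gs.n_syn}
        planted = 0
        for codon_i in candidates:
            if need["missense"] == 0 and need["synonymous"] == 0:
                break
            codon = cds[codon_i * 3 : codon_i * 3 + 3]
            edits = _codon_edits(codon)
            kind = None
            if need["missense"] > 0 and edits["missense"]:
                kind = "missense"
            elif need["synonymous"] > 0 and edits["synonymous"]:
                kind = "synonymous"
            if kind is None:
                continue
            pos_in_codon, alt_sense = edits[kind][rng.integers(len(edits[kind]))]
            ci = codon_i * 3 + pos_in_codon
            gpos = genomic[ci]
            chrom_seq = reference[gene.chromosome]
            ref_g = chrom_seq[gpos - 1]
            alt_g = (
                reverse_complement(alt_sense) if gene.strand == "-" else alt_sense
            )
            p = rng.uniform(lo, hi)
            dosage = rng.binomial(2, p, size=n).astype(np.int8)
            if config.missing_rate > 0:
                dosage[rng.random(n) < config.missing_rate] = -1
            if kind == "missense":
                true_tnsv += np.where(dosage > 0, dosage, 0)
            records.append(VariantRecord(gene.chromosome, gpos, ref_g, alt_g, dosage))
            truth_rows.append(
                {
                    "chrom": gene.chromosome,
                    "pos": gpos,
                    "ref": ref_g,
                    "alt": alt_g,
                    "gene": gene.gene_id,
                    "planted_class": (
                        "non_synonymous" if kind == "missense" else "synonymous"
                    ),
                    "allele_freq": p,
                }
            )
            need[kind] -= 1
            planted += 1
        if need["missense"] > 0 or need["synonymous"] > 0:
            raise ValueError(
                f"{gs.gene_id}: requested {gs.n_nonsyn}+{gs.n_syn} sites but only "
                f"{planted} codon positions were available"
            )

    order = np.argsort([(r.chromosome, r.pos) for r in records], axis=0)
    records_sorted = sorted(records, key=lambda r: (r.chromosome, r.pos))
    del order
    site_truth = (
        pd.DataFrame(truth_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    )

    soc = config.mu_soc + config.beta_soc * true_tnsv + rng.normal(
        0.0, config.sigma_soc, n
    )
    oac = config.mu_oac + config.beta_oac * true_tnsv + rng.normal(
        0.0, config.sigma_oac, n
    )
    phenotypes = pd.DataFrame({"soc": soc, "oac": oac}, index=pd.Index(accessions, name="accession"))
    return PanelSim(
        variants=VariantTable(samples=accessions, records=records_sorted),
        phenotypes=phenotypes,
        true_tnsv=pd.Series(true_tnsv, index=phenotypes.index, name="tnsv"),
        site_truth=site_truth,
    )


# ---------------------------------------------------------------------------
# EMS screen


@dataclass(frozen=True)
class EmsSimConfig:
    """Study conditions for a TILLING screen of a mutagenized population."""

    amplicons: tuple[tuple[str, int], ...]
    n_families: int = 3488
    rate_per_bp: float = 1.0 / 24500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.amplicons or any(length <= 0 for _, length in self.amplicons):
            raise ValueError("amplicon lengths must be positive")
        if not (0.0 <= self.rate_per_bp < 0.01):
            raise ValueError("rate_per_bp must be small and non-negative")
        if self.n_families < 1:
            raise ValueError("need at least one family")


@dataclass
class EmsScreenSim:
    """Simulated screen: summary counts plus the individual mutation calls."""

    screen: MutationScreen
    mutations: pd.DataFrame  # family, gene, pos (1-based in amplicon), ref, alt
    per_family_counts: np.ndarray


def simulate_ems_screen(config: EmsSimConfig) -> EmsScreenSim:
    """Draw per-family Poisson mutation counts and place G:C -> A:T transitions.

    Counts per family follow Poisson(rate_per_bp x total amplicon length);
    every mutation is a transition at a uniformly chosen G/C position of the
    (internally generated) amplicon sequences, the canonical EMS spectrum.
    """
    rng = child_rng(config.seed, "ems")
    amp_seqs = {
        gene: _random_seq(rng, length) for gene, length in config.amplicons
    }
    gc_sites: list[tuple[str, int, str]] = [
        (gene, i + 1, b)
        for gene, seq in amp_seqs.items()
        for i, b in enumerate(seq)
        if b in "GC"
    ]
    total_len = sum(length for _, length in config.amplicons)
    counts = rng.poisson(config.rate_per_bp * total_len, size=config.n_families)
    n_total = int(counts.sum())
    rows = []
    if n_total and gc_sites:
        picks = rng.integers(0, len(gc_sites), size=n_total)
        fam_ids = np.repeat(np.arange(1, config.n_families + 1), counts)
        for fam, k in zip(fam_ids, picks):
            gene, pos, ref = gc_sites[k]
            rows.append(
                {
                    "family": int(fam),
                    "gene": gene,
                    "pos": pos,
                    "ref": ref,
                    "alt": "A" if ref == "G" else "T",
                }
            )
    mutations = pd.DataFrame(rows, columns=["family", "gene", "pos", "ref", "alt"])
    screen = MutationScreen(
        n_mutations=n_total,
        total_screened_bp=total_len * config.n_families,
        n_families=config.n_families,
    )
    return EmsScreenSim(screen=screen, mutations=mutations, per_family_counts=counts)


# ---------------------------------------------------------------------------
# Selfed progeny


@dataclass
class SelfingResult:
    """Genotype-class counts among selfed progeny of a multi-locus parent."""

    per_locus_counts: list[dict[tuple[str, str], int]]
    multilocus_counts: Counter
    homozygous_loci: list[int]  # indices of parent loci that were homozygous
    n_progeny: int


def simulate_selfed_progeny(
    parent_genotypes: Sequence[tuple[str, str]],
    n_progeny: int,
    seed: int = 0,
) -> SelfingResult:
    """Self a parent heterozygous at unlinked loci; classes segregate 1:2:1.

    A homozygous parent locus is allowed but flagged: it emits a single
    progeny class. With zero loci every progeny falls in one (empty) class.
    """
    if n_progeny < 1:
        raise ValueError("need at least one progeny")
    rng = child_rng(seed, "selfing")
    per_locus: list[np.ndarray] = []
    homozygous = []
    for i, (a1, a2) in enumerate(parent_genotypes):
        if a1 == a2:
            homozygous.append(i)
            classes = np.zeros(n_progeny, dtype=np.int64)  # only a1/a1
        else:
            g1 = rng.integers(0, 2, n_progeny)
            g2 = rng.integers(0, 2, n_progeny)
            classes = g1 + g2  # 0: a1/a1, 1: a1/a2, 2: a2/a2
        per_locus.append(classes)

    def class_name(i: int, c: int) -> tuple[str, str]:
        a1, a2 = parent_genotypes[i]
        return ((a1, a1), (a1, a2), (a2, a2))[c]

    per_locus_counts = []
    for i, classes in enumerate(per_locus):
        cnt: dict[tuple[str, str], int] = {}
        for c, k in zip(*np.unique(classes, return_counts=True)):
            cnt[class_name(i, int(c))] = int(k)
        per_locus_counts.append(cnt)

    multi = Counter()
    if parent_genotypes:
        stacked = np.stack(per_locus, axis=1)
        for row in stacked:
            multi[tuple(class_name(i, int(c)) for i, c in enumerate(row))] += 1
    else:
        multi[()] = n_progeny
    return SelfingResult(
        per_locus_counts=per_locus_counts,
        multilocus_counts=multi,
        homozygous_loci=homozygous,
        n_progeny=n_progeny,
    )
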