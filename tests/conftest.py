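"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest
from Bio.Seq import Seq

from tnsvkit.synthetic_data import (
    PanelSimConfig,
    generate_reference,
    simulate_panel,
)


# ---------------------------------------------------------------------------
# Independent oracles (Biopython-based; deliberately unaware of the package's
# own codon table and CDS arithmetic).


def oracle_extract_cds(gene, reference) -> str:
    seq = "".join(reference[gene.chromosome][a - 1 : b] for a, b in gene.cds_segments)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq.upper()


def oracle_translate(cds: str) -> str:
    usable = cds[: len(cds) - len(cds) % 3]
    return str(Seq(usable).translate())


def oracle_classify_snp(gene, reference, pos: int, alt: str) -> str:
    """Full-protein comparison: mutate the chromosome, re-extract, translate."""
    chrom = reference[gene.chromosome]
    mutated = {gene.chromosome: chrom[: pos - 1] + alt + chrom[pos:]}
    ref_cds = oracle_extract_cds(gene, reference)
    ref_p = oracle_translate(ref_cds)
    alt_p = oracle_translate(oracle_extract_cds(gene, mutated))
    if ref_p == alt_p:
        return "synonymous"
    if ref_cds[:3] == "ATG" and alt_p[0] != ref_p[0] == "M":
        return "start_lost"
    ref_stop = ref_p.find("*")
    alt_stop = alt_p.find("*")
    if alt_stop != -1 and (ref_stop == -1 or alt_stop < ref_stop):
        return "nonsense"
    if ref_stop != -1 and alt_stop == -1:
        return "stop_loss"
    return "missense"


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def reference_and_genes():
    """Default 12-gene candidate panel reference (both strands, multi-exon)."""
    return generate_reference(seed=11)


@pytest.fixture(scope="session")
def medium_panel(reference_and_genes):
    """A 500-accession panel with the default study conditions."""
    reference, genes = reference_and_genes
    config = PanelSimConfig(n_accessions=500, seed=7)
    return config, simulate_panel(config, genes, reference)
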