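"""Total non-synonymous value (TNSV): a per-accession dosage burden.

At every retained non-synonymous site an accession scores 2 (homozygous
alternate), 1 (heterozygous) or 0 (homozygous reference). The TNSV is the
sum of these scores over all sites of one gene, of one gene family, or of
the whole candidate set (the aggregate). Sites first pass a minor-allele-
frequency filter: only 0.05 < MAF < 0.50, strict on both bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .variant_effects import EffectAnnotation, GeneModel, VariantTable

__all__ = [
    "DEFAULT_SCORING_CLASSES",
    "SiteScorePolicy",
    "TNSVTable",
    "maf_filter",
    "site_score",
    "compute_tnsv",
]

#: SNP classes that change the encoded protein and are scored by default.
#: Splice-site variants do not alter a codon and are excluded unless opted in.
DEFAULT_SCORING_CLASSES = frozenset(
    {"missense", "nonsense", "start_lost", "stop_loss"}
)


@dataclass(frozen=True)
class SiteScorePolicy:
    """Which effect classes count, and how missing genotypes are handled.

    The 2/1/0 genotype scores are fixed. ``missing_policy`` is either
    ``"zero"`` (missing scores 0, accession kept) or
    ``"exclude-accession-at-gene"`` (that accession's TNSV for the affected
    gene becomes NA and is excluded from family/aggregate sums).
    """

    scoring_classes: frozenset[str] = DEFAULT_SCORING_CLASSES
    missing_policy: str = "zero"
    include_splice_site: bool = False

    SCORE_HOM = 2
    SCORE_HET = 1
    SCORE_REF = 0

    def __post_init__(self) -> None:
        classes = frozenset(self.scoring_classes)
        if self.include_splice_site:
            classes = classes | {"splice_site"}
        if not classes:
            raise ValueError("scoring_classes must be non-empty")
        if self.missing_policy not in ("zero", "exclude-accession-at-gene"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        object.__setattr__(self, "scoring_classes", classes)


@dataclass
class TNSVTable:
    """Accession x gene burden matrix with family and aggregate roll-ups."""

    per_gene: pd.DataFrame  # index accession, one column per gene
    per_family: pd.DataFrame  # index accession, one column per family
    aggregate: pd.Series  # index accession

    @property
    def accessions(self) -> pd.Index:
        return self.per_gene.index

    def scope(self, name: str) -> pd.Series:
        """TNSV under a named scope: 'aggregate', 'family:<F>' or 'gene:<G>'."""
        if name == "aggregate":
            return self.aggregate
        if name.startswith("family:"):
            fam = name.split(":", 1)[1]
            if fam not in self.per_family.columns:
                raise KeyError(f"unknown family {fam!r}")
            return self.per_family[fam]
        if name.startswith("gene:"):
            gene = name.split(":", 1)[1]
            if gene not in self.per_gene.columns:
                raise KeyError(f"unknown gene {gene!r}")
            return self.per_gene[gene]
        raise KeyError(f"unknown scope {name!r}")

    def to_frame(self) -> pd.DataFrame:
        df = self.per_gene.copy()
        for fam in self.per_family.columns:
            df[f"family:{fam}"] = self.per_family[fam]
        df["aggregate"] = self.aggregate
        return df


def maf_filter(
    variants: VariantTable,
    min_maf: float = 0.05,
    max_maf: float = 0.50,
) -> tuple[VariantTable, pd.DataFrame]:
    """Keep sites with min_maf < MAF < max_maf (both bounds strict).

    MAF is min(f_alt, 1 - f_alt) over non-missing alleles. Returns the
    filtered table and a per-site log (chrom, pos, ref, alt, maf, kept).
    Sites with every genotype missing are dropped with a warning.
    """
    kept_records = []
    log_rows = []
    for r in variants.records:
        g = r.genotypes
        called = g[g >= 0]
        if called.size == 0:
            warnings.warn(
                f"site {r.chromosome}:{r.pos} has no called genotypes; dropped",
                stacklevel=2,
            )
            log_rows.append(
                {"chrom": r.chromosome, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                 "maf": np.nan, "kept": False}
            )
            continue
        f_alt = float(called.sum()) / (2.0 * called.size)
        maf = min(f_alt, 1.0 - f_alt)
        keep = min_maf < maf < max_maf
        log_rows.append(
            {"chrom": r.chromosome, "pos": r.pos, "ref": r.ref, "alt": r.alt,
             "maf": maf, "kept": keep}
        )
        if keep:
            kept_records.append(r)
    log = pd.DataFrame(
        log_rows, columns=["chrom", "pos", "ref", "alt", "maf", "kept"]
    )
    return VariantTable(samples=list(variants.samples), records=kept_records), log


def site_score(
    genotype: int,
    effect: EffectAnnotation,
    policy: SiteScorePolicy = SiteScorePolicy(),
) -> int:
    """Score one genotype at one annotated site under the 2/1/0 rule.

    Sites whose effect class is not scored (e.g. synonymous) contribute 0
    regardless of genotype. Missing genotypes score 0 under the ``zero``
    policy (the table-level computation handles the exclusion policy).
    """
    if effect.effect_class not in policy.scoring_classes:
        return 0
    if genotype < 0:
        return 0
    return (policy.SCORE_REF, policy.SCORE_HET, policy.SCORE_HOM)[genotype]


def compute_tnsv(
    variants: VariantTable,
    annotations: Sequence[EffectAnnotation],
    genes: Sequence[GeneModel],
    policy: SiteScorePolicy = SiteScorePolicy(),
) -> TNSVTable:
    """Per-gene, per-family and aggregate TNSV for every accession.

    ``variants`` should already be MAF-filtered; ``annotations`` must cover
    every (variant, gene) pair to score. A gene with no scored sites has
    TNSV 0 everywhere.
    """
    family_of = {g.gene_id: (g.family or g.gene_id) for g in genes}
    gene_ids = [g.gene_id for g in genes]
    n_acc = len(variants.samples)
    acc_index = pd.Index(variants.samples, name="accession")

    scored_by_key: dict[tuple, set[str]] = {}
    for a in annotations:
        if a.gene_id is not None and a.effect_class in policy.scoring_classes:
            scored_by_key.setdefault(a.variant_key, set()).add(a.gene_id)

    per_gene = pd.DataFrame(
        0.0, index=acc_index, columns=pd.Index(gene_ids, name="gene")
    )
    exclude = policy.missing_policy == "exclude-accession-at-gene"
    for r in variants.records:
        for gene_id in scored_by_key.get(r.key, ()):
            if gene_id not in per_gene.columns:
                continue
            d = r.genotypes.astype(np.float64)
            if exclude:
                d[d < 0] = np.nan
            else:
                d[d < 0] = 0.0
            per_gene[gene_id] += d

    families = sorted(set(family_of.values()))
    per_family = pd.DataFrame(0.0, index=acc_index, columns=pd.Index(families, name="family"))
    for gid in gene_ids:
        per_family[family_of[gid]] += per_gene[gid].fillna(0.0)
    aggregate = per_gene.fillna(0.0).sum(axis=1)
    aggregate.name = "aggregate"

    if not exclude:
        per_gene = per_gene.astype(np.int64)
        per_family = per_family.astype(np.int64)
        aggregate = aggregate.astype(np.int64)
    return TNSVTable(per_gene=per_gene, per_family=per_family, aggregate=aggregate)
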