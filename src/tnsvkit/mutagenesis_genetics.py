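"""Quantitative-genetics arithmetic for mutagenesis experiments.

Covers the bookkeeping around a TILLING/EMS screen and a gene-editing
programme: mutation density ("one mutation per X kb"), the implied
genome-wide mutation load per plant, transformation efficiency, enumeration
of expected multilocus genotype classes among selfed progeny, chi-square
goodness of fit of observed segregation to a Mendelian ratio, and allele
transmission fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from scipy import stats

__all__ = [
    "MutationScreen",
    "SegregationObservation",
    "MutationFrequency",
    "SegregationTestResult",
    "mutation_frequency",
    "genome_load",
    "transformation_efficiency",
    "expected_genotype_classes",
    "segregation_test",
    "transmission_check",
]


@dataclass(frozen=True)
class MutationScreen:
    """Summary of an amplicon screen of a mutagenized population.

    ``total_screened_bp`` is amplicon length summed over genes times the
    number of families screened. ``class_tallies`` (nonsense / missense /
    splice / silent) is optional; it is known only when the individual
    mutations were annotated.
    """

    n_mutations: int
    total_screened_bp: int
    n_families: int
    class_tallies: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        if self.n_mutations < 0 or self.n_families < 0:
            raise ValueError("counts must be non-negative")
        if self.total_screened_bp <= 0:
            raise ValueError("total_screened_bp must be positive")


@dataclass(frozen=True)
class MutationFrequency:
    """Mutation density as 'one mutation per kb_per_mutation kb'."""

    kb_per_mutation: float  # rounded to 1 decimal
    is_lower_bound: bool = False  # True when no mutations were found

    def __str__(self) -> str:
        prefix = ">" if self.is_lower_bound else ""
        return f"{prefix}1/{self.kb_per_mutation:.1f} kb"


def mutation_frequency(screen: MutationScreen) -> MutationFrequency:
    """Density of induced mutations: X = screened bp / mutations / 1000.

    With zero mutations the frequency is undefined; the whole screened length
    is reported as a '< 1 per total' lower bound on X.
    """
    if screen.n_mutations == 0:
        return MutationFrequency(
            kb_per_mutation=round(screen.total_screened_bp / 1000.0, 1),
            is_lower_bound=True,
        )
    x = screen.total_screened_bp / screen.n_mutations / 1000.0
    return MutationFrequency(kb_per_mutation=round(x, 1))


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    q = 10.0 ** (exp - sig + 1)
    return float(Decimal(x / q).quantize(Decimal(1), rounding=ROUND_HALF_UP)) * q


@dataclass(frozen=True)
class GenomeLoad:
    raw: float
    rounded: float  # two significant figures


def genome_load(
    frequency_kb_per_mutation: float, genome_size_mb: float
) -> GenomeLoad:
    """Expected mutations carried per plant across the whole genome.

    load = genome size (kb) / kb-per-mutation; e.g. a density of 1/24.5 kb on
    a 1130 Mb genome implies ~46,000 mutations per plant.
    """
    if frequency_kb_per_mutation <= 0 or genome_size_mb <= 0:
        raise ValueError("inputs must be positive")
    raw = genome_size_mb * 1000.0 / frequency_kb_per_mutation
    return GenomeLoad(raw=raw, rounded=_round_sig(raw, 2))


def transformation_efficiency(n_transgenic: int, n_explants: int) -> float:
    """Percent of explants yielding transgenic plants, half-up to 1 decimal."""
    if n_explants <= 0:
        raise ValueError("n_explants must be positive")
    if not (0 <= n_transgenic <= n_explants):
        raise ValueError("need 0 <= n_transgenic <= n_explants")
    pct = Decimal(100 * n_transgenic) / Decimal(n_explants)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def expected_genotype_classes(
    n_loci: int, parent_heterozygous_per_locus: bool | Sequence[bool] = True
) -> int:
    """Distinct multilocus genotype classes among selfed progeny.

    Each heterozygous biallelic locus segregates into 3 classes (m1/m1,
    m1/m2, m2/m2); a homozygous locus contributes a single class. Loci are
    unlinked, so classes multiply: 3^(#het loci).
    """
    if n_loci < 0:
        raise ValueError("n_loci must be >= 0")
    if isinstance(parent_heterozygous_per_locus, bool):
        het = n_loci if parent_heterozygous_per_locus else 0
    else:
        flags = list(parent_heterozygous_per_locus)
        if len(flags) != n_loci:
            raise ValueError("one heterozygosity flag per locus required")
        het = sum(bool(f) for f in flags)
    return 3 ** het


@dataclass(frozen=True)
class SegregationObservation:
    """Observed progeny genotype-class counts at one locus."""

    locus_id: str
    parent_alleles: tuple[str, str]
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...] = (1.0, 2.0, 1.0)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.observed):
            raise ValueError("observed counts must be >= 0")
        if any(r <= 0 for r in self.expected_ratio):
            raise ValueError("ratio terms must be > 0")
        if len(self.observed) != len(self.expected_ratio):
            raise ValueError("observed and ratio must have equal length")


@dataclass(frozen=True)
class SegregationTestResult:
    chi2: float
    df: int
    p_value: float
    verdict: str  # "consistent" | "not consistent"
    small_expected_warning: bool
    expected: tuple[float, ...]


def segregation_test(
    obs: SegregationObservation, alpha: float = 0.05
) -> SegregationTestResult:
    """Pearson chi-square of observed counts against the expected ratio.

    df = classes - 1; verdict is "consistent" iff p >= alpha. A warning flag
    is set when any expected cell count falls below 5.
    """
    total = sum(obs.observed)
    if total == 0:
        raise ValueError("zero total observed count")
    ratio_sum = sum(obs.expected_ratio)
    expected = tuple(total * r / ratio_sum for r in obs.expected_ratio)
    chi2, p = stats.chisquare(list(obs.observed), f_exp=list(expected))
    return SegregationTestResult(
        chi2=float(chi2),
        df=len(obs.observed) - 1,
        p_value=float(p),
        verdict="consistent" if p >= alpha else "not consistent",
        small_expected_warning=any(e < 5 for e in expected),
        expected=expected,
    )


def transmission_check(
    parent_genotype: tuple[str, str],
    progeny_genotypes: Sequence[tuple[str, str]],
) -> dict[str, float]:
    """Fraction of progeny carrying each parental allele.

    A homozygous parent allele must show 1.0 in error-free data; a selfed
    heterozygote transmits each allele to ~3/4 of progeny (carrier = het or
    homozygote for that allele).
    """
    if not progeny_genotypes:
        raise ValueError("non-empty progeny set required")
    n = len(progeny_genotypes)
    out = {}
    for allele in dict.fromkeys(parent_genotype):  # preserve order, dedupe
        carriers = sum(1 for g in progeny_genotypes if allele in g)
        out[allele] = carriers / n
    return out
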