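# Methods

This note documents the models implemented in `tnsvkit`, the parameter
choices that matter, and what the synthetic data can and cannot show.

## Variant-effect annotation

Gene models are single-transcript: ordered, non-overlapping CDS segments in
1-based inclusive coordinates (the convention of both GFF3 and VCF, used for
all internal arithmetic to avoid an off-by-one seam). The coding sequence is
the spliced concatenation of segments, reverse-complemented for minus-strand
genes. Models whose CDS violates the ATG…stop structure are flagged by
`GeneModel.validate_cds`, not rejected — real annotations contain such genes.

A CDS SNP is classified by translating the reference codon against the
alternate codon (standard nuclear code, hard-coded): same amino acid →
synonymous; a disrupted ATG start codon → start-lost; reference stop lost →
stop-loss; alternate codon a stop → nonsense (the truncated protein length
is recorded); otherwise missense. Classification is therefore codon-local,
but the test suite proves it equivalent to a full-protein comparison oracle
(mutate the chromosome, re-extract, translate both proteins with Biopython)
on tens of thousands of random SNPs on both strands.

The splice-site window is the 2 intronic bp flanking each CDS junction — the
canonical GT/AG dinucleotides. Positions inside the gene span that are
neither CDS nor splice are intronic; everything else is intergenic.

Indels are left-aligned before classification (shared-suffix/prefix
trimming, then shifting through reference repeats). A coding indel is a
frameshift when the length difference is not a multiple of 3, else an
in-frame indel. For indels contained in a single CDS segment the mutated
CDS is rebuilt and translated to locate a premature stop; an indel spanning
an exon–intron junction is classified by length only, without the truncated-
protein rebuild — a stated limitation, acceptable because junction indels
disrupt splicing in ways a CDS-level model cannot predict anyway.
Multi-allelic VCF records are split into biallelic records and each
alternate allele annotated independently.

## TNSV burden scoring

Sites pass a minor-allele-frequency filter first: MAF = min(f_alt, 1−f_alt)
computed over non-missing alleles, retained iff 0.05 < MAF < 0.50 with both
bounds strict (a site at exactly 50% is removed). The per-site MAF is logged
so filtering is auditable.

Scoring is the literal dosage rule: homozygous alternate 2, heterozygous 1,
homozygous reference 0, summed per gene, per family and over the whole
candidate set (the aggregate equals the sum of per-gene values by
construction, and the suite verifies it against a naive double loop and
against the simulator's planted burden). Scored classes default to
{missense, nonsense, start_lost, stop_loss} — every SNP that changes the
encoded protein. Splice-site SNPs do not change a codon and are excluded by
default; `SiteScorePolicy(include_splice_site=True)` opts them in.

Missing genotypes score 0 by default (`missing_policy="zero"`), which keeps
per-bin sample sizes stable; `"exclude-accession-at-gene"` instead sets that
accession's TNSV for the affected gene to NA. Heterozygotes are scored 1
even though rapeseed is largely self-pollinating; no inbreeding correction
is applied, because the statistic is defined on observed genotypes.

## Binning and association

Bins: low (TNSV < 10), mid (10 ≤ TNSV ≤ 20), high (TNSV > 20). Values equal
to a threshold land in the middle bin; thresholds are configurable through
`BinSpec`. Testing uses one-way ANOVA across usable bins (n ≥ 2 each), all
pairwise two-sided Welch *t*-tests — the unequal-variance form is the safer
default when a "two-tailed unpaired t-test" is not further qualified — and
Tukey HSD with a compact-letter display (maximal sets of mutually
non-significant bins share a letter). Fewer than two usable bins yields an
explicit "not testable" result, never a silent pass. Accessions missing a
phenotype are dropped for that trait only. Per-family scans report raw
p-values; no multiple-testing correction is applied across families by
default since each family is a separate hypothesis of interest (BH is
available in `expression_filters.bh_adjust` if a user wants it).

Under the null the pairwise contrast is calibrated: the suite measures an
empirical type-I error within [0.03, 0.07] at α = 0.05 over 1000 replicate
panels of 2 × 400 accessions.

## Mutagenesis genetics

- Mutation density: X kb per mutation = screened bp / mutations / 1000,
  reported to one decimal. Zero mutations gives an explicit lower-bound
  report rather than a number.
- Genome-wide load = genome size (kb) / X, reported raw and rounded to two
  significant figures (e.g. density 1/24.5 kb on a 1130 Mb genome → 46,122,
  ~46,000).
- Transformation efficiency = 100 × transgenic / explants, rounded half-up
  to one decimal so that 2/857 → 0.2% and 5/442 → 1.1%.
- Expected selfed-progeny genotype classes = 3^(heterozygous loci); a locus
  whose T1 parent carries two distinct mutant alleles segregates into three
  classes with no wild-type class. The closed form is tested against
  exhaustive enumeration of gamete pairings for up to five loci.
- Segregation: Pearson chi-square against the expected ratio (default
  1:2:1), df = classes − 1, verdict "consistent" iff p ≥ α = 0.05, with a
  flag when any expected cell is below 5 (where the chi-square approximation
  weakens).
- Transmission: fraction of progeny carrying each parental allele; a
  homozygous parent must show 1.0 in error-free data, a selfed heterozygote
  ~3/4.

## Expression filters

Expressed means FPKM strictly above 1 at either developmental stage.
Differential-expression calls apply Benjamini–Hochberg (via statsmodels)
to the supplied raw p-values and threshold at FDR < 0.05 with |log2FC| ≥ 1
(inclusive); the negative-binomial model that produces those statistics is
out of scope by design — the module consumes per-gene summaries. "Equally
expressed" is simply the complement of the up/down calls; no separate
equivalence test is performed. qPCR relative expression is 2^(−ΔCt) with
ΔCt = Ct_target − Ct_control; base 2 is the standard amplification-doubling
convention. Candidate ranking counts three criteria — significant burden
association, differential expression, and peak expression within 35–55 DAP
(arg-max over supplied stages, window inclusive) — with unknown (absent)
inputs flagged as such rather than counted false; ties break by association
p-value then gene id.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: 870 accessions; 12
candidate paralogs in 5 families (the four-member family mirrors the
largest candidate family); 3 non-synonymous + 2 synonymous segregating sites
per gene (36 protein-changing sites total, placing the panel's burden
distribution across all three bins); allele frequencies uniform on
(0.10, 0.40), inside the MAF filter window so planted sites are retained;
Hardy–Weinberg unphased diploid genotypes with no missingness by default
(missing rates are injectable but no empirical rate was available to
emulate); phenotype baselines μ_SOC = 43 % (a typical winter-type seed oil
content), μ_OAC = 62 %, residual SDs σ_SOC = 2, σ_OAC = 3, and effects
β_SOC = +0.2 % per burden unit, β_OAC = −0.3 % per unit — signs chosen so
higher burden raises oil content and lowers oleic acid, magnitudes so the
high/low bin contrast is detectable at panel scale without being trivial.

The EMS simulator draws per-family mutation counts from
Poisson(rate × amplicon bp) at a default rate of 1/24,500 per bp per family
over 3,488 families, and places every mutation as a G:C→A:T transition at a
uniformly chosen G/C position — the canonical EMS alkylation spectrum.
Selfed progeny segregate 1:2:1 per heterozygous locus with unlinked loci.

Deliberately not modelled: linkage disequilibrium, population structure and
kinship, selection, per-gene effect heterogeneity (all genes share β),
genotyping error, and read-level data. Passing tests therefore demonstrate
that the pipeline's bookkeeping, annotation and inference are correct under
an additive, structure-free model — not that burden effects of this size
are detectable in a structured real panel, where kinship correction (out of
scope here) would be required.

All generators derive child seeds deterministically from one master seed by
stage name (CRC32 of the stage label mixed into a numpy `SeedSequence`), so
every artefact is bitwise reproducible and independent stages are decoupled.

## Numerical choices

Chi-square, ANOVA, Welch t and Tukey HSD come from scipy/statsmodels;
p-values are used as returned. Rounding uses decimal half-up where a printed
precision is specified (efficiencies to 0.1%, loads to two significant
figures), avoiding banker's-rounding surprises. Degenerate inputs are
explicit errors (zero explants, zero progeny, empty progeny sets, all-zero
segregation counts) or flagged results (all-missing genotype sites dropped
with a warning, non-testable bin configurations). Test problem sizes —
10,000 oracle SNPs, 2,000-accession exactness panels, 1000-replicate
calibration loops — were chosen to make stochastic assertions comfortably
stable at 3–4 standard deviations while keeping the default suite around
ten seconds.
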