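# Methods

## The screening model

The package targets species with genotypic sex determination and a single
sex-determining region, assayed by reduced-representation sequencing
(2b-RAD-style uniform tags). Two signatures identify sex linkage:

1. **Presence/absence**: a tag inside a region carried by only one sex
   chromosome is sequenced only in the heterogametic sex. The screen
   declares a tag male-exclusive when it is present in every male (up to
   `max_missing_target` missing calls, none confidently absent) and
   present in at most `max_present_other` females, and mirrored for
   female-exclusive tags. The defaults (0, 0) implement the strict
   all-present/all-absent rule appropriate for small discovery cohorts;
   the tolerances exist because real matrices have missing data.

2. **Heterozygosity**: at a SNP inside the sex-determining region of a ZW
   system, females (ZW) are obligate heterozygotes and males (ZZ)
   homozygotes. The association test therefore collapses the per-locus
   sex × {hom-ref, het, hom-alt} table to sex × {het, hom} and applies the
   two-sided Fisher exact test. Heterozygosity is exactly the quantity the
   downstream interpretation uses, which is why the collapse is the
   primary test; the full 2×3 exact (Freeman–Halton) p-value is computed
   alongside for users who want the uncollapsed view. No published
   description of the upstream genotype-caller's own p-value was
   available, so the test is defined here explicitly rather than imitated.

**Two-sided convention.** Conventions for two-sided Fisher tests differ;
this package uses the minimum-likelihood rule: the p-value is the sum of
the point probabilities, over all tables with the observed margins, that
do not exceed the observed table's point probability. scipy's
`fisher_exact` implements this rule; the test suite checks it against an
exhaustive exact-rational enumeration for every 2×2 table with all four
margins ≤ 30.

**Multiple testing.** Benjamini–Hochberg q-values are reported across all
tested loci but are deliberately not used for selection: candidate loci
are taken as the `top_k` (default 10) smallest p-values, ties broken by
locus id, mirroring rank-based marker discovery practice where the
follow-up is wet-lab validation rather than a significance claim.

**Presence re-calling.** When a depth matrix is available, presence is
re-called as depth ≥ `min_depth` (default 3), 0 < depth < `min_depth` as
missing, and 0 as absent. A single read is indistinguishable from index
hopping or alignment noise, hence the default; users with deeper or
shallower libraries should scale it.

**Heterogamety call.** A locus is called ZW when at least `min_fraction`
(default 1.0, i.e. all) of genotyped females are heterozygous and the same
fraction of males homozygous, XY for the mirror image, otherwise
inconclusive. The default demands a perfect pattern, which is what a
single-region model predicts in a discovery cohort; `min_fraction` < 1
accommodates genotyping error in larger cohorts.

## Validation statistics

At a validated marker in a breeding population, the **dominant genotype**
of a sex is defined as its modal genotype (the term is used loosely in the
marker-validation literature; the modal definition makes it computable).
Ties are broken toward the lexicographically smallest genotype and both
logged and recorded in the report's notes. Per-sex dominant fractions use
the full count of genotyped individuals of that sex as denominator —
mixing denominators (e.g. dividing a minority-genotype count by the
dominant count) is a known source of inconsistent published percentages,
so every reported fraction states its denominator implicitly through this
one rule. Overall consistency is the summed dominant counts over all
genotyped individuals; discordant individuals are those carrying any
non-dominant genotype. Proportions are reported to 4 decimals and as
half-up-rounded percentages to 2 decimals.

The **sex-ratio test** is the exact two-sided binomial test against 0.5,
summing Binomial(n, ½) point masses ≤ the observed mass (checked against
direct pmf summation for all n ≤ 200). The ratio string is
female:male with the quotient rounded half-up to 2 decimals.

### The ZW linkage/discordance model

Off-pattern genotypes (homozygous-alternate females, heterozygous males)
admit two genetic explanations that single-locus data cannot separate:
the Z chromosome may itself carry the "female" allele at frequency q > 0,
or phenotypic sex may disagree with chromosomal sex (sex reversal) at
rate r > 0. The model makes both explicit. With the W chromosome fixed
for the alternate allele, genotype laws over [hom-ref, het, hom-alt] are

- genetic females (ZW): F(q) = [0, 1−q, q]
- genetic males (ZZ): M(q) = [(1−q)², 2q(1−q), q²] (Hardy–Weinberg on Z)

and with a 1:1 genetic-sex prior (the Fisherian expectation — the observed
phenotypic imbalance is precisely what r and sampling are meant to
absorb), phenotypic cohorts follow the mixtures (1−r)F + rM and
(1−r)M + rF. The fit maximizes the two-cohort multinomial log-likelihood
over (q, r) ∈ [0,1] × [0,0.5] by a coarse grid (step 0.005 on both axes)
followed by coordinate-wise golden-section refinement within one grid
step; the r = 0 constrained profile is fitted the same way and its
log-likelihood is floored at the corresponding profile of the joint fit so
the unconstrained likelihood can never be lower. The likelihood-ratio
p-value for r > 0 uses the ½χ²₀ + ½χ²₁ boundary mixture, which is
approximate because r lies on the parameter boundary under the null; it is
reported as a guide, not a calibrated test. A table with a single nonzero
cell is fitted but flagged `converged=false`, its estimates being boundary
artifacts. Parameter recovery is verified at n = 5,000 (±0.02 over 20
seeds) and forward/inverse consistency at n = 1,000.

The model is explicitly a formalization built for this package: it
quantifies how much Z-linkage versus discordance a validation table
supports, and makes no claim about the biological cause (genotyping error,
true sex reversal, or Z-linked variation) of any individual discordance.

## Sequence annotation

A gene model is a cDNA with stated 5′UTR/CDS/3′UTR lengths; construction
asserts the lengths sum to the sequence length, the CDS length is a
multiple of 3, and the CDS starts with ATG and ends in a stop codon. All
coordinates are 1-based inclusive; RNA `U` is normalized to `T` on
ingestion so all internal sequences are DNA alphabet. Translation uses the
standard genetic code (appropriate for echinoderm nuclear genes), drops
the terminal stop, maps fully ambiguous codons to `X` and raises on an
internal stop naming the codon. A SNP at CDS position p lands in codon
⌈p/3⌉ at within-codon position ((p−1) mod 3)+1; the synonymous flag
compares translations of the reference and substituted codons.

`synthetic_spata4_model` builds a stand-in transcript honouring the
documented spata4 architecture — 489 + 825 + 494 = 1,808 bp, a 274-aa
protein, CAC at codon 175 so that C>T at CDS position 525 is the His→His
synonymous change — with seeded random non-stop filler codons, because the
real nucleotide sequence is not redistributed with this package. It is
synthetic: only the architecture, not the sequence, is faithful.

## qPCR relative expression

ΔCt = Ct_target − Ct_reference per sample (technical replicates averaged
first), ΔΔCt = ΔCt − mean ΔCt(control), per-sample fold = 2^−ΔΔCt. Group
folds are geometric means — folds are log-scale quantities, and the
geometric mean makes the control group normalize to exactly 1 — with
per-sample folds emitted so arithmetic summaries can be recomputed. The
group comparison is a Welch t-test on the ΔCt scale (the scale on which
the normality assumption is tenable); this is a stated convention, since
expression studies rarely say which scale their tests ran on. Amplification
efficiency is assumed to be 2.0 per cycle for both genes; no
standard-curve correction or multi-reference normalization is attempted.

## The simulator

`simulate_population` draws the study design the analysis assumes:
phenotypic cohort sizes are hit exactly (defaults 10♀/10♂, the discovery
design; validation-scale runs use 65♀/35♂), and genetic sex is drawn per
phenotypic individual from the conditional law implied by a 1:1 genetic
prior and flip probability r — the genetic sex of a phenotypic female is
female with probability 1−r — which is equivalent to flipping and
conditioning on the margins but needs no rejection loop. Sex-linked loci
use ref=G/alt=A (the validated marker's alleles) and the F(q)/M(q) laws
above; autosomal loci draw an alternate-allele frequency uniform on
[0.1, 0.9] and Hardy–Weinberg genotypes, giving realistic nulls for the
association screen. Planted exclusive tags follow *genetic* sex (so
discordant individuals carry the "wrong" tags, as they would in reality);
background tags are present independently with probability 0.95. Depth per
present tag is Poisson with mean `mean_depth` (default 33.75, a typical
2b-RAD average; only a mean is specified, so the least-informative
standard count model is used) truncated at ≥ 1 by resampling; cells are
masked missing with probability `missing_rate`. A single
`numpy.random.default_rng(seed)` drives every draw; no global RNG state is
touched, and equal seeds give byte-identical fixture files.

What the simulator does **not** emulate — and what passing tests therefore
do not establish about real data: read-level error (no FASTQ), linkage
disequilibrium between loci, multi-locus W/Z haplotype structure,
population structure or relatedness in the validation cohort, and
locus-specific genotyping error. Tests against simulated data validate the
statistical machinery, not the wet-lab assay.

## Numerical choices and edge cases

- Genotypes are unordered; the canonical text form sorts alleles
  lexicographically (`A/G`, never `G/A`). Missing is `./.` in both TSV and
  VCF; missing individuals are excluded per-locus, never imputed.
- Only the GT subfield of VCF FORMAT is consumed; other subfields are
  ignored with a logged warning. Candidate VCFs are written sorted by
  (scaffold, position) with p-value and heterogamety call in INFO keys
  `SEXP` and `HET`.
- Monomorphic loci and loci with an entirely ungenotyped sex are skipped
  and logged, not scored.
- Percent rounding is half-up (via `decimal`), so printed percentages are
  stable across platforms.
- Problem sizes in the test suite — 1,000-tag screens, n = 5,000
  likelihood recoveries, 4,000-individual frequency checks, the
  margins ≤ 30 Fisher sweep — were chosen as the smallest scales at which
  each property is sharply testable (3-SE bands, ±0.02 recovery).

## Known limitations

- The exclusive-tag screen is per-tag and sequence-blind: paralogous tags
  that collapse in clustering or primers that amplify both sex
  chromosomes (the dominant failure mode of tag validation) are invisible
  to it.
- The linkage model is single-locus; with several markers a joint
  haplotype model would separate q from r far better.
- The LRT for r > 0 is boundary-approximate, and with n = 100 the model
  has little power to distinguish q from r at all — the report shows both
  estimates precisely so that readers do not over-interpret either.
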