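# Methods

This note documents the statistical procedures implemented in `ddgrs`, the
assumptions behind them, the choices made where the design was genuinely
open, and what the synthetic-data validation does and does not demonstrate.

## Risk scores

The unweighted genetic risk score of an individual is the mean risk-allele
count over the scored SNPs, GRS = (Σ X_i)/n ∈ [0, 2]; the weighted score
uses natural-log odds-ratio weights, wGRS = (Σ w_i X_i)/n. Both divide by
the number of SNPs n. Some GRS conventions omit the division for the
weighted score; we keep it so the two scores stay on comparable scales and
the population closed form below is exact for both.

Population scores are computed from risk-allele frequencies,
GRS_pop = (Σ_i 2·RAF_i)/n, rather than by averaging individuals. Under
complete genotype data the two are identical (a tested invariant); the
closed form is what makes scoring 10,000 random SNP sets in every
population cheap. Missing dosages in individual scores divide by the count
of non-missing variants, avoiding the downward bias of dividing by n.

Dosages always count the risk allele. VCF records may store either allele
as REF; records with REF equal to the risk allele are complemented
(2 − ALT count). Any other allele pair raises an error — ambiguous-strand
(A/T, C/G) mismatches are never silently flipped, because a wrong flip
corrupts every downstream frequency. Multiallelic records are rejected;
the Fst estimator below assumes biallelic sites.

## Prevalence harmonisation

Studies are eligible when they sample the general (non-comorbid) population,
cover both sexes, and have n ≥ 100. Each exclusion carries a reason code
(`small_sample`, `single_sex`, `comorbid`, `not_general_population`,
checked in that order).

Age adjustment divides the observed prevalence by the *relative
contribution* r of the study's age window [lo, hi]:

    r = E[prev | age ∈ window] / E[prev],

both expectations under a reference age-specific prevalence curve p_d and
reference population age counts n_d (decade bins). This is the unique
reading under which a study covering the full age range is unadjusted, and
it operationalises the assumption that the *shape* of prevalence over age is
shared across countries while its level differs. Choices the formulation
leaves open, pinned here: partial bin coverage prorates the bin's count
linearly by years of overlap; open-ended windows extend to the end of the
reference range; studies with no stated age range pass through unadjusted
(matching how such studies are handled in practice). r = 0 (window entirely
inside a zero-prevalence region) is an error, not infinity.

Pooling is the sample-size-weighted mean with the pooled binomial standard
error sqrt(p(1−p)/ΣN). The shipped default age reference is **synthetic**
(a monotone-increasing decade curve with a thinning population pyramid);
real analyses must supply a measured curve as TSV.

## Matched random SNP sets and empirical p-values

Null sets contain one random SNP per risk variant, with reference-population
allele-frequency difference strictly below the tolerance (default 0.01).
Matching is per target — the stricter reading of frequency matching — and
sampling is uniform among eligible candidates, without reuse inside a set,
with reuse allowed across sets. For unassociated SNPs there is no "risk"
allele, so matching and scoring use the counted (ALT) allele frequency of
the frequency source as supplied; folding to minor-allele frequency would
discard the orientation the targets are expressed in. No LD pruning is
applied within sets or against the risk variants; this is a known
limitation.

The empirical p-value is the plain exceedance fraction
#{null > observed}/N with strict inequality and no +1 correction, so 3
exceedances among 10,000 sets give exactly 0.0003. The correlation test is
one-sided (only larger null correlations count); a two-sided variant on
|r| exists behind a flag.

## Weir–Cockerham Fst

Per-site differentiation uses the Weir & Cockerham (1984) variance-component
estimator θ = a/(a+b+c) for r populations, from diploid sample sizes,
counted-allele frequencies, and observed heterozygote proportions (the
component formulas are spelled out in `ddgrs/fst.py`). Negative finite-sample
estimates are preserved, never clipped. Sites monomorphic across all
populations have an undefined θ and are skipped in set summaries with a
logged count. All sites are treated as diploid autosomal; non-autosomal
variants are rejected.

Two set-level summaries are reported: the arithmetic mean of per-site θ
(the headline "mean Fst") and the ratio of summed numerators to summed
denominators ("weighted Fst"). The two conventions differ and both are
printed, since published set-level values do not always state which was
used. "Global" Fst is the same estimator with r equal to all panel
populations.

Significance of an observed set-mean Fst is a percentile test against the
set-mean Fst of the matched null sets: below the 2.5th percentile the
populations are more similar than matched random SNPs predict, above the
97.5th less. Percentiles use linear interpolation between order statistics
(with 10,000 null values the method choice is negligible but must be pinned
for reproducibility).

Because the candidate pool carries allele *frequencies* rather than
genotypes, null-set Fst is computed after parametrically drawing genotype
counts at each population's panel sample size under Hardy–Weinberg. This
gives the null estimates the same finite-sample noise and bias as the
observed panel estimates; scoring the null on the frequencies directly
would centre it near zero and spuriously flag weakly differentiated
populations as outliers.

## Pipeline conventions

Population merging (e.g. several panel populations sharing one literature
prevalence) applies to scores and prevalence only; Fst stays at the panel
population level, since differentiation is a property of the genotyped
populations themselves. The same merge, weighted by panel sample sizes, is
applied to every null set's scores before computing null correlations.
The reference population (default `GBR`) is the score-discovery population:
matching tolerances and pairwise Fst are both anchored to it.

## Synthetic data: what it emulates, and what it does not

Structure follows the Balding–Nichols model: each population's frequency is
Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral p ~ U(0.05, 0.95), with a
per-population differentiation parameter F. The default gradient
(0, 0.003, …, 0.15 over ten populations; ~100 diploids each; 26 risk
variants; a 2,600-SNP candidate pool with ≥ 30 guaranteed matches per
target) mirrors the span from closely related to strongly diverged human
populations at a scale the test suite can run in seconds. Large-sample
simulation shows the two-population weighted θ under this model converges to
F itself, which is the expectation the recovery tests use.

Prevalence truths follow a linear link clamp(α + β·GRS + ε, [0, 1]) with
Gaussian ε; by default α, β are calibrated at generation time to plant a
population-level correlation of 0.9 at noise 0.01 around a mean prevalence
of 0.08 (solving β·sd(GRS)/σ = r/√(1−r²)). Studies observe the truth
through a random age window — the observed value is truth × the window's
relative-contribution factor, so the age-adjustment step has exactly the
distortion it is designed to invert — plus binomial sampling at the study
size, with optional ineligible decoy studies to exercise the filters.

The generator omits LD between SNPs, demographic history, admixture,
genotyping error, and any systematic bias in literature prevalences beyond
age structure. Passing tests therefore demonstrate internal statistical
correctness and calibration of the machinery, not robustness to those
real-data complications.

## Numerical and degenerate-input conventions

Frequencies from samples with missing genotypes use complete-allele counts
(missing dosages excluded from numerator and denominator). Matching uses a
strict inequality at the tolerance boundary. Empty candidate pools, empty
null distributions, all-missing dosage vectors, zero-variance correlation
inputs, and r < 2 populations for Fst are errors, not NaNs. All generators
and the pipeline are deterministic given a seed; the null-Fst genotype
draws use a seed derived from the run seed so reruns are byte-identical.

## Known limitations

* The percentile Fst test inherits the matched null's blind spots: sets are
  matched on reference-population frequency only, not on LD, recombination
  context, or ascertainment of the risk variants.
* Set-level "mean Fst" (mean of ratios) is downward-biased relative to the
  ratio-of-sums estimator at low sample sizes; both are reported.
* The pooled binomial standard error ignores between-study heterogeneity.
* Age adjustment assumes a shared prevalence-over-age shape across
  populations; violations bias adjusted prevalences multiplicatively.
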