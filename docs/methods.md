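# Methods

This note documents the models implemented in `rescue_eval`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Six-category descent model

The classifier assigns each post-supplementation individual a posterior over
{pure resident, pure supplemented, F1, F2, backcross-to-resident,
backcross-to-supplemented}. Category c is characterised by φ_c, the
probability that a random autosomal locus carries (both genes of resident
origin, one of each, both supplemented): (1,0,0), (0,0,1), (0,1,0),
(¼,½,¼), (½,½,0), (0,½,½). Later backcross generations are not modelled —
they are progressively harder to distinguish with ~16 microsatellites and
are not expected one generation after supplementation.

Per locus, P(genotype | c) = Σ_o φ_c(o) P(genotype | o) with
P({x,y} | both-resident) the Hardy–Weinberg probability under resident
frequencies (likewise both-supplemented), and
P({x,y} | one-each) = p_res(x)p_sup(y) + p_res(y)p_sup(x) for heterozygotes,
p_res(x)p_sup(x) for homozygotes. Missing genotypes contribute likelihood 1
(the locus is dropped for that individual).

**Inference.** Gibbs sampling with data augmentation: each sweep resamples
(i) every mixture individual's category z given current frequencies and
mixing proportions, (ii) the per-locus origin configuration given z, and the
gene-by-gene origin within the one-each configuration, (iii) both pools'
per-locus allele frequencies from their Dirichlet full conditionals, and
(iv) the six mixing proportions. Reported posteriors are Rao-Blackwellised
(the conditional category probabilities are averaged over post-burn-in
sweeps, rather than indicator draws). Parental reference individuals enter
as fixed-origin (their gene copies always count toward their own pool and
they are excluded from the mixing proportions); this is the natural reading
of an analysis "conditioned on allele frequencies from two parental
samples", and it keeps frequency updates conjugate.

**Priors.** Jeffreys-like by default: Dirichlet(1/k_ℓ) per locus (k_ℓ
alleles) in each pool and Dirichlet(1/6) on mixing proportions; a uniform
(Dirichlet(1)) switch is provided. Defaults are 10⁴ burn-in and 10⁵
collection sweeps over three over-dispersed chains; chains are compared on
every posterior mean, and a maximum discrepancy above 0.05 triggers one
rerun at doubled length before the run is flagged unconverged. Power and
recovery studies in the test-suite use shortened chains (10³/10⁴ for the
power table at 200 simulated genotypes per class; 500/3000 for the
20-replicate recovery study) — sizes chosen to keep the full validation
suite fast while leaving conclusions unchanged at production lengths.

**Decision rule.** Hybrid iff posterior mass on the four admixed categories
exceeds 0.50 (strict). The mitochondrial override then adjusts the census:
a source-private haplotype in a nuclear pure-resident individual promotes it
to hybrid (maternal lineages cross only through admixture, so the nuclear
call was a false negative); a source-private haplotype with a nuclear
pure-supplemented assignment marks a pure-supplemented animal, which is
excluded from the census denominator, as are individuals older than the age
cutoff (born before supplementation). Missing haplotypes trigger no
override. Loci failing Hardy–Weinberg in a parental pool are reported but
not excluded.

**Power table.** Hybrids of each class are simulated by gamete sampling from
the parental samples' empirical allele frequencies (an F1 gamete is one
allele drawn per locus from a simulated F1 parent, etc.), classified
jointly, and tabulated: MAP assignments per class, the hybrid
false-negative rate under the >0.50 rule, and the class-misassignment rate
(1 − MAP agreement). On diverged parental pools the hybrid false-negative
rate is near zero while class-level assignment degrades from F1 through F2 —
hybrid detection is reliable even where pedigree-class assignment is not.

## Synthetic-data generator

Two parental gene pools are drawn from an F-model: per locus an ancestral
frequency vector (Dirichlet(1), floored at 0.05 to keep loci informative),
then each pool ~ Dirichlet(p_anc · (1−θ)/θ). θ (default 0.2) is the single
divergence knob and approximates the expected F_ST between pools; the
realised multi-locus F_ST of a given study varies around it. Defaults mirror
the motivating study design: 16 tetra-allelic microsatellite loci, samples
of 20 (resident, pre), 31 (source) and 48 (post), a post sample containing
4 F1 + 5 F2 + 3 backcross-to-resident + 3 pure-source individuals with the
rest pure resident, one over-age decoy, 0.5% missing genotypes. Generated
parental pools have mean H_E ≈ 0.52 and A_R ≈ 3.2, matching the diversity
of real microsatellite panels in this system. mtDNA: a 515-bp backbone
haplotype shared by all resident matrilines plus four source-private
haplotypes placed 9–31 substitutions away; haplotypes follow the dam
(F1 and F2 dams are supplemented-lineage ewes because only ewes were
translocated; a backcross-to-resident dam is either side with probability ½).

What the generator does **not** emulate: genotyping error, allele dropout
and null alleles, linkage, drift between the pre and post sampling dates,
family structure within samples, and microsatellite mutation. Passing
recovery tests therefore demonstrate correctness of the estimators under
the model's own assumptions, not robustness to those artefacts.

## Demographic screen

**Stage table** (defaults; one truncated-normal draw per parameter per run,
shared across years and individuals — parameter uncertainty, not
year-to-year environmental noise):

| transition into age | survival mean (SD) | ewe age | fecundity mean (SD) |
|---|---|---|---|
| 1 (lamb) | 0.450 (0.1500) | 1 | 0 |
| 2 | 0.825 (0.0625) | 2 | 0.300 (0.0125) |
| 3–7 | 0.940 (0.0200) | 3–13 | 0.950 (0.00625) |
| 8–13 | 0.875 (0.0375) | 14–16 | 0.400 (0.0125) |
| 14–16 | 0.600 (0.1000) | | |

Draws are truncated to [0,1] (they are probabilities). Within a simulated
year, every animal first advances one age class with its age-specific
survival (death past age 16), then each surviving ewe aged ≥2 produces a
single lamb with her age-specific fecundity (twinning is rare in mountain
sheep); lamb sex is Bernoulli(½), males share female survival and never
reproduce. Founder ewes that arrived aged ≥2 were likely pregnant at
release, so their first-year litters are pure-supplemented: they are dropped
from the model (they are identified and excluded in sampling, and
pure-supplemented breeding within the six-year horizon is treated as
negligible). A run's result is the number of hybrid-lineage descendants at
or below the age cutoff after the elapsed years; founders are never counted.

**Expected hybrids.** The stable age distribution of the Leslie matrix built
from stage means gives the fraction of a stable population young enough to
be sampled; multiplied by the census estimate it gives the adjusted
population size, and by the observed hybrid proportion the expected hybrid
count E. Runs with final counts within ±10% of E (a prior allowance for
census error and deviation from stable age structure) contribute their
lamb-survival draws to a mean ± 2 SD pseudo-95% interval, compared against
the maximum pre-supplementation lambs-per-100-ewes value (a conservative
bound, since herd inventories overestimate survival to age 1).

**Matrix convention.** 17 age classes (0–16); subdiagonal = mean survivals;
first row = mean fecundity at the ewe's own age × ½ (equal birth sex ratio
and equal-sex survival make the total-population age structure equal the
female-only structure with halved fecundity). Under this convention the
stable-age fraction at or below 6 years is 73.6% (74% to the nearest
percent). The stage table's age column can also be read as labelling
transitions, shifting fecundity one age later (`fecundity_shift=-1`), which
gives 70.9%; the reference figure of 72% lies between the two readings, and
the package exposes the shift as a configuration switch rather than
adjudicating. The expected-hybrid arithmetic is reported to one decimal;
one published value (25.7) differs from the recomputation (25.8) by a
rounding of intermediate values.

## Diversity statistics

- H_E: Nei's unbiased (2n/(2n−1))(1 − Σp²); H_D is the haplotype analogue
  with n = sequences. Both reach their bound (1) only for all-singleton
  samples.
- Allelic richness: expected allele count in g gene copies drawn without
  replacement, g defaulting to twice the smallest number of complete
  genotypes at that locus across the populations compared.
- Hardy–Weinberg: exact conditional test (Levene distribution given allele
  counts); complete enumeration of genotype arrays when the table space is
  small (≤10⁶ by a crude bound), otherwise vectorised Monte-Carlo
  permutation of gene copies (default 10⁵ shuffles, +1 correction); Holm
  correction across locus × population tests.
- Relatedness: Lynch–Ritland (1999) regression estimator by default
  (information-weighted across loci, both reference/proband directions
  averaged), Queller–Goodnight (1989) as a switch; the published analysis
  cites "r" without a formula, so both common estimators are provided.
  Reference allele frequencies are the pooled pre+post sample of the
  population under comparison — per-sample references would shift the mean
  by a sample-size artefact rather than by kinship. CIs are percentile
  bootstrap over pairwise values (9999 resamples by default). Pairs sharing
  no typed locus are excluded and logged.
- Pre/post comparisons: paired t-tests across loci (df = n_loci − 1).
- k (mean pairwise nucleotide differences): unbiased n/(n−1) form; whether
  the original analyses used the biased or unbiased form is not stated, and
  the unbiased form is adopted throughout.

Haplotype collapsing uses exact identity with pairwise deletion of N/gap
positions: unambiguous sequences define haplotypes; an ambiguous sequence
compatible with exactly one haplotype joins it, otherwise it is left
unresolved rather than forced (mirroring how an unresolved field sample is
treated as missing). Labels are assigned A, B, … by descending count. Note
that pairwise-deletion identity is not transitive; defining haplotypes by
the unambiguous sequences first makes the procedure deterministic.

## Known limitations

- Classification power depends on realised parental differentiation: at
  θ ≈ 0.2 with 16 loci, backcross-to-resident and pure-resident overlap, and
  for unlucky frequency draws pure residents are misassigned as backcrosses
  even with the true frequencies in hand (the error is in the data, not the
  sampler). Hybrid *detection* (the >0.50 rule) remains much more reliable
  than class assignment.
- The mean-H_E increase after supplementation at the default composition
  (~25% admixed individuals) is comparable to its between-sample noise, so
  its direction flips in a minority of replicate studies; the allelic
  richness and relatedness shifts are more robust. This mirrors the
  motivating analysis, where the heterozygosity increase was not significant
  in one of the two treatment herds.
- The demographic model has no density dependence, disease, immigration or
  male-limited breeding; the lamb-survival interval is a consistency bound,
  not a survival estimate.
- The synthetic truth-table validation covers estimator correctness, not
  genotyping artefacts (see generator section).
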