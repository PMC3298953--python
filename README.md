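# rescue-eval

Evaluation toolkit for **genetic-rescue supplementation experiments** in
wild ungulate populations. When a declining, inbred herd is supplemented
with animals from a genetically distinct source population, a manager needs
to answer three questions one generation later:

1. **Did introgression happen?** — identify interpopulation hybrids from
   multilocus microsatellite genotypes and maternally inherited mtDNA
   haplotypes;
2. **Did it hurt?** — screen for outbreeding depression by asking what range
   of juvenile (lamb) survival is consistent with the number of
   hybrid-lineage animals observed;
3. **Did diversity recover?** — compare heterozygosity, rarefacted allelic
   richness, relatedness and mitochondrial diversity before and after
   supplementation.

The package implements the full analysis pipeline for that design, plus a
synthetic-data generator with known ground truth (two diverged parental gene
pools, admixed individuals of known pedigree class, source-private
haplotypes) so that every stage can be validated end to end.

## The models

**Hybrid classification.** Each individual is assigned a posterior over six
categories of descent — pure resident, pure supplemented, F1, F2 and the two
first-generation backcrosses — distinguishable by the expected proportion of
loci with (both genes resident, one from each pool, both supplemented):

| category | both res. | one each | both sup. |
|---|---|---|---|
| pure resident | 1 | 0 | 0 |
| pure supplemented | 0 | 0 | 1 |
| F1 | 0 | 1 | 0 |
| F2 | ¼ | ½ | ¼ |
| BX (×res) | ½ | ½ | 0 |
| BX (×sup) | 0 | ½ | ½ |

Genotype likelihoods mix Hardy–Weinberg terms over those origin
configurations; inference is Gibbs sampling with per-locus origin
augmentation, Dirichlet-conjugate allele-frequency updates, parental
reference individuals held at their known pure category, and Jeffreys-like
priors. An individual is called a hybrid when the posterior mass on the four
admixed categories exceeds 0.50; a source-private mtDNA haplotype overrides
a pure-resident nuclear call (maternal lineages cannot cross without
admixture).

**Outbreeding-depression screen.** A stochastic, individual-based
transition-matrix model projects the supplemented-ewe cohort through the
years to resampling. Each run draws one value per stage-specific survival
and fecundity parameter from truncated-normal distributions; runs whose
hybrid-lineage descendant count lands within ±10% of the expected hybrid
number (hybrid proportion × stable-age-adjusted census, with the stable age
structure from Leslie-matrix eigenanalysis) contribute their lamb-survival
draw to a mean ± 2 SD pseudo-95% interval, read against pre-supplementation
lambs-per-100-ewes baselines.

**Diversity change.** Nei's unbiased expected heterozygosity, rarefacted
allelic richness (hypergeometric expectation for a fixed number of gene
copies), exact Hardy–Weinberg tests (Levene conditional distribution,
enumerated or Monte-Carlo, Holm-corrected), Lynch–Ritland or
Queller–Goodnight pairwise relatedness with bootstrap CIs, unbiased
haplotype diversity H_D and mean pairwise nucleotide differences k.

## Worked example

```python
from rescue_eval import synthetic_data as sd, hybrid_model as hm, demography as dem

study = sd.build_study(sd.GeneratorSpec(seed=1))   # 16 loci, 3 samples, known truth
settings = hm.McmcSettings(burn_in=1000, sweeps=5000, n_chains=2, seeds=[11, 223])
posteriors, diags = hm.run_gibbs(study.post, study.resident_pre, study.source, settings)
private = set(study.haplotype_sequences) - {sd.SHARED_HAPLOTYPE}
_, census = hm.apply_mtdna_override(posteriors, study.post.individuals, private, age_cutoff=6)
print(f"hybrids: {census['n_hybrids']} of {census['denominator']} ({100*census['proportion']:.1f}%)")

lam, vec, prop = dem.stable_age_distribution(dem.build_leslie(), age_cutoff=6)
print(f"lambda = {lam:.3f}, proportion aged <=6 = {prop:.3f}")
e, lo, hi = dem.expected_hybrids(census["proportion"], round(175 * prop))
runs = dem.run_ensemble([2,2,3,3,3,4,4,5,5,6,6,7,7,1,1], n_runs=10_000, seed=1)
interval = dem.infer_lamb_survival(runs, (lo, hi))
print(f"lamb survival {interval.mean:.3f} -> ({interval.lower:.3f}, {interval.upper:.3f})")
print(dem.compare_to_baseline(interval, [11, 26])["verdict"])
```

prints

```
hybrids: 12 of 45 (26.7%)
lambda = 1.036, proportion aged <=6 = 0.736
lamb survival 0.498 -> (0.289, 0.707)
at or above baseline
```

The generated study contained 12 admixed individuals among the 45 eligible
post-supplementation animals, so the classifier-plus-override census is
exact here; the population grows at λ ≈ 1.04 with ~74% of a stable
population at or below the 6-year sampling cutoff; and the lamb-survival
values consistent with that census sit at or above the herd's
pre-supplementation recruitment (11–26 lambs per 100 ewes) — no
outbreeding-depression signal.

A `rescue-eval` command-line tool wraps the same stages
(`simulate | classify | power | demography | report`).

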