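"""Bayesian assignment of individuals to six categories of descent.

Given multilocus codominant genotypes and two parental reference samples
(resident herd and supplemented source), each unknown individual receives a
posterior over {pure_res, pure_sup, F1, F2, BX_res, BX_sup}. Each category c
is characterised by the probabilities phi_c that a random locus carries (both
genes resident, one from each pool, both supplemented); genotype likelihoods
mix Hardy-Weinberg terms over those origin configurations. Inference is by
Gibbs sampling with explicit per-locus origin augmentation so that allele
frequencies stay Dirichlet-conjugate; parental individuals are held fixed at
their pure category. An individual is called a hybrid when its posterior mass
on the four admixed categories exceeds 0.50; a source-private mitochondrial
haplotype overrides a pure-resident nuclear call, since maternal lineages
cannot cross without admixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import Individual, PopulationSample, logger
from .synthetic_data import CLASSES, simulate_individual

# origin-configuration probabilities (both-resident, one-each, both-supplemented)
PHI = {
    "pure_res": (1.0, 0.0, 0.0),
    "pure_sup": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BX_res": (0.5, 0.5, 0.0),
    "BX_sup": (0.0, 0.5, 0.5),
}
PHI_MATRIX = np.array([PHI[c] for c in CLASSES])  # (6, 3)
HYBRID_CLASSES = ("F1", "F2", "BX_res", "BX_sup")
_HYBRID_IDX = [CLASSES.index(c) for c in HYBRID_CLASSES]


@dataclass
class McmcSettings:
    """Sampler lengths and priors.

    Defaults mirror a long production run (1e4 burn-in, 1e5 collection
    sweeps, three over-dispersed chains); tests and power studies use shorter
    chains. ``prior='jeffreys'`` puts Dirichlet(1/k) on each locus's
    frequencies per pool and Dirichlet(1/6) on the mixing proportions;
    ``'uniform'`` uses Dirichlet(1).
    """

    burn_in: int = 10_000
    sweeps: int = 100_000
    n_chains: int = 3
    seeds: list[int] = field(default_factory=lambda: [101, 2002, 30003])
    prior: str = "jeffreys"
    convergence_tol: float = 0.05

    def __post_init__(self) -> None:
        if self.burn_in <= 0 or self.sweeps <= 0:
            raise ValueError("burn_in and sweeps must be positive")
        if self.prior not in ("jeffreys", "uniform"):
            raise ValueError(f"unknown prior {self.prior!r}")
        if len(set(self.seeds)) < self.n_chains:
            raise ValueError("need n_chains distinct seeds")


@dataclass
class HybridPosterior:
    """Per-individual category posterior and the hybrid call derived from it."""

    id: str
    posterior: dict[str, float]
    hybrid_flag: bool
    basis: str = "nuclear"  # {nuclear, mtDNA_override, both}

    @classmethod
    def from_vector(cls, ind_id: str, vec: np.ndarray) -> "HybridPosterior":
        post = {c: float(v) for c, v in zip(CLASSES, vec)}
        hyb = sum(post[c] for c in HYBRID_CLASSES) > 0.50
        return cls(id=ind_id, posterior=post, hybrid_flag=hyb)

    @property
    def hybrid_mass(self) -> float:
        return sum(self.posterior[c] for c in HYBRID_CLASSES)

    @property
    def map_category(self) -> str:
        return max(self.posterior, key=self.posterior.get)


def genotype_likelihood(
    genotype: tuple[int, int] | None,
    category: str,
    freqs_res_locus: dict[int, float],
    freqs_sup_locus: dict[int, float],
) -> float:
    """P(genotype at one locus | category), mixing HWE over gene origins.

    A missing genotype contributes 1 (the locus is dropped). Raises if an
    observed allele is absent from both pools' frequency maps.
    """
    if category not in PHI:
        raise ValueError(f"unknown category {category!r}")
    if genotype is None:
        return 1.0
    a, b = genotype
    for allele in (a, b):
        if allele not in freqs_res_locus and allele not in freqs_sup_locus:
            raise ValueError(f"allele {allele} absent from both frequency maps")
    pr = freqs_res_locus.get
    ps = freqs_sup_locus.get
    if a == b:
        p_rr = pr(a, 0.0) ** 2
        p_ss = ps(a, 0.0) ** 2
        p_rs = pr(a, 0.0) * ps(a, 0.0)
    else:
        p_rr = 2.0 * pr(a, 0.0) * pr(b, 0.0)
        p_ss = 2.0 * ps(a, 0.0) * ps(b, 0.0)
        p_rs = pr(a, 0.0) * ps(b, 0.0) + pr(b, 0.0) * ps(a, 0.0)
    phi = PHI[category]
    return phi[0] * p_rr + phi[1] * p_rs + phi[2] * p_ss


def posterior_fixed_frequencies(
    individual: Individual,
    freqs_res: dict,
    freqs_sup: dict,
    mixing: dict[str, float] | None = None,
) -> HybridPosterior:
    """Exact category posterior with allele frequencies held fixed.

    With known frequencies and fixed mixing proportions the posterior is the
    normalised product of per-locus likelihoods; no sampling is involved.
    """
    log_l = np.zeros(len(CLASSES))
    for locus, geno in individual.genotype.items():
        lik = np.array(
            [
                genotype_likelihood(geno, c, freqs_res[locus], freqs_sup[locus])
                for c in CLASSES
            ]
        )
        with np.errstate(divide="ignore"):
            log_l += np.log(lik)
    if mixing is not None:
        with np.errstate(divide="ignore"):
            log_l += np.log(np.array([mixing[c] for c in CLASSES]))
    log_l -= log_l.max()
    vec = np.exp(log_l)
    vec /= vec.sum()
    return HybridPosterior.from_vector(individual.id, vec)


# ---------------------------------------------------------------------------
# Gibbs sampler


class _EncodedData:
    """Integer-coded genotypes and fixed parental allele counts."""

    def __init__(
        self,
        mixture: list[Individual],
        parental_res: PopulationSample,
        parental_sup: PopulationSample,
    ):
        loci = parental_res.loci
        universe: dict[str, list[int]] = {}
        for locus in loci:
            alleles: set[int] = set()
            for coll in (mixture, parental_res.individuals, parental_sup.individuals):
                for ind in coll:
                    pair = ind.genotype.get(locus)
                    if pair is not None:
                        alleles.update(pair)
            universe[locus] = sorted(alleles)
        polymorphic = [l for l in loci if len(universe[l]) >= 2]
        if not polymorphic:
            raise ValueError("no polymorphic shared loci between the samples")
        self.loci = loci
        self.universe = universe
        self.n_alleles = np.array([len(universe[l]) for l in loci])
        self.kmax = int(self.n_alleles.max())
        self.n_loci = len(loci)
        self.ids = [ind.id for ind in mixture]
        n = len(mixture)
        self.ia = np.zeros((n, self.n_loci), dtype=np.int64)
        self.ib = np.zeros((n, self.n_loci), dtype=np.int64)
        self.observed = np.zeros((n, self.n_loci), dtype=bool)
        code = {
            locus: {a: i for i, a in enumerate(universe[locus])} for locus in loci
        }
        for i, ind in enumerate(mixture):
            for l, locus in enumerate(loci):
                pair = ind.genotype.get(locus)
                if pair is None:
                    continue
                self.ia[i, l] = code[locus][pair[0]]
                self.ib[i, l] = code[locus][pair[1]]
                self.observed[i, l] = True
        self.base_counts = np.zeros((2, self.n_loci, self.kmax))
        for pool, sample in ((0, parental_res), (1, parental_sup)):
            for l, locus in enumerate(loci):
                for allele, count in sample.allele_counts(locus).items():
                    self.base_counts[pool, l, code[locus][allele]] += count
        self.valid = np.zeros((self.n_loci, self.kmax), dtype=bool)
        for l in range(self.n_loci):
            self.valid[l, : self.n_alleles[l]] = True


def _sample_categorical_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one index per row of an unnormalised probability matrix."""
    cum = np.cumsum(probs, axis=-1)
    u = rng.random(probs.shape[:-1]) * cum[..., -1]
    return (u[..., None] > cum).sum(axis=-1)


def _run_chain(
    data: _EncodedData,
    burn_in: int,
    sweeps: int,
    prior: str,
    seed: int,
    update_frequencies: bool = True,
    update_mixing: bool = True,
    init_freqs: np.ndarray | None = None,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    L, kmax = data.n_loci, data.kmax
    n = len(data.ids)
    arangeL = np.arange(L)

    freq_prior = np.where(
        data.valid,
        (1.0 / data.n_alleles)[:, None] if prior == "jeffreys" else 1.0,
        0.0,
    )
    pi_prior = np.full(len(CLASSES), 1.0 / 6.0 if prior == "jeffreys" else 1.0)

    # initialise frequencies from parental counts + prior, pi at uniform
    if init_freqs is not None:
        freqs = init_freqs.copy()
    else:
        alpha0 = data.base_counts + freq_prior
        freqs = alpha0 / alpha0.sum(axis=2, keepdims=True)
        freqs[:, ~data.valid] = 0.0
    pi = np.full(len(CLASSES), 1.0 / 6.0)

    het = (data.ia != data.ib) & data.observed
    post_accum = np.zeros((n, len(CLASSES)))
    n_acc = 0

    for sweep in range(burn_in + sweeps):
        fr_a = freqs[0][arangeL, data.ia]
        fr_b = freqs[0][arangeL, data.ib]
        fs_a = freqs[1][arangeL, data.ia]
        fs_b = freqs[1][arangeL, data.ib]
        p_rr = fr_a * fr_b * (1.0 + het)
        p_ss = fs_a * fs_b * (1.0 + het)
        p_rs = fr_a * fs_b + np.where(het, fr_b * fs_a, 0.0)
        p3 = np.stack([p_rr, p_rs, p_ss], axis=-1)  # (n, L, 3)
        p3[~data.observed] = 1.0

        m = p3 @ PHI_MATRIX.T  # (n, L, 6)
        with np.errstate(divide="ignore"):
            ll = np.log(m).sum(axis=1) + np.log(pi)
        ll -= ll.max(axis=1, keepdims=True)
        w = np.exp(ll)
        w /= w.sum(axis=1, keepdims=True)
        if sweep >= burn_in:
            post_accum += w  # Rao-Blackwellised category posterior
            n_acc += 1
        z = _sample_categorical_rows(w, rng)

        # per-locus origin configuration given z
        o_probs = PHI_MATRIX[z][:, None, :] * p3  # (n, L, 3)
        o = _sample_categorical_rows(o_probs, rng)

        # direction of the one-each configuration at heterozygous loci
        p_dir1 = fr_a * fs_b
        p_dir2 = fr_b * fs_a
        with np.errstate(divide="ignore", invalid="ignore"):
            take_a_res = rng.random((n, L)) < np.where(
                p_dir1 + p_dir2 > 0, p_dir1 / (p_dir1 + p_dir2), 0.5
            )

        if update_frequencies:
            obs = data.observed
            both_res = (o == 0) & obs
            one_each = (o == 1) & obs
            both_sup = (o == 2) & obs
            res_from_a = both_res | (one_each & take_a_res)
            res_from_b = both_res | (one_each & ~take_a_res)
            sup_from_a = both_sup | (one_each & ~take_a_res)
            sup_from_b = both_sup | (one_each & take_a_res)
            flat_a = arangeL[None, :] * kmax + data.ia
            flat_b = arangeL[None, :] * kmax + data.ib
            size = L * kmax
            counts_res = (
                np.bincount(flat_a[res_from_a], minlength=size)
                + np.bincount(flat_b[res_from_b], minlength=size)
            ).reshape(L, kmax)
            counts_sup = (
                np.bincount(flat_a[sup_from_a], minlength=size)
                + np.bincount(flat_b[sup_from_b], minlength=size)
            ).reshape(L, kmax)
            alpha = data.base_counts + freq_prior
            alpha[0] += counts_res
            alpha[1] += counts_sup
            gam = rng.standard_gamma(alpha)
            gam[:, ~data.valid] = 0.0
            freqs = gam / gam.sum(axis=2, keepdims=True)

        if update_mixing:
            z_counts = np.bincount(z, minlength=len(CLASSES))
            gam_pi = rng.standard_gamma(pi_prior + z_counts)
            pi = gam_pi / gam_pi.sum()

    return post_accum / n_acc


def run_gibbs(
    post_sample: PopulationSample | list[Individual],
    parental_res: PopulationSample,
    parental_sup: PopulationSample,
    settings: McmcSettings | None = None,
    update_frequencies: bool = True,
    update_mixing: bool = True,
    fixed_frequencies: tuple[dict, dict] | None = None,
) -> tuple[list[HybridPosterior], dict]:
    """Category posteriors for every individual in ``post_sample``.

    Runs ``settings.n_chains`` independent chains from over-dispersed seeds,
    averages the post-burn-in category posteriors, and reports the maximum
    across-chain discrepancy. If the discrepancy exceeds the tolerance the
    run is repeated once with doubled sweeps before being flagged.

    ``fixed_frequencies`` pins the pool allele frequencies at the given
    (resident, supplemented) maps and disables their updating; with
    ``update_mixing=False`` as well, the per-individual posterior is computed
    under known frequencies and a uniform prior (no information is shared
    between individuals, so the result equals direct normalisation of the
    per-individual likelihoods).
    """
    settings = settings or McmcSettings()
    mixture = (
        post_sample.individuals
        if isinstance(post_sample, PopulationSample)
        else list(post_sample)
    )
    data = _EncodedData(mixture, parental_res, parental_sup)
    init_freqs = None
    if fixed_frequencies is not None:
        update_frequencies = False
        init_freqs = np.zeros((2, data.n_loci, data.kmax))
        for pool, fmap in enumerate(fixed_frequencies):
            for l, locus in enumerate(data.loci):
                for i, allele in enumerate(data.universe[locus]):
                    init_freqs[pool, l, i] = fmap[locus].get(allele, 0.0)
    logger.info(
        "run_gibbs: n=%d loci=%d burn=%d sweeps=%d chains=%d",
        len(mixture), data.n_loci, settings.burn_in, settings.sweeps,
        settings.n_chains,
    )

    def run_all(burn: int, sweeps: int) -> tuple[np.ndarray, float]:
        chains = [
            _run_chain(data, burn, sweeps, settings.prior, seed,
                       update_frequencies=update_frequencies,
                       update_mixing=update_mixing, init_freqs=init_freqs)
            for seed in settings.seeds[: settings.n_chains]
        ]
        stacked = np.stack(chains)
        disc = float(np.max(stacked.max(axis=0) - stacked.min(axis=0))) if len(chains) > 1 else 0.0
        return stacked.mean(axis=0), disc

    mean_post, discrepancy = run_all(settings.burn_in, settings.sweeps)
    reran = False
    if discrepancy > settings.convergence_tol:
        mean_post, discrepancy = run_all(settings.burn_in * 2, settings.sweeps * 2)
        reran = True
    diagnostics = {
        "max_chain_discrepancy": discrepancy,
        "converged": discrepancy <= settings.convergence_tol,
        "reran_with_doubled_sweeps": reran,
        "n_chains": settings.n_chains,
    }
    posteriors = [
        HybridPosterior.from_vector(ind_id, mean_post[i])
        for i, ind_id in enumerate(data.ids)
    ]
    return posteriors, diagnostics


# ---------------------------------------------------------------------------
# Decision rule with the mtDNA override


def apply_mtdna_override(
    posteriors: list[HybridPosterior],
    individuals: list[Individual],
    source_private_haplotypes: set[str],
    age_cutoff: int = 6,
) -> tuple[list[HybridPosterior], dict]:
    """Final hybrid census combining nuclear calls with maternal lineages.

    A source-private haplotype in a nuclear pure-resident individual promotes
    it to hybrid (the nuclear call was a likely false negative: maternal
    lineages only cross via admixture). A source-private haplotype with a
    nuclear pure-supplemented call marks a pure-supplemented animal, which is
    excluded, as are individuals older than ``age_cutoff`` (born before the
    supplementation). A missing haplotype triggers no override.
    """
    by_id = {ind.id: ind for ind in individuals}
    hybrids: list[str] = []
    excluded: list[tuple[str, str]] = []
    updated: list[HybridPosterior] = []
    for post in posteriors:
        ind = by_id[post.id]
        post = HybridPosterior(
            id=post.id, posterior=dict(post.posterior),
            hybrid_flag=post.hybrid_flag, basis=post.basis,
        )
        if ind.age is not None and ind.age > age_cutoff:
            excluded.append((post.id, "over_age"))
            updated.append(post)
            continue
        has_private = (
            ind.mt_haplotype is not None
            and ind.mt_haplotype in source_private_haplotypes
        )
        if has_private and not post.hybrid_flag:
            if post.map_category == "pure_sup":
                excluded.append((post.id, "pure_supplemented"))
                updated.append(post)
                continue
            post.hybrid_flag = True
            post.basis = "mtDNA_override"
        elif has_private and post.hybrid_flag:
            post.basis = "both"
        if post.hybrid_flag:
            hybrids.append(post.id)
        updated.append(post)

    n_sampled = len(posteriors)
    n_excluded = len(excluded)
    denom = n_sampled - n_excluded
    census = {
        "n_sampled": n_sampled,
        "n_excluded": n_excluded,
        "exclusions": excluded,
        "n_hybrids": len(hybrids),
        "hybrid_ids": hybrids,
        "denominator": denom,
        "proportion": len(hybrids) / denom if denom else float("nan"),
    }
    return updated, census


# ---------------------------------------------------------------------------
# Power assessment on simulated hybrids


def power_simulation(
    parental_res: PopulationSample,
    parental_sup: PopulationSample,
    n_per_class: int = 1000,
    settings: McmcSettings | None = None,
    seed: int = 0,
) -> "pd.DataFrame":
    """Error rates of the classifier on simulated known-category hybrids.

    Simulates ``n_per_class`` genotypes in each of F1, F2, BX_res and BX_sup
    by gamete sampling from the parental samples' empirical allele
    frequencies, classifies them all jointly, and tabulates per-class MAP
    assignments, the hybrid false-negative rate under the >0.50 rule
    ("hybrid_error"), and the hybrid-class misassignment rate ("class_error",
    1 - MAP agreement with the true class).
    """
    import pandas as pd

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    freqs_res = _empirical_frequencies(parental_res)
    freqs_sup = _empirical_frequencies(parental_sup)
    sims: list[Individual] = []
    truth: list[str] = []
    for cls in HYBRID_CLASSES:
        for i in range(n_per_class):
            sims.append(
                simulate_individual(
                    cls, freqs_res, freqs_sup, "supplemented", rng,
                    id=f"sim_{cls}_{i}", population="SIM",
                )
            )
            truth.append(cls)
    posteriors, _ = run_gibbs(sims, parental_res, parental_sup, settings)

    rows = []
    truth_arr = np.array(truth)
    for cls in HYBRID_CLASSES:
        sel = [p for p, t in zip(posteriors, truth_arr) if t == cls]
        maps = np.array([p.map_category for p in sel])
        flags = np.array([p.hybrid_flag for p in sel])
        row = {"true_class": cls, "n": len(sel)}
        for target in CLASSES:
            row[f"assigned_{target}"] = int((maps == target).sum())
        row["n_hybrid"] = int(flags.sum())
        row["hybrid_error"] = 1.0 - flags.mean()
        row["class_error"] = 1.0 - (maps == cls).mean()
        rows.append(row)
    total = {
        "true_class": "total",
        "n": len(posteriors),
        **{
            f"assigned_{t}": sum(r[f"assigned_{t}"] for r in rows) for t in CLASSES
        },
        "n_hybrid": sum(r["n_hybrid"] for r in rows),
        "hybrid_error": 1.0
        - sum(r["n_hybrid"] for r in rows) / len(posteriors),
        "class_error": float("nan"),
    }
    rows.append(total)
    return pd.DataFrame(rows)


def _empirical_frequencies(sample: PopulationSample) -> dict:
    freqs: dict[str, dict[int, float]] = {}
    for locus in sample.loci:
        counts = sample.allele_counts(locus)
        n = sum(counts.values())
        freqs[locus] = {a: c / n for a, c in counts.items()}
    return freqs
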