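"""Synthetic study generator: two diverged parental gene pools plus admixture.

The real study genotypes were never deposited, so every downstream stage is
exercised on generated data with known ground truth. The generator emulates
the study's shape: ~16 polymorphic microsatellite loci, a resident herd and a
genetically distinct source herd (differentiation controlled by a single
F-model drift parameter), maternally inherited control-region haplotypes with
four source-private haplotypes and one shared resident haplotype, and a
post-supplementation sample containing admixed individuals of known category
(F1, F2, and the two backcrosses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import Individual, PopulationSample, logger

CLASSES = ("pure_res", "pure_sup", "F1", "F2", "BX_res", "BX_sup")

SHARED_HAPLOTYPE = "E"


@dataclass
class GeneratorSpec:
    """Knobs of the synthetic study.

    ``divergence`` is the F-model drift parameter theta in (0,1): both pools'
    per-locus allele frequencies are Dirichlet draws around a common ancestral
    vector with concentration (1-theta)/theta, so expected F_ST between the
    pools is approximately theta. The default 0.2 reflects strongly diverged
    reintroduction stocks (distinct source herds, private haplotypes).
    """

    n_loci: int = 16
    alleles_per_locus: int | list[int] = 4
    divergence: float = 0.2
    sample_sizes: dict = field(
        default_factory=lambda: {"resident_pre": 20, "source": 31, "post": 48}
    )
    hybrid_composition: dict = field(
        default_factory=lambda: {"F1": 4, "F2": 5, "BX_res": 3, "pure_sup": 3}
    )
    mt_private_haplotypes: int = 4
    missing_rate: float = 0.005
    n_overage: int = 1
    seq_length: int = 515
    age_cutoff: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.divergence < 1.0:
            raise ValueError("divergence must be in (0,1)")
        if isinstance(self.alleles_per_locus, int):
            self.alleles_per_locus = [self.alleles_per_locus] * self.n_loci
        if len(self.alleles_per_locus) != self.n_loci:
            raise ValueError("alleles_per_locus length != n_loci")
        if any(v < 0 for v in self.sample_sizes.values()):
            raise ValueError("sample sizes must be >= 0")
        if any(v < 0 for v in self.hybrid_composition.values()):
            raise ValueError("hybrid_composition counts must be >= 0")
        bad = set(self.hybrid_composition) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown classes in hybrid_composition: {sorted(bad)}")
        if sum(self.hybrid_composition.values()) > self.sample_sizes["post"]:
            raise ValueError("hybrid_composition total exceeds post sample size")

    @property
    def loci(self) -> list[str]:
        return [f"L{j + 1:02d}" for j in range(self.n_loci)]


@dataclass
class StudyData:
    """One generated study: samples, sequences, metadata, and the truth table."""

    resident_pre: PopulationSample
    source: PopulationSample
    post: PopulationSample
    sequences: dict[str, str]
    haplotype_sequences: dict[str, str]
    truth: pd.DataFrame  # columns: id, true_class, maternal_lineage
    frequencies: tuple[dict, dict]  # (resident, source) locus -> allele -> freq

    @property
    def samples(self) -> dict[str, PopulationSample]:
        return {
            s.label: s for s in (self.resident_pre, self.source, self.post)
        }

    @property
    def metadata(self) -> pd.DataFrame:
        rows = []
        for sample in self.samples.values():
            for ind in sample.individuals:
                rows.append(
                    {
                        "id": ind.id,
                        "population": ind.population,
                        "sex": ind.sex,
                        "age": ind.age,
                        "mt_haplotype": ind.mt_haplotype,
                    }
                )
        return pd.DataFrame(rows)


def draw_parental_frequencies(
    spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> tuple[dict, dict]:
    """Draw per-locus allele frequencies for the two parental pools.

    F-model: an ancestral frequency vector p_l ~ Dirichlet(1,..,1) per locus,
    then each pool draws Dirichlet(p_l * (1-theta)/theta), which has mean p_l
    and F-statistic-like variance parameter theta.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    theta = spec.divergence
    conc = (1.0 - theta) / theta
    res: dict[str, dict[int, float]] = {}
    sup: dict[str, dict[int, float]] = {}
    for locus, k in zip(spec.loci, spec.alleles_per_locus):
        ancestral = rng.dirichlet(np.ones(k))
        # keep ancestral frequencies away from 0 so the Dirichlet parameters
        # stay positive and loci remain informative
        ancestral = (ancestral + 0.05) / (1.0 + 0.05 * k)
        alleles = list(range(1, k + 1))
        p_res = rng.dirichlet(ancestral * conc)
        p_sup = rng.dirichlet(ancestral * conc)
        res[locus] = dict(zip(alleles, p_res))
        sup[locus] = dict(zip(alleles, p_sup))
    return res, sup


def _freq_arrays(freqs: dict) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return {
        locus: (np.array(list(d.keys())), np.array(list(d.values())))
        for locus, d in freqs.items()
    }


def _gamete_pure(freq_arrays: dict, rng: np.random.Generator) -> dict[str, int]:
    return {
        locus: int(alleles[rng.choice(len(alleles), p=probs)])
        for locus, (alleles, probs) in freq_arrays.items()
    }


def _gamete_from_parent(parent: dict[str, tuple[int, int]], rng) -> dict[str, int]:
    return {locus: pair[rng.integers(2)] for locus, pair in parent.items()}


def _f1_genotype(fa_res, fa_sup, rng) -> dict[str, tuple[int, int]]:
    g_res = _gamete_pure(fa_res, rng)
    g_sup = _gamete_pure(fa_sup, rng)
    return {locus: (g_res[locus], g_sup[locus]) for locus in g_res}


def simulate_individual(
    cls: str,
    freqs_res: dict,
    freqs_sup: dict,
    dam_lineage: str,
    rng: np.random.Generator,
    id: str = "sim",
    population: str = "sim",
) -> Individual:
    """Simulate one multilocus genotype of a given category of descent.

    Pure individuals are two independent gametes from one pool per locus
    (Hardy-Weinberg within the pool); an F1 is one gamete from each pool; an
    F2 is two gametes from independently simulated F1 parents; a backcross is
    an F1 gamete plus a pure gamete. The mtDNA haplotype follows the dam.
    """
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    if dam_lineage not in ("resident", "supplemented"):
        raise ValueError(f"unknown dam lineage {dam_lineage!r}")
    fa_res = _freq_arrays(freqs_res)
    fa_sup = _freq_arrays(freqs_sup)

    if cls == "pure_res":
        g1, g2 = _gamete_pure(fa_res, rng), _gamete_pure(fa_res, rng)
    elif cls == "pure_sup":
        g1, g2 = _gamete_pure(fa_sup, rng), _gamete_pure(fa_sup, rng)
    elif cls == "F1":
        g1, g2 = _gamete_pure(fa_res, rng), _gamete_pure(fa_sup, rng)
    elif cls == "F2":
        g1 = _gamete_from_parent(_f1_genotype(fa_res, fa_sup, rng), rng)
        g2 = _gamete_from_parent(_f1_genotype(fa_res, fa_sup, rng), rng)
    elif cls == "BX_res":
        g1 = _gamete_from_parent(_f1_genotype(fa_res, fa_sup, rng), rng)
        g2 = _gamete_pure(fa_res, rng)
    else:  # BX_sup
        g1 = _gamete_from_parent(_f1_genotype(fa_res, fa_sup, rng), rng)
        g2 = _gamete_pure(fa_sup, rng)

    genotype = {locus: (g1[locus], g2[locus]) for locus in freqs_res}
    return Individual(id=id, population=population, genotype=genotype)


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    bases = "ACGT"
    out = list(seq)
    for pos in positions:
        current = out[pos]
        out[pos] = rng.choice([b for b in bases if b != current])
    return "".join(out)


def make_haplotype_sequences(
    spec: GeneratorSpec, rng: np.random.Generator
) -> dict[str, str]:
    """Shared haplotype backbone plus private haplotypes 9-31 steps away."""
    backbone = "".join(rng.choice(list("ACGT"), size=spec.seq_length))
    haps = {SHARED_HAPLOTYPE: backbone}
    for i in range(spec.mt_private_haplotypes):
        label = chr(ord("A") + i)
        n_sub = int(rng.integers(9, 32))
        positions = rng.choice(spec.seq_length, size=n_sub, replace=False)
        haps[label] = _mutate(backbone, positions, rng)
    return haps


def _inject_missing(ind: Individual, rate: float, rng: np.random.Generator) -> None:
    for locus in ind.genotype:
        if rng.random() < rate:
            ind.genotype[locus] = None


def _dam_lineage_for(cls: str, rng: np.random.Generator) -> str:
    # only ewes were supplemented, so F1 dams are supplemented; F2 dams are F1
    # ewes, whose own dams were supplemented; a resident-backcross dam may be
    # either the F1 ewe or a resident ewe
    if cls == "pure_res":
        return "resident"
    if cls in ("pure_sup", "F1", "F2", "BX_sup"):
        return "supplemented"
    return "supplemented" if rng.random() < 0.5 else "resident"


def build_study(spec: GeneratorSpec) -> StudyData:
    """Generate the full synthetic study with ground truth.

    The post sample holds the requested hybrid composition, pure residents for
    the remainder, and ``n_overage`` too-old decoys (pure residents aged past
    the cutoff, mimicking captures later redacted by age).
    """
    rng = np.random.default_rng(spec.seed)
    logger.info("build_study: seed=%s divergence=%s n_loci=%s",
                spec.seed, spec.divergence, spec.n_loci)
    freqs_res, freqs_sup = draw_parental_frequencies(spec, rng)
    hap_seqs = make_haplotype_sequences(spec, rng)
    private = [h for h in hap_seqs if h != SHARED_HAPLOTYPE]
    # source-pool haplotype frequencies: uneven, as in real matrilines
    source_hap_probs = rng.dirichlet(np.ones(len(private)))

    truth_rows = []
    sequences: dict[str, str] = {}

    def finish(ind: Individual, cls: str, lineage: str, age: int, sex: str) -> Individual:
        ind.sex = sex
        ind.age = age
        if lineage == "resident":
            hap = SHARED_HAPLOTYPE
        else:
            hap = private[rng.choice(len(private), p=source_hap_probs)]
        ind.mt_haplotype = hap
        sequences[ind.id] = hap_seqs[hap]
        _inject_missing(ind, spec.missing_rate, rng)
        truth_rows.append(
            {"id": ind.id, "true_class": cls, "maternal_lineage": lineage}
        )
        return ind

    def rand_sex() -> str:
        return "ewe" if rng.random() < 0.5 else "ram"

    res_inds = []
    for i in range(spec.sample_sizes["resident_pre"]):
        ind = simulate_individual(
            "pure_res", freqs_res, freqs_sup, "resident", rng,
            id=f"RES_{i + 1:03d}", population="RES",
        )
        res_inds.append(finish(ind, "pure_res", "resident",
                               int(rng.integers(1, 10)), rand_sex()))

    src_inds = []
    for i in range(spec.sample_sizes["source"]):
        ind = simulate_individual(
            "pure_sup", freqs_res, freqs_sup, "supplemented", rng,
            id=f"SRC_{i + 1:03d}", population="SRC",
        )
        src_inds.append(finish(ind, "pure_sup", "supplemented",
                               int(rng.integers(2, 9)), "ewe"))

    post_inds = []
    i = 0
    for cls in CLASSES:
        for _ in range(spec.hybrid_composition.get(cls, 0)):
            i += 1
            lineage = _dam_lineage_for(cls, rng)
            ind = simulate_individual(
                cls, freqs_res, freqs_sup, lineage, rng,
                id=f"POST_{i:03d}", population="POST",
            )
            post_inds.append(finish(ind, cls, lineage,
                                    int(rng.integers(0, spec.age_cutoff + 1)),
                                    rand_sex()))
    n_rest = spec.sample_sizes["post"] - len(post_inds)
    n_young = n_rest - min(spec.n_overage, n_rest)
    for j in range(n_rest):
        i += 1
        ind = simulate_individual(
            "pure_res", freqs_res, freqs_sup, "resident", rng,
            id=f"POST_{i:03d}", population="POST",
        )
        age = (
            int(rng.integers(0, spec.age_cutoff + 1))
            if j < n_young
            else int(rng.integers(spec.age_cutoff + 1, spec.age_cutoff + 5))
        )
        post_inds.append(finish(ind, "pure_res", "resident", age, rand_sex()))

    study = StudyData(
        resident_pre=PopulationSample("RES", res_inds, epoch="pre"),
        source=PopulationSample("SRC", src_inds, epoch="source"),
        post=PopulationSample("POST", post_inds, epoch="post"),
        sequences=sequences,
        haplotype_sequences=hap_seqs,
        truth=pd.DataFrame(truth_rows),
        frequencies=(freqs_res, freqs_sup),
    )
    return study


def write_study(study: StudyData, outdir) -> dict[str, str]:
    """Write a generated study to disk in the pipeline's input formats."""
    from pathlib import Path

    from . import formats_io as fio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": str(outdir / "genotypes.gen"),
        "sequences": str(outdir / "control_region.fasta"),
        "metadata": str(outdir / "metadata.csv"),
        "truth": str(outdir / "truth.csv"),
    }
    fio.write_genepop(paths["genotypes"], study.samples)
    fio.write_fasta_alignment(paths["sequences"], study.sequences)
    all_inds = [i for s in study.samples.values() for i in s.individuals]
    fio.write_metadata(paths["metadata"], all_inds)
    study.truth.to_csv(paths["truth"], index=False)
    return paths
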