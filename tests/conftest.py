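import numpy as np
import pytest

from rescue_eval import synthetic_data as sd
from rescue_eval.formats_io import Individual, PopulationSample


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across tests (seed fixed)."""
    return sd.build_study(sd.GeneratorSpec(seed=1))


@pytest.fixture(scope="session")
def truth_by_id(study):
    return dict(zip(study.truth.id, study.truth.true_class))


def make_fixed_parents(n_loci=8, n_per_pool=20):
    """Parental samples fixed for distinct alleles at every locus: allele 1 in
    the resident pool, allele 2 in the source pool (perfectly diagnostic)."""
    loci = [f"L{j + 1:02d}" for j in range(n_loci)]
    res = PopulationSample(
        "RES",
        [
            Individual(
                id=f"RES_{i}", population="RES",
                genotype={l: (1, 1) for l in loci},
            )
            for i in range(n_per_pool)
        ],
    )
    sup = PopulationSample(
        "SRC",
        [
            Individual(
                id=f"SRC_{i}", population="SRC",
                genotype={l: (2, 2) for l in loci},
            )
            for i in range(n_per_pool)
        ],
    )
    return res, sup, loci


@pytest.fixture
def fixed_parents():
    return make_fixed_parents()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
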