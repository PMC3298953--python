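import numpy as np
import pytest

from rescue_eval import hybrid_model as hm
from rescue_eval import synthetic_data as sd
from rescue_eval.formats_io import Individual


DIAG_RES = {"L1": {1: 1.0, 2: 0.0}}
DIAG_SUP = {"L1": {1: 0.0, 2: 1.0}}


class TestGenotypeLikelihood:
    @pytest.mark.parametrize(
        "category,expected",
        [
            ("F1", 1.0),
            ("F2", 0.5),
            ("BX_res", 0.5),
            ("BX_sup", 0.5),
            ("pure_res", 0.0),
            ("pure_sup", 0.0),
        ],
    )
    def test_diagnostic_heterozygote(self, category, expected):
        lik = hm.genotype_likelihood((1, 2), category, DIAG_RES["L1"], DIAG_SUP["L1"])
        assert lik == pytest.approx(expected)

    def test_missing_genotype_drops_locus(self):
        for c in hm.CLASSES:
            assert hm.genotype_likelihood(None, c, DIAG_RES["L1"], DIAG_SUP["L1"]) == 1.0

    def test_identical_pools_equalise_categories(self):
        freqs = {1: 0.3, 2: 0.5, 3: 0.2}
        liks = {
            c: hm.genotype_likelihood((1, 2), c, freqs, freqs) for c in hm.CLASSES
        }
        assert len({round(v, 12) for v in liks.values()}) == 1

    def test_homozygote_one_each_term(self):
        # P({x,x}|one-each) = p_res(x) p_sup(x)
        fr = {1: 0.4, 2: 0.6}
        fs = {1: 0.9, 2: 0.1}
        assert hm.genotype_likelihood((1, 1), "F1", fr, fs) == pytest.approx(0.36)

    def test_unknown_allele_rejected(self):
        with pytest.raises(ValueError, match="absent from both"):
            hm.genotype_likelihood((1, 9), "F1", DIAG_RES["L1"], DIAG_SUP["L1"])


class TestFixedFrequencyPosterior:
    def test_single_diagnostic_locus_closed_form(self):
        # likelihoods (0, 0, 1, .5, .5, .5) normalise to F1=0.4, others 0.2
        ind = Individual(id="x", population="P", genotype={"L1": (1, 2)})
        post = hm.posterior_fixed_frequencies(ind, DIAG_RES, DIAG_SUP)
        assert post.posterior["F1"] == pytest.approx(0.4)
        for c in ("F2", "BX_res", "BX_sup"):
            assert post.posterior[c] == pytest.approx(0.2)
        assert post.posterior["pure_res"] == pytest.approx(0.0)
        assert post.hybrid_mass == pytest.approx(1.0)
        assert post.hybrid_flag

    def test_matches_independent_brute_force(self, study, truth_by_id):
        """Package posterior vs an in-test normalisation of likelihood products."""
        fr, fs = study.frequencies
        for ind in study.post.individuals[:12]:
            expected = np.array(
                [
                    np.prod(
                        [
                            hm.genotype_likelihood(
                                ind.genotype[l], c, fr[l], fs[l]
                            )
                            for l in ind.genotype
                        ]
                    )
                    for c in hm.CLASSES
                ]
            )
            expected = expected / expected.sum()
            got = hm.posterior_fixed_frequencies(ind, fr, fs)
            for c, e in zip(hm.CLASSES, expected):
                assert got.posterior[c] == pytest.approx(e, abs=1e-9)


class TestGibbs:
    def test_fixed_frequency_gibbs_equals_direct_normalisation(self, study):
        """With frequencies pinned at truth and no mixing updates, the sampler's
        averaged posterior must equal the closed-form product posterior."""
        fr, fs = study.frequencies
        subset = study.post.individuals[:8]
        settings = hm.McmcSettings(burn_in=10, sweeps=50, n_chains=1, seeds=[3])
        posts, _ = hm.run_gibbs(
            subset, study.resident_pre, study.source, settings,
            fixed_frequencies=(fr, fs), update_mixing=False,
        )
        for ind, got in zip(subset, posts):
            want = hm.posterior_fixed_frequencies(ind, fr, fs)
            for c in hm.CLASSES:
                assert got.posterior[c] == pytest.approx(
                    want.posterior[c], abs=1e-6
                )

    def test_posteriors_are_probability_vectors(self, study):
        settings = hm.McmcSettings(burn_in=100, sweeps=400, n_chains=1, seeds=[3])
        posts, _ = hm.run_gibbs(
            study.post.individuals[:10], study.resident_pre, study.source, settings
        )
        for p in posts:
            vec = np.array([p.posterior[c] for c in hm.CLASSES])
            assert np.all(vec >= 0)
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_pure_residents_recovered(self, study, truth_by_id):
        pure = [
            i for i in study.post.individuals if truth_by_id[i.id] == "pure_res"
        ][:20]
        settings = hm.McmcSettings(burn_in=500, sweeps=3000, n_chains=1, seeds=[17])
        posts, _ = hm.run_gibbs(pure, study.resident_pre, study.source, settings)
        flags = [p.hybrid_flag for p in posts]
        assert sum(flags) <= 2
        assert np.median([p.posterior["pure_res"] for p in posts]) > 0.9

    def test_chains_agree_from_overdispersed_seeds(self, study):
        settings = hm.McmcSettings(
            burn_in=800, sweeps=5000, n_chains=2, seeds=[1, 999983]
        )
        _, diags = hm.run_gibbs(
            study.post.individuals[:12], study.resident_pre, study.source, settings
        )
        assert diags["max_chain_discrepancy"] <= 0.05

    def test_label_symmetry_under_parent_swap(self, study):
        subset = study.post.individuals[:6]
        settings = hm.McmcSettings(burn_in=4000, sweeps=40000, n_chains=2, seeds=[5, 907])
        fwd, _ = hm.run_gibbs(subset, study.resident_pre, study.source, settings)
        rev, _ = hm.run_gibbs(subset, study.source, study.resident_pre, settings)
        swap = {
            "pure_res": "pure_sup", "pure_sup": "pure_res",
            "BX_res": "BX_sup", "BX_sup": "BX_res",
            "F1": "F1", "F2": "F2",
        }
        for pf, pr in zip(fwd, rev):
            for c in hm.CLASSES:
                assert pf.posterior[c] == pytest.approx(
                    pr.posterior[swap[c]], abs=0.02
                )

    def test_no_polymorphic_loci_rejected(self, fixed_parents):
        res, sup, loci = fixed_parents
        # make both pools fixed for the SAME allele -> monomorphic universe
        for ind in sup.individuals:
            for l in loci:
                ind.genotype[l] = (1, 1)
        probe = [Individual(id="x", population="P", genotype={l: (1, 1) for l in loci})]
        with pytest.raises(ValueError, match="polymorphic"):
            hm.run_gibbs(probe, res, sup, hm.McmcSettings(burn_in=5, sweeps=5, n_chains=1, seeds=[1]))


class TestMtdnaOverride:
    def _mk(self, n, overage_ids, puresup_ids, nuclear_hybrid_ids, override_ids):
        individuals, posteriors = [], []
        for i in range(n):
            iid = f"I{i:03d}"
            age = 8 if iid in overage_ids else 3
            if iid in puresup_ids or iid in override_ids:
                hap = "A"  # source-private
            else:
                hap = "E"
            individuals.append(
                Individual(id=iid, population="P", age=age, mt_haplotype=hap)
            )
            if iid in puresup_ids:
                vec = {c: 0.0 for c in hm.CLASSES}
                vec["pure_sup"] = 1.0
            elif iid in nuclear_hybrid_ids:
                vec = {c: 0.0 for c in hm.CLASSES}
                vec["F2"] = 1.0
            else:
                vec = {c: 0.0 for c in hm.CLASSES}
                vec["pure_res"] = 1.0
            posteriors.append(
                hm.HybridPosterior(
                    id=iid, posterior=vec,
                    hybrid_flag=iid in nuclear_hybrid_ids,
                )
            )
        return individuals, posteriors

    def test_census_with_one_exclusion_each_kind(self):
        # 48 sampled: 1 over-age, 3 pure-supplemented, 9 hybrids -> 9/44
        ids = [f"I{i:03d}" for i in range(48)]
        inds, posts = self._mk(
            48,
            overage_ids={ids[0]},
            puresup_ids=set(ids[1:4]),
            nuclear_hybrid_ids=set(ids[4:11]),
            override_ids=set(ids[11:13]),
        )
        _, census = hm.apply_mtdna_override(posts, inds, {"A"}, age_cutoff=6)
        assert census["n_hybrids"] == 9
        assert census["denominator"] == 44
        assert round(100 * census["proportion"], 1) == 20.5

    def test_census_second_composition(self):
        # 50 sampled: 2 over-age, 1 pure-supplemented, 11 hybrids -> 11/47
        ids = [f"I{i:03d}" for i in range(50)]
        inds, posts = self._mk(
            50,
            overage_ids=set(ids[:2]),
            puresup_ids={ids[2]},
            nuclear_hybrid_ids=set(ids[3:12]),
            override_ids=set(ids[12:14]),
        )
        _, census = hm.apply_mtdna_override(posts, inds, {"A"}, age_cutoff=6)
        assert census["n_hybrids"] == 11
        assert census["denominator"] == 47
        assert round(100 * census["proportion"], 1) == 23.4

    def test_no_hybrids_no_private(self):
        inds, posts = self._mk(10, set(), set(), set(), set())
        _, census = hm.apply_mtdna_override(posts, inds, {"A"})
        assert census["n_hybrids"] == 0
        assert census["proportion"] == 0.0

    def test_missing_haplotype_no_override(self):
        ind = Individual(id="x", population="P", age=2, mt_haplotype=None)
        post = hm.HybridPosterior(
            id="x",
            posterior={**{c: 0.0 for c in hm.CLASSES}, "pure_res": 1.0},
            hybrid_flag=False,
        )
        updated, census = hm.apply_mtdna_override([post], [ind], {"A"})
        assert census["n_hybrids"] == 0
        assert updated[0].basis == "nuclear"

    def test_override_promotes_and_marks_basis(self):
        ind = Individual(id="x", population="P", age=2, mt_haplotype="A")
        post = hm.HybridPosterior(
            id="x",
            posterior={**{c: 0.0 for c in hm.CLASSES}, "pure_res": 1.0},
            hybrid_flag=False,
        )
        updated, census = hm.apply_mtdna_override([post], [ind], {"A"})
        assert updated[0].hybrid_flag
        assert updated[0].basis == "mtDNA_override"
        assert census["n_hybrids"] == 1


class TestPower:
    def test_perfectly_diagnostic_loci_have_zero_f1_error(self, fixed_parents):
        res, sup, _ = fixed_parents
        settings = hm.McmcSettings(burn_in=100, sweeps=500, n_chains=1, seeds=[2])
        table = hm.power_simulation(res, sup, n_per_class=10, settings=settings, seed=1)
        f1 = table[table.true_class == "F1"].iloc[0]
        assert f1["hybrid_error"] == 0.0
        assert f1["class_error"] == 0.0

    def test_invalid_n_rejected(self, fixed_parents):
        res, sup, _ = fixed_parents
        with pytest.raises(ValueError, match="n_per_class"):
            hm.power_simulation(res, sup, n_per_class=0)
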