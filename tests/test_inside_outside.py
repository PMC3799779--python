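import numpy as np
import pytest
from scipy.stats import chisquare

from _oracles import enumerate_pedigree, pairwise_joint
from conftest import make_observed, random_observation
from prioriseq.family_sim import random_pedigree
from prioriseq.inside_outside import (
    MendelianError,
    inside_pass,
    outside_pass,
    sample_genotypes,
    transmission,
)
from prioriseq.pedigree import ObservedGenotypes


class TestTransmission:
    def test_homozygous_parents_fix_the_child(self):
        _, M = transmission(0.3)
        assert M[2, 2, 2] == 1.0
        assert M[0, 0, 0] == 1.0
        assert M[0, 0, 1] == 0.0  # Mendelian zero

    def test_het_by_het_punnett_square(self):
        _, M = transmission(0.3)
        assert np.allclose(M[1, 1], [0.25, 0.5, 0.25])

    def test_founder_prior_is_hwe(self):
        prior, _ = transmission(0.5)
        assert np.allclose(prior, [0.25, 0.5, 0.25])

    def test_rows_normalize(self):
        _, M = transmission(0.17)
        assert np.allclose(M.sum(axis=2), 1.0)

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError):
            transmission(0.0)


class TestInsidePass:
    def test_fully_observed_trio_closed_form(self, trio):
        obs = make_observed(trio, ["L1"], {"dad": [1], "mum": [0], "kid": [1]})
        f = 0.3
        it = inside_pass(trio, obs, f)
        prior, M = transmission(f)
        assert np.exp(it.loglik) == pytest.approx(
            prior[1] * prior[0] * M[0, 1, 1], abs=1e-14
        )

    def test_no_observations_give_unit_likelihood(self, trio):
        obs = ObservedGenotypes(locus_ids=["L1"], dosages={})
        it = inside_pass(trio, obs, 0.3)
        assert it.loglik == pytest.approx(0.0, abs=1e-12)

    def test_mendelian_impossible_data_names_the_locus(self, trio):
        obs = make_observed(
            trio, ["L1", "L2"],
            {"dad": [0, 0], "mum": [0, 0], "kid": [0, 2]},
        )
        with pytest.raises(MendelianError, match="L2"):
            inside_pass(trio, obs, 0.3)

    def test_partial_observation_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for seed in range(30):
            n = int(rng.integers(3, 7))
            ped = random_pedigree(n, seed=seed)
            f = float(rng.choice([0.05, 0.3, 0.5]))
            empty = ObservedGenotypes(locus_ids=["L1"], dosages={})
            truth = sample_genotypes(ped, empty, f, 1, seed=seed).dosages[0, :, 0]
            obs = random_observation(ped, truth, rng.random(n) < 0.5)
            it = inside_pass(ped, obs, f)
            lik, _, _, _ = enumerate_pedigree(ped, obs.matrix(ped), f)
            assert np.exp(it.loglik) == pytest.approx(lik, abs=1e-12)


class TestOutsidePass:
    def test_ungenotyped_singleton_founders_get_hwe_prior(self, trio):
        obs = ObservedGenotypes(locus_ids=["L1"], dosages={})
        post = outside_pass(inside_pass(trio, obs, 0.3))
        prior, _ = transmission(0.3)
        for iid in ("dad", "mum"):
            assert np.allclose(post.marginal[trio.index(iid), 0], prior)

    def test_child_of_observed_parents_is_punnett(self, trio):
        obs = make_observed(trio, ["L1"], {"dad": [1], "mum": [0]})
        post = outside_pass(inside_pass(trio, obs, 0.3))
        assert np.allclose(
            post.marginal[trio.index("kid"), 0], [0.5, 0.5, 0.0]
        )

    def test_genotyped_individuals_are_point_masses(self, trio):
        obs = make_observed(trio, ["L1"], {"kid": [2]})
        post = outside_pass(inside_pass(trio, obs, 0.25))
        assert np.allclose(post.marginal[trio.index("kid"), 0], [0, 0, 1])

    def test_marginals_match_enumeration(self):
        rng = np.random.default_rng(7)
        for seed in range(30):
            n = int(rng.integers(3, 7))
            ped = random_pedigree(n, seed=100 + seed)
            f = float(rng.choice([0.05, 0.3, 0.5]))
            empty = ObservedGenotypes(locus_ids=["L1"], dosages={})
            truth = sample_genotypes(ped, empty, f, 1, seed=seed).dosages[0, :, 0]
            obs = random_observation(ped, truth, rng.random(n) < 0.5)
            post = outside_pass(inside_pass(ped, obs, f))
            _, marg, _, _ = enumerate_pedigree(ped, obs.matrix(ped), f)
            assert np.max(np.abs(post.marginal[:, 0, :] - marg)) < 1e-12

    def test_marginals_invariant_to_member_input_order(self):
        ped = random_pedigree(8, seed=3)
        empty = ObservedGenotypes(locus_ids=["L1"], dosages={})
        truth = sample_genotypes(ped, empty, 0.3, 1, seed=8).dosages[0, :, 0]
        rng = np.random.default_rng(0)
        obs = random_observation(ped, truth, rng.random(8) < 0.5)
        post1 = outside_pass(inside_pass(ped, obs, 0.3))
        perm = rng.permutation(8)
        from prioriseq.pedigree import Pedigree

        ped2 = Pedigree(
            members=[ped.members[k] for k in perm], family_id=ped.family_id
        )
        post2 = outside_pass(inside_pass(ped2, obs, 0.3))
        assert post1.loglik == pytest.approx(post2.loglik, abs=1e-10)
        for iid in ped.ids:
            a = post1.marginal[ped.index(iid), 0]
            b = post2.marginal[ped2.index(iid), 0]
            assert np.allclose(a, b, atol=1e-10)


class TestSampling:
    def test_fully_observed_pedigree_reproduced_exactly(self, trio):
        obs = make_observed(trio, ["L1"], {"dad": [1], "mum": [0], "kid": [1]})
        samp = sample_genotypes(trio, obs, 0.3, 200, seed=0)
        assert np.all(samp.dosages[:, trio.index("dad"), 0] == 1)
        assert np.all(samp.dosages[:, trio.index("mum"), 0] == 0)
        assert np.all(samp.dosages[:, trio.index("kid"), 0] == 1)

    def test_mendelian_zero_enforced(self, trio):
        obs = make_observed(trio, ["L1"], {"dad": [0], "mum": [0]})
        samp = sample_genotypes(trio, obs, 0.4, 500, seed=1)
        assert np.all(samp.dosages[:, trio.index("kid"), 0] == 0)

    def test_reproducible_for_fixed_seed(self, trio):
        obs = make_observed(trio, ["L1"], {"dad": [1]})
        a = sample_genotypes(trio, obs, 0.3, 50, seed=9).dosages
        b = sample_genotypes(trio, obs, 0.3, 50, seed=9).dosages
        assert np.array_equal(a, b)

    def test_empirical_frequencies_match_marginals(self):
        ped = random_pedigree(6, seed=11)
        empty = ObservedGenotypes(locus_ids=["L1"], dosages={})
        truth = sample_genotypes(ped, empty, 0.3, 1, seed=2).dosages[0, :, 0]
        rng = np.random.default_rng(5)
        obs = random_observation(ped, truth, rng.random(6) < 0.4)
        post = outside_pass(inside_pass(ped, obs, 0.3))
        R = 50_000
        samp = sample_genotypes(ped, obs, 0.3, R, seed=13).dosages[:, :, 0]
        for i in range(ped.n):
            exp = post.marginal[i, 0] * R
            got = np.array([(samp[:, i] == g).sum() for g in range(3)])
            keep = exp > 0
            assert got[~keep].sum() == 0
            if keep.sum() > 1:
                p = chisquare(got[keep], exp[keep]).pvalue
                assert p > 0.001

    def test_pairwise_joint_matches_enumeration(self):
        ped = random_pedigree(5, seed=21)
        empty = ObservedGenotypes(locus_ids=["L1"], dosages={})
        truth = sample_genotypes(ped, empty, 0.3, 1, seed=4).dosages[0, :, 0]
        obs = random_observation(ped, truth, np.array([True] + [False] * 4))
        tree = ped.validate()
        u = tree.units[tree.order[0]]
        parent, child = u.father, u.children[0]
        joint = pairwise_joint(ped, obs.matrix(ped), 0.3, parent, child)
        R = 50_000
        samp = sample_genotypes(ped, obs, 0.3, R, seed=17).dosages
        ia, ib = ped.index(parent), ped.index(child)
        counts = np.zeros((3, 3))
        for ga in range(3):
            for gb in range(3):
                counts[ga, gb] = np.sum(
                    (samp[:, ia, 0] == ga) & (samp[:, ib, 0] == gb)
                )
        exp = joint.ravel() * R
        got = counts.ravel()
        keep = exp > 0
        assert got[~keep].sum() == 0
        p = chisquare(got[keep], exp[keep]).pvalue
        assert p > 0.001

    def test_unconditioned_sampling_recovers_population_frequency(self):
        ped = random_pedigree(12, seed=31)
        obs = ObservedGenotypes(locus_ids=["L1"], dosages={})
        f = 0.3
        R = 20_000
        samp = sample_genotypes(ped, obs, f, R, seed=23).dosages[:, :, 0]
        # every member individually follows HWE at f (exchangeable founders
        # plus Mendelian transmission keeps allele frequency constant)
        for i in range(ped.n):
            emp = samp[:, i].mean() / 2.0
            se = np.sqrt(f * (1 - f) / (2 * R))
            assert abs(emp - f) < 4 * se

    def test_invalid_replicate_count_rejected(self, trio):
        obs = ObservedGenotypes(locus_ids=["L1"], dosages={})
        with pytest.raises(ValueError):
            sample_genotypes(trio, obs, 0.3, 0, seed=0)
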