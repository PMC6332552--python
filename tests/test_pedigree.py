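"""Gene-dropping cohorts and exact IBD sharing."""

import numpy as np
import pytest

from ldsim.fixtures import make_trio_pedigree
from ldsim.haplotype import HaplotypePool
from ldsim.meiosis import RecombinationParams, mate
from ldsim.pedigree import (
    compute_pair_ibd12,
    founder_from_pool,
    generate_unrelated,
    ibd_matrix,
    ibd_pair_table,
    simulate_pedigree,
)
from ldsim.vcf_io import read_pedigree


@pytest.fixture()
def pool(rare_fixture, rng):
    _, _, model, _ = rare_fixture
    return HaplotypePool(model, rng)


@pytest.fixture()
def cms(rare_fixture):
    _, _, _, cms = rare_fixture
    # stretch to a 10 cM region so recombination is exercised
    return cms * 10.0


def _region(cms):
    return float(cms[0]), float(cms[-1]) + 1e-9


class TestGenerateUnrelated:
    def test_empty_cohort(self, pool, cms):
        cohort = generate_unrelated(pool, 0, cms)
        assert len(cohort) == 0

    def test_pool_batch_consumption(self, rare_fixture, cms):
        _, _, model, _ = rare_fixture
        pool = HaplotypePool(model, np.random.default_rng(0), batch_size=1000)
        generate_unrelated(pool, 600, cms)
        # 1200 haplotypes -> second batch of 1000 triggered
        assert pool.batches_generated == 2

    def test_cohort_maf_matches_model(self, rare_fixture, cms):
        _, _, model, _ = rare_fixture
        pool = HaplotypePool(model, np.random.default_rng(1))
        cohort = generate_unrelated(pool, 5000, cms)
        p_sim = cohort.haplotype_matrix().alleles.mean(axis=0)
        se = np.sqrt(model.p * (1 - model.p) / 10000)
        assert np.all(np.abs(p_sim - model.p) < 3.5 * se)

    def test_founders_have_unique_origins(self, pool, cms):
        cohort = generate_unrelated(pool, 50, cms)
        origins = [int(ind.track1.sources[0]) for ind in cohort.individuals]
        origins += [int(ind.track2.sources[0]) for ind in cohort.individuals]
        assert len(set(origins)) == 100


class TestSimulatePedigree:
    def test_trio_mendelian_at_all_sites(self, pool, cms, rng):
        ped = read_pedigree(make_trio_pedigree())
        cohort = simulate_pedigree(ped, pool, RecombinationParams(), rng, cms)
        by_id = {ind.id: ind for ind in cohort.individuals}
        kid, dad, mom = by_id["kid"], by_id["dad"], by_id["mom"]
        # paternal gamete allele must be one of dad's two alleles, per site
        ok_p = (kid.gamete1 == dad.gamete1) | (kid.gamete1 == dad.gamete2)
        ok_m = (kid.gamete2 == mom.gamete1) | (kid.gamete2 == mom.gamete2)
        assert ok_p.all() and ok_m.all()

    def test_founder_only_pedigree_matches_unrelated(self, pool, cms, rng):
        import pandas as pd

        df = pd.DataFrame(
            [["f", "a", "0", "0", 1], ["f", "b", "0", "0", 2]],
            columns=["fam", "id", "father", "mother", "sex"],
        )
        cohort = simulate_pedigree(read_pedigree(df), pool, RecombinationParams(),
                                   rng, cms)
        assert len(cohort) == 2
        assert cohort.founder_count == 2
        r = compute_pair_ibd12(*cohort.individuals)
        assert r.ibd0 == 1.0

    def test_three_generation_family_size(self, rare_fixture, rng):
        from ldsim.frailty import simulate_three_generation_family
        from ldsim.haplotype import HaplotypePool

        _, _, model, cms = rare_fixture
        pool = HaplotypePool(model, rng)
        for _ in range(20):
            members, gens, sexes = simulate_three_generation_family(
                pool, RecombinationParams(), rng, cms, _region(cms)
            )
            assert 4 <= len(members) <= 8
            assert set(gens) == {1, 2, 3}


class TestIBD:
    def test_parent_offspring_is_exactly_ibd1(self, pool, cms, rng):
        region = _region(cms)
        for _ in range(10):
            f = founder_from_pool(pool, region)
            m = founder_from_pool(pool, region)
            child = mate(f, m, rng, RecombinationParams(), cms, region)
            r = compute_pair_ibd12(f, child)
            assert r.ibd1 == 1.0 and r.ibd2 == 0.0 and r.ibd0 == 0.0
            assert r.mean_ibd == pytest.approx(0.5)

    def test_unrelated_founders_share_nothing(self, pool, cms):
        region = _region(cms)
        a = founder_from_pool(pool, region)
        b = founder_from_pool(pool, region)
        assert compute_pair_ibd12(a, b).ibd0 == 1.0

    def test_self_duplicate_is_ibd2(self, pool, cms):
        a = founder_from_pool(pool, _region(cms))
        r = compute_pair_ibd12(a, a)
        assert r.ibd2 == 1.0

    def test_proportions_sum_to_one(self, pool, cms, rng):
        region = _region(cms)
        f, m = (founder_from_pool(pool, region) for _ in range(2))
        inds = [f, m]
        for _ in range(6):
            inds.append(mate(f, m, rng, RecombinationParams(), cms, region))
        for i in range(len(inds)):
            for j in range(i + 1, len(inds)):
                r = compute_pair_ibd12(inds[i], inds[j])
                assert r.ibd0 + r.ibd1 + r.ibd2 == pytest.approx(1.0, abs=1e-12)

    def test_sibling_expectations(self, pool, cms, rng):
        """Mean sib sharing: IBD1 -> 1/2, IBD2 -> 1/4, pi-hat -> 1/2."""
        region = _region(cms)
        params = RecombinationParams()
        vals = []
        for _ in range(400):
            f = founder_from_pool(pool, region)
            m = founder_from_pool(pool, region)
            s1 = mate(f, m, rng, params, cms, region)
            s2 = mate(f, m, rng, params, cms, region)
            r = compute_pair_ibd12(s1, s2)
            vals.append([r.ibd1, r.ibd2, r.mean_ibd])
        vals = np.asarray(vals)
        mean, se = vals.mean(0), vals.std(0) / np.sqrt(len(vals))
        for got, s, expect in zip(mean, se, [0.5, 0.25, 0.5]):
            assert abs(got - expect) < 4 * max(s, 1e-3)

    def test_grandparent_mean_ibd(self, pool, cms, rng):
        """E[pi-hat] = 0.25 for grandparent-grandchild."""
        region = _region(cms)
        params = RecombinationParams()
        vals = []
        for _ in range(300):
            gf = founder_from_pool(pool, region)
            gm = founder_from_pool(pool, region)
            child = mate(gf, gm, rng, params, cms, region)
            spouse = founder_from_pool(pool, region)
            gc = mate(child, spouse, rng, params, cms, region)
            vals.append(compute_pair_ibd12(gf, gc).mean_ibd)
        vals = np.asarray(vals)
        assert abs(vals.mean() - 0.25) < 4 * vals.std() / np.sqrt(len(vals))

    def test_region_mismatch_rejected(self, pool, cms):
        a = founder_from_pool(pool, (0.0, 5.0))
        b = founder_from_pool(pool, (0.0, 9.0))
        with pytest.raises(ValueError, match="region"):
            compute_pair_ibd12(a, b)

    def test_ibd_matrix_and_table(self, pool, cms, rng):
        region = _region(cms)
        f = founder_from_pool(pool, region, id="f")
        m = founder_from_pool(pool, region, id="m")
        kid = mate(f, m, rng, RecombinationParams(), cms, region, child_id="k")
        from ldsim.pedigree import Cohort

        cohort = Cohort([f, m, kid], None, cms, region)
        B = ibd_matrix(cohort)
        assert B.shape == (3, 3)
        np.testing.assert_allclose(np.diag(B), 1.0)
        assert B[0, 2] == pytest.approx(0.5)  # parent-offspring pi-hat
        table = ibd_pair_table(cohort)
        assert len(table) == 3
        row = table[(table.id1 == "f") & (table.id2 == "k")].iloc[0]
        assert row.ibd1 == 1.0
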