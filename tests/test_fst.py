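"""Weir-Cockerham theta, ENA correction, Nei distance, PCoA and AMOVA."""

import math

import numpy as np
import pandas as pd
import pytest

from escapetrace.dataset import GenotypeDataset, Locus, allele_frequencies
from escapetrace.fst import (amova, fst_ena, nei_distance, nei_distance_matrix,
                             pairwise_fst, pcoa, weir_cockerham_fst)
from escapetrace.simulate import (PopulationSpec, ScenarioSpec,
                                  balding_nichols_dataset, generate_scenario,
                                  null_biased_dataset)
from conftest import make_dataset


class TestWeirCockerham:
    def test_fixed_difference_is_one(self, biallelic_two_pops):
        res = weir_cockerham_fst(biallelic_two_pops, permutations=0)
        assert res.theta == pytest.approx(1.0)

    def test_panmictic_near_zero_with_uniform_p(self):
        ds = balding_nichols_dataset(2, 60, 1e-9, seed=0)
        res = weir_cockerham_fst(ds, permutations=100, seed=1)
        assert abs(res.theta) < 0.01
        assert res.p_value > 0.05

    def test_balding_nichols_recovery(self):
        thetas = [weir_cockerham_fst(balding_nichols_dataset(8, 40, 0.02, seed=s),
                                     permutations=0).theta for s in range(20)]
        assert abs(np.mean(thetas) - 0.02) < 0.005

    def test_invariant_to_population_order_and_relabelling(self):
        ds = balding_nichols_dataset(4, 30, 0.03, seed=6)
        base = weir_cockerham_fst(ds, permutations=0).theta
        shuffled = ds.subset_populations(["pop3", "pop1", "pop4", "pop2"])
        assert weir_cockerham_fst(shuffled, permutations=0).theta == pytest.approx(base)
        # relabel alleles at every locus
        rng = np.random.default_rng(0)
        g = ds.genotypes.copy()
        loci2 = []
        for li, locus in enumerate(ds.loci):
            perm = rng.permutation(locus.n_alleles)
            col = g[:, li, :]
            ok = col != -1
            col[ok] = perm[col[ok]]
            loci2.append(Locus(locus.name, locus.alleles))
        g = np.sort(g, axis=2)
        ds2 = GenotypeDataset(loci2, ds.pop_names, ds.pop_index, g)
        assert weir_cockerham_fst(ds2, permutations=0).theta == pytest.approx(base)

    def test_pairwise_pair_count_and_symmetry(self):
        ds = balding_nichols_dataset(6, 20, 0.03, seed=1)
        mat = pairwise_fst(ds)
        assert mat.attrs["n_pairs"] == 15
        np.testing.assert_allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 0.0)


class TestEna:
    def test_zero_nulls_reduces_to_plain_theta(self):
        from escapetrace.nullalleles import NullAlleleEstimate

        ds = balding_nichols_dataset(4, 30, 0.02, seed=3)
        plain = weir_cockerham_fst(ds, permutations=0).theta
        freqs = allele_frequencies(ds)
        zero_estimates = {
            (pop, locus.name): NullAlleleEstimate(
                0.0, freqs.vector(pop, locus.name).copy(), 1, True, 0.0)
            for pop in ds.pop_names for locus in ds.loci
        }
        ena = fst_ena(ds, null_estimates=zero_estimates, bootstrap_reps=0).theta
        assert ena == pytest.approx(plain, abs=1e-12)

    def test_bias_reduction_with_drifting_nulls(self):
        wins = 0
        n_rep = 20
        for s in range(n_rep):
            ds, truth = null_biased_dataset(n_pops=10, n_per=50, seed=s)
            raw = weir_cockerham_fst(ds, permutations=0).theta
            ena = fst_ena(ds, bootstrap_reps=0).theta
            wins += abs(ena - truth) < abs(raw - truth)
        assert wins >= 0.7 * n_rep

    def test_bootstrap_ci_contains_point(self):
        ds = balding_nichols_dataset(5, 30, 0.03, seed=2)
        res = fst_ena(ds, bootstrap_reps=2000, seed=0)
        lo, hi = res.ci95
        assert lo <= res.theta <= hi


class TestNeiDistance:
    def test_identical_populations_zero(self):
        rows = [[(0, 1)], [(0, 0)], [(1, 1)]] * 2
        ds = make_dataset(rows, [2], [3, 3])
        freqs = allele_frequencies(ds)
        assert nei_distance(freqs, 0, 1) == pytest.approx(0.0)

    def test_disjoint_alleles_infinite_with_flag(self, biallelic_two_pops):
        freqs = allele_frequencies(biallelic_two_pops)
        assert math.isinf(nei_distance(freqs, 0, 1))
        mat = nei_distance_matrix(freqs)
        assert mat.attrs["infinite"][0, 1]

    def test_two_locus_hand_computation(self):
        # pop1: locus1 p=(1,0), locus2 p=(0.5,0.5); pop2: locus1 (0.5,0.5),
        # locus2 (0.5,0.5)
        rows1 = [[(0, 0), (0, 1)], [(0, 0), (0, 1)]]
        rows2 = [[(0, 1), (0, 1)], [(0, 1), (0, 1)]]
        ds = make_dataset(rows1 + rows2, [2, 2], [2, 2])
        freqs = allele_frequencies(ds)
        jx = (1.0 + 0.5) / 2
        jy = (0.5 + 0.5) / 2
        jxy = (0.5 + 0.5) / 2
        expected = -math.log(jxy / math.sqrt(jx * jy))
        assert nei_distance(freqs, 0, 1) == pytest.approx(expected)


class TestPcoa:
    def test_points_on_line_ordered_one_axis(self):
        x = np.array([0.0, 1.0, 2.0, 3.5])
        D = np.abs(x[:, None] - x[None, :])
        res = pcoa(D)
        coords = res["coordinates"].to_numpy()
        order = np.argsort(coords[:, 0])
        assert list(order) == [0, 1, 2, 3] or list(order) == [3, 2, 1, 0]

    def test_equidistant_triplet_equal_eigenvalues(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = pcoa(D)
        pos = res["eigenvalues"][res["eigenvalues"] > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_recovers_planted_coordinates_up_to_rotation(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 2))
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        got = pcoa(D)["coordinates"].to_numpy()[:, :2]
        # Procrustes: optimal rotation of recovered onto planted
        a = pts - pts.mean(axis=0)
        b = got - got.mean(axis=0)
        u, _, vt = np.linalg.svd(b.T @ a)
        rotated = b @ (u @ vt)
        assert np.max(np.abs(rotated - a)) < 1e-6

    def test_matches_scikit_bio_ordination(self):
        """Independent cross-check: coordinates agree with scikit-bio's
        principal-coordinates implementation up to axis sign."""
        import skbio

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(7, 3))
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        mine = pcoa(D)["coordinates"].to_numpy()
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D)).samples.to_numpy()
        for axis in range(3):
            assert (np.allclose(mine[:, axis], ref[:, axis], atol=1e-8)
                    or np.allclose(mine[:, axis], -ref[:, axis], atol=1e-8))

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_rejects_infinite_distances(self):
        D = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            pcoa(D)


class TestAmova:
    def test_percentages_sum_to_100(self):
        ds = balding_nichols_dataset(6, 25, 0.03, seed=0)
        grouping = {f"pop{i+1}": ("A" if i < 3 else "B") for i in range(6)}
        res = amova(ds, grouping, permutations=0)
        assert res.percentages.sum() == pytest.approx(100.0, abs=0.01)

    def test_single_pool_has_no_group_variance(self):
        ds = balding_nichols_dataset(6, 30, 1e-9, seed=1)
        grouping = {f"pop{i+1}": ("A" if i < 3 else "B") for i in range(6)}
        res = amova(ds, grouping, permutations=0)
        assert res.percentages["within_pops"] > 99.0
        assert abs(res.components["among_groups"]) / res.components.sum() < 0.005

    def test_two_level_hierarchy_recovery(self):
        """Group and population components recover the generator's two-level
        design (group FST 0.02, population-within FST 0.008) within Monte
        Carlo error over replicates."""
        among_g, among_p = [], []
        for s in range(10):
            pops = [PopulationSpec(f"g{g}p{p}", 40, "wild", f"cl{g}")
                    for g in range(4) for p in range(3)]
            spec = ScenarioSpec(pops, {f"cl{g}": 0.02 for g in range(4)},
                                pop_fst=0.008, missing_rate=0.0, seed=s)
            ds, _ = generate_scenario(spec)
            grouping = {p.name: p.cluster for p in pops}
            res = amova(ds, grouping, permutations=0)
            total = res.components.sum()
            among_g.append(res.components["among_groups"] / total)
            among_p.append(res.components["among_pops_within_groups"] / total)
        assert np.mean(among_g) == pytest.approx(0.02, abs=0.008)
        assert np.mean(among_p) == pytest.approx(0.008, abs=0.005)

    def test_permutation_detects_real_groups(self):
        pops = [PopulationSpec(f"g{g}p{p}", 30, "wild", f"cl{g}")
                for g in range(2) for p in range(4)]
        spec = ScenarioSpec(pops, {"cl0": 0.06, "cl1": 0.06}, pop_fst=0.005,
                            missing_rate=0.0, seed=3)
        ds, _ = generate_scenario(spec)
        res = amova(ds, {p.name: p.cluster for p in pops}, permutations=200,
                    seed=0)
        assert res.p_values["among_groups"] < 0.05
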