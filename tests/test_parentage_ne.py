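"""Parentage LOD assignment and LD effective population size."""

import math

import numpy as np
import pytest

from escapetrace.dataset import allele_frequencies
from escapetrace.ne import harmonic_mean_ne, ne_ld
from escapetrace.parentage import (ParentageSettings, critical_lod,
                                   find_parent_offspring, parentage_lod)
from escapetrace.simulate import (PopulationSpec, ScenarioSpec,
                                  balding_nichols_dataset, generate_scenario,
                                  wright_fisher_sample)
from conftest import make_dataset


def lod_bruteforce(offspring, parent, p, e):
    """Independent oracle: enumerate transmission events at one biallelic
    locus and form the CERVUS-style likelihood ratio directly."""
    a, b = offspring

    def hw(g):
        x, y = g
        return p[x] * p[y] * (2 if x != y else 1)

    # transmission probability: each parental allele passed with prob 1/2,
    # the other offspring allele drawn from the population frequencies
    trans = 0.0
    for passed in parent:
        for other_idx in range(len(p)):
            prob = 0.5 * p[other_idx]
            g = tuple(sorted((passed, other_idx)))
            if g == tuple(sorted((a, b))):
                trans += prob
    keep = 1 - e
    l1 = keep * keep * trans + (1 - keep * keep) * hw((a, b))
    return math.log(l1 / hw((a, b)))


def freq_table(n_alleles_per_locus, rows):
    ds = make_dataset(rows, n_alleles_per_locus, [len(rows)])
    return ds, allele_frequencies(ds)


class TestParentageLod:
    def test_mendelian_exclusion_is_large_negative(self):
        rows = [[(0, 0)] * 12] * 5 + [[(1, 2)] * 12] * 5 + [[(0, 1)] * 12] * 10
        ds, freqs = freq_table([3] * 12, rows)
        parent = np.array([[0, 0]] * 12)
        child = np.array([[1, 2]] * 12)
        res = parentage_lod(child, parent, freqs, error_rate=0.01)
        assert res["lod"] < -20
        assert res["mismatches"] == 12

    def test_rare_allele_match_is_positive(self):
        # parent homozygous for a rare allele, offspring carries it
        rows = [[(0, 0)]] * 18 + [[(1, 1)]] * 2
        ds, freqs = freq_table([2], rows)
        parent = np.array([[1, 1]])
        child = np.array([[0, 1]])
        res = parentage_lod(child, parent, freqs, error_rate=0.01, min_shared=1)
        assert res["lod"] > 0

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(2)
        rows = [[tuple(sorted(rng.choice(2, 2, p=[0.3, 0.7])))
                 for _ in range(10)] for _ in range(40)]
        ds, freqs = freq_table([2] * 10, rows)
        pooled = allele_frequencies(ds).pooled()
        parent = np.array([[0, 1]] * 10)
        child = np.array([[1, 1]] * 10)
        res = parentage_lod(child, parent, freqs, error_rate=0.01)
        expected = sum(
            lod_bruteforce((1, 1), (0, 1), pooled.vector(0, li), 0.01)
            for li in range(10)
        )
        assert res["lod"] == pytest.approx(expected, rel=1e-9)

    def test_additive_over_loci(self):
        rng = np.random.default_rng(4)
        rows = [[tuple(sorted(rng.choice(3, 2))) for _ in range(12)]
                for _ in range(30)]
        ds, freqs = freq_table([3] * 12, rows)
        parent = ds.genotypes[0]
        child = ds.genotypes[1]
        full = parentage_lod(child, parent, freqs, min_shared=1)["lod"]
        parts = 0.0
        for li in range(12):
            sub = ds.restrict_loci([ds.locus_names[li]])
            fsub = allele_frequencies(sub)
            parts += parentage_lod(child[[li]], parent[[li]], fsub,
                                   min_shared=1)["lod"]
        assert full == pytest.approx(parts, rel=1e-9)


class TestCriticalLod:
    def test_monotone_in_confidence(self):
        ds = balding_nichols_dataset(2, 60, 0.02, seed=0)
        freqs = allele_frequencies(ds)
        c90 = critical_lod(freqs, 50, confidence=0.90, reps=1500, seed=1)
        c99 = critical_lod(freqs, 50, confidence=0.99, reps=1500, seed=1)
        assert c99["critical_lod"] >= c90["critical_lod"]

    def test_unrelated_lods_negative_on_average(self):
        ds = balding_nichols_dataset(2, 60, 0.02, seed=1)
        freqs = allele_frequencies(ds)
        res = critical_lod(freqs, 30, reps=1000, seed=2)
        assert np.mean(res["unrelated_lods"]) < 0
        assert np.mean(res["true_pair_lods"]) > 0

    def test_requires_enough_replicates(self):
        ds = balding_nichols_dataset(2, 40, 0.02, seed=2)
        with pytest.raises(ValueError, match="reps"):
            critical_lod(allele_frequencies(ds), 10, reps=100)


class TestFindParentOffspring:
    def _scenario(self, seed):
        pops = [PopulationSpec("adults", 120, "farm-associated", "res"),
                PopulationSpec("juv", 100, "YoY", "res")]
        spec = ScenarioSpec(pops, {"res": 0.01}, pop_fst=0.003,
                            missing_rate=0.003, trios=[("adults", "juv", 6)],
                            seed=seed)
        return generate_scenario(spec)

    def test_planted_trios_recovered_with_low_false_positive_rate(self):
        """All planted parent-offspring pairs found; juveniles with no
        sampled parent are falsely assigned at most 5% of the time."""
        tot_fp = tot_missed = tot_clean = 0
        for seed in (0, 1):
            ds, truth = self._scenario(seed)
            adults = ds.subset_populations(["adults"])
            juv = ds.subset_populations(["juv"])
            freqs = allele_frequencies(ds)
            pairs = find_parent_offspring(adults, juv, freqs,
                                          ParentageSettings(reps=1000),
                                          seed=50 + seed)
            off = truth["individuals"].query("origin == 'trio_offspring'")
            true_pairs = set()
            for _, row in off.iterrows():
                true_pairs.add((row.parent1, row.individual))
                true_pairs.add((row.parent2, row.individual))
            found = set(zip(pairs.adult, pairs.juvenile))
            tot_missed += len(true_pairs - found)
            fp_juv = {j for _, j in (found - true_pairs)}
            tot_fp += len(fp_juv)
            tot_clean += 100 - len(off)
        assert tot_missed == 0
        assert tot_fp / tot_clean <= 0.05

    def test_empty_juvenile_set(self):
        ds, _ = self._scenario(3)
        adults = ds.subset_populations(["adults"])
        empty = ds.subset_populations(["juv"]).subset_individuals([])
        out = find_parent_offspring(adults, empty, allele_frequencies(ds),
                                    ParentageSettings(reps=1000), seed=0)
        assert len(out) == 0

    def test_accepted_set_invariant_to_individual_order(self):
        ds, _ = self._scenario(4)
        adults = ds.subset_populations(["adults"])
        juv = ds.subset_populations(["juv"])
        freqs = allele_frequencies(ds)
        crit = 6.0
        a = find_parent_offspring(adults, juv, freqs, critical=crit)
        rng = np.random.default_rng(0)
        perm = rng.permutation(adults.n_individuals)
        b = find_parent_offspring(adults.subset_individuals(perm), juv, freqs,
                                  critical=crit)
        assert set(zip(a.adult, a.juvenile)) == set(zip(b.adult, b.juvenile))


class TestNeLd:
    def test_small_sample_refused(self):
        ds = balding_nichols_dataset(1, 25, 0.02, seed=0)
        with pytest.raises(ValueError, match="not estimated"):
            ne_ld(ds, 0)

    def test_large_population_estimates_infinite_or_large(self):
        # HW draws are unlinked with no drift LD: r2' hovers at 0, so the
        # estimate is huge or infinite
        ds = balding_nichols_dataset(1, 80, 0.02, seed=1)
        est = ne_ld(ds, 0)
        assert est.ne > 500 or math.isinf(est.ne)

    def test_wright_fisher_recovery(self):
        estimates = [ne_ld(wright_fisher_sample(100, 60, 19, seed=s), 0).ne
                     for s in range(15)]
        assert 60 <= np.median(estimates) <= 170

    def test_cutoff_monotone_in_allele_pairs(self):
        ds = wright_fisher_sample(150, 60, 10, seed=3)
        loose = ne_ld(ds, 0, freq_cutoff=0.02)
        strict = ne_ld(ds, 0, freq_cutoff=0.10)
        assert strict.n_allele_pairs <= loose.n_allele_pairs

    def test_harmonic_mean_drops_infinite_terms(self):
        class E:
            def __init__(self, ne):
                self.ne = ne

        assert harmonic_mean_ne([E(100.0), E(float("inf"))]) == pytest.approx(100.0)
        assert math.isinf(harmonic_mean_ne([E(float("inf"))]))
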