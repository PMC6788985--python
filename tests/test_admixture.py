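"""Admixture EM, delta-K, label alignment, K selection and the hierarchy."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from escapetrace.admixture import (AdmixtureFit, align_labels,
                                   cross_validation_scores, delta_k,
                                   fit_admixture, fit_replicates,
                                   hierarchical_structure, select_k)
from escapetrace.dataset import GenotypeDataset, Locus
from escapetrace.simulate import (balding_nichols_freqs, clustered_dataset,
                                  hardy_weinberg_sample, panel_frequencies)
from conftest import make_dataset


def two_level_dataset(seed, fst_top=0.12, fst_sub=0.06, n_per=60, subs=(3, 2)):
    rng = np.random.default_rng(seed)
    anc = panel_frequencies(19, (7, 14), 0.8, rng)
    loci = [Locus(f"L{i}", tuple(range(1, p.size + 1))) for i, p in enumerate(anc)]
    rows, pops, names = [], [], []
    for t in range(len(subs)):
        top = [balding_nichols_freqs(p, fst_top, rng) for p in anc]
        for s in range(subs[t]):
            sub = [balding_nichols_freqs(p, fst_sub, rng) for p in top]
            rows.append(hardy_weinberg_sample(sub, n_per, rng))
            names.append(f"t{t}s{s}")
            pops += [len(names) - 1] * n_per
    return GenotypeDataset(loci, names, np.array(pops), np.concatenate(rows))


class TestFitAdmixture:
    def test_k1_reduces_to_pooled_multinomial(self):
        ds = clustered_dataset(2, 30, 0.05, n_loci=5, seed=0)
        fit = fit_admixture(ds, 1)
        assert np.allclose(fit.q, 1.0)
        # log-likelihood equals the multinomial of pooled frequencies
        expected = 0.0
        for li, locus in enumerate(ds.loci):
            copies = ds.genotypes[:, li, :].ravel()
            copies = copies[copies != -1]
            p = np.bincount(copies, minlength=locus.n_alleles) / copies.size
            expected += float(np.sum(np.log(p[copies])))
        assert fit.log_likelihood == pytest.approx(expected, rel=1e-6)
        np.testing.assert_allclose(
            fit.P[0][0], np.bincount(
                ds.genotypes[:, 0, :].ravel()[ds.genotypes[:, 0, :].ravel() != -1],
                minlength=ds.loci[0].n_alleles)
            / (2 * ds.n_individuals), atol=1e-9)

    def test_f1_between_fixed_pools_is_half_half(self):
        rows = ([[(0, 0)] * 6] * 12 + [[(1, 1)] * 6] * 12 + [[(0, 1)] * 6])
        ds = make_dataset(rows, [2] * 6, [25])
        fit = fit_admixture(ds, 2, seed=1, tol=1e-10, max_iter=3000)
        assert fit.q[-1] == pytest.approx([0.5, 0.5], abs=1e-3)

    def test_three_cluster_recovery(self):
        """Modal-cluster assignment accuracy above 0.9 at divergence 0.05."""
        accs = []
        for seed in range(4):
            ds = clustered_dataset(3, 50, 0.05, seed=seed)
            fit = fit_admixture(ds, 3, seed=seed)
            M = np.stack([fit.q[ds.pop_index == t].mean(axis=0) for t in range(3)])
            r, c = linear_sum_assignment(-M)
            inv = np.empty(3, dtype=int)
            inv[c] = r
            accs.append(np.mean(inv[fit.modal_cluster()] == ds.pop_index))
        assert np.mean(accs) > 0.9

    def test_loglik_monotone(self):
        ds = clustered_dataset(2, 40, 0.05, seed=2)
        fit = fit_admixture(ds, 2, seed=0)
        t = fit.loglik_trace
        assert all(b >= a - 1e-6 for a, b in zip(t, t[1:]))

    def test_q_rows_and_p_rows_are_simplices(self):
        ds = clustered_dataset(3, 30, 0.05, seed=5)
        fit = fit_admixture(ds, 3, seed=3)
        np.testing.assert_allclose(fit.q.sum(axis=1), 1.0, atol=1e-9)
        for p in fit.P:
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_k_exceeding_individuals_raises(self):
        ds = clustered_dataset(1, 5, 0.02, n_loci=3, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            fit_admixture(ds, 6)

    def test_supervised_agrees_with_unsupervised_when_separated(self):
        ds = clustered_dataset(2, 60, 0.1, seed=7)
        unsup = fit_admixture(ds, 2, seed=1)
        sup = fit_admixture(ds, 2, seed=2,
                            supervised_sources={"c1": 0, "c2": 1})
        corr = max(np.corrcoef(unsup.q[:, 0], sup.q[:, 0])[0, 1],
                   np.corrcoef(unsup.q[:, 0], sup.q[:, 1])[0, 1])
        assert corr > 0.95


class TestDeltaK:
    def _fits(self, lnls_by_k, sds_by_k=None):
        out = {}
        rng = np.random.default_rng(0)
        for k, mean in lnls_by_k.items():
            sd = 0.0 if sds_by_k is None else sds_by_k[k]
            lls = mean + (sd * np.array([-1.0, 0.0, 1.0]) if sd else np.zeros(3))
            out[k] = [AdmixtureFit(k, np.ones((2, k)) / k, [], float(l), 0, 1, True)
                      for l in lls]
        return out

    def test_linear_lnl_gives_zero(self):
        fits = self._fits({1: -1000.0, 2: -900.0, 3: -800.0, 4: -700.0},
                          {1: 5.0, 2: 5.0, 3: 5.0, 4: 5.0})
        table = delta_k(fits)
        assert table.loc[2, "delta_K"] == pytest.approx(0.0)
        assert table.loc[3, "delta_K"] == pytest.approx(0.0)

    def test_hand_worked_elbow(self):
        # means {-1000, -900, -890, -888}; replicate SD sqrt(ddof-1 var) of
        # [-5, 0, +5] is 5 -> delta K(2) = |(-890) - 2(-900) + (-1000)|/5 = 18
        fits = self._fits({1: -1000.0, 2: -900.0, 3: -890.0, 4: -888.0},
                          {k: 5.0 for k in (1, 2, 3, 4)})
        table = delta_k(fits)
        assert table.loc[2, "delta_K"] == pytest.approx(90 / 5.0)
        assert table.loc[3, "delta_K"] == pytest.approx(8 / 5.0)
        assert table.attrs["selected_K"] == 2

    def test_zero_sd_excluded_with_note(self):
        fits = self._fits({1: -1000.0, 2: -900.0, 3: -890.0})
        table = delta_k(fits)
        assert np.isnan(table.loc[2, "delta_K"])
        assert "zero SD" in table.loc[2, "note"]

    def test_requires_three_consecutive_k(self):
        with pytest.raises(ValueError):
            delta_k(self._fits({1: -10.0, 2: -9.0}))


class TestAlignLabels:
    def test_recovers_permutation_exactly(self):
        ds = clustered_dataset(3, 30, 0.08, seed=1)
        fit = fit_admixture(ds, 3, seed=4)
        perm = [2, 0, 1]
        permuted = AdmixtureFit(3, fit.q[:, perm], [p[perm] for p in fit.P],
                                fit.log_likelihood, 1, fit.iterations, True)
        aligned, mean_q = align_labels([fit, permuted])
        np.testing.assert_allclose(aligned[1].q, fit.q, atol=1e-12)
        np.testing.assert_allclose(mean_q.sum(axis=1), 1.0)

    def test_alignment_never_decreases_agreement(self):
        ds = clustered_dataset(3, 40, 0.06, seed=2)
        fits = [fit_admixture(ds, 3, seed=s) for s in range(3)]
        aligned, _ = align_labels(fits)
        for raw, al in zip(fits[1:], aligned[1:]):
            raw_score = np.trace(np.corrcoef(fits[0].q.T, raw.q.T)[:3, 3:])
            al_score = np.trace(np.corrcoef(fits[0].q.T, al.q.T)[:3, 3:])
            assert al_score >= raw_score - 1e-9


class TestSelectK:
    def test_panmictic_selects_one(self):
        ds = clustered_dataset(1, 120, 0.02, seed=0)
        fits = fit_replicates(ds, range(1, 4), replicates=1, seed=0)
        assert select_k(fits, ds, seed=0) == 1

    def test_four_clusters_selected(self):
        hits = 0
        for seed in range(3):
            ds = clustered_dataset(4, 60, 0.05, seed=300 + seed)
            scores = cross_validation_scores(ds, range(1, 7), seed=seed)
            hits += max(sorted(scores), key=lambda k: scores[k]) == 4
        assert hits >= 2


class TestHierarchy:
    def test_panmictic_depth_zero(self):
        ds = clustered_dataset(1, 100, 0.02, seed=1)
        # split the single sample into two arbitrary localities
        ds.pop_index[:50] = 0
        ds.pop_index[50:] = 1
        ds.pop_names = ["locA", "locB"]
        tree = hierarchical_structure(ds, replicates=2, seed=0)
        assert tree.selected_K == 1
        assert len(tree.leaves()) == 1

    def test_two_level_hierarchy_recovers_five_leaves(self):
        counts = []
        for seed in (1, 3, 4):
            ds = two_level_dataset(seed)
            tree = hierarchical_structure(ds, replicates=3, seed=seed)
            counts.append(len(tree.leaves()))
        assert sum(c == 5 for c in counts) >= 2

    def test_leaves_partition_root_assignment(self):
        ds = two_level_dataset(0)
        tree = hierarchical_structure(ds, replicates=2, seed=5)
        if tree.children:
            leaf_members = np.concatenate([l.individuals for l in tree.leaves()])
            assert len(leaf_members) == len(set(leaf_members.tolist()))
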