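"""Hybrid-class simulation, six-class classification, threshold calibration
and population-level ancestry banding."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from escapetrace.admixture import (DEFAULT_MEMBERSHIP_ALPHA, fit_admixture,
                                   posterior_mean_q2)
from escapetrace.dataset import GenotypeDataset, Locus
from escapetrace.hybrids import (CLASS_ORIGIN_PROPORTIONS, HYBRID_CLASSES,
                                 PurePanels, apply_hybrid_calls,
                                 calibrate_thresholds, classify_sixclass,
                                 select_pure_reference, simulate_hybrids)
from escapetrace.simulate import clustered_dataset, escapee_mixture_scenario, \
    generate_scenario
from conftest import make_dataset


def fixed_difference_panels(n_loci=8, n=20):
    rows1 = [[(0, 0)] * n_loci] * n
    rows2 = [[(1, 1)] * n_loci] * n
    p1 = make_dataset(rows1, [2] * n_loci, [n])
    p2 = make_dataset(rows2, [2] * n_loci, [n])
    return PurePanels.from_datasets(p1, p2)


def diverged_panels(fst=0.15, n=60, seed=0):
    ds = clustered_dataset(2, n, fst, seed=seed)
    return PurePanels.from_datasets(ds.subset_populations(["c1"]),
                                    ds.subset_populations(["c2"]))


def test_class_origin_proportions_are_distributions():
    for props in CLASS_ORIGIN_PROPORTIONS.values():
        assert sum(props) == pytest.approx(1.0)


class TestSimulateHybrids:
    def test_f1_fixed_pools_all_heterozygous(self):
        panels = fixed_difference_panels()
        ds, labels = simulate_hybrids(panels, {"F1": 50}, seed=0)
        g = ds.genotypes
        assert (g[:, :, 0] != g[:, :, 1]).all()

    def test_f2_mendelian_ratios(self):
        panels = fixed_difference_panels(n_loci=1)
        ds, _ = simulate_hybrids(panels, {"F2": 1000}, seed=1)
        g = ds.genotypes[:, 0, :]
        n_aa = int(((g == 0).all(axis=1)).sum())
        n_ab = int((g[:, 0] != g[:, 1]).sum())
        n_bb = 1000 - n_aa - n_ab
        chi2 = stats.chisquare([n_aa, n_ab, n_bb], [250, 500, 250])
        assert chi2.pvalue > 0.01

    def test_bc1_mean_ancestry_three_quarters(self):
        panels = fixed_difference_panels(n_loci=30)
        ds, _ = simulate_hybrids(panels, {"BC1": 200}, seed=2)
        pool1_fraction = (ds.genotypes == 0).mean()
        assert pool1_fraction == pytest.approx(0.75, abs=0.02)

    def test_class_frequency_expectations_match_mixture(self):
        """Simulated allele frequencies per class equal the analytic
        origin-proportion mixture of the pool frequencies (n = 2000)."""
        panels = diverged_panels(seed=3)
        for cname in ("F1", "BC1", "F2"):
            ds, _ = simulate_hybrids(panels, {cname: 2000}, seed=4)
            w11, w12, w22 = CLASS_ORIGIN_PROPORTIONS[cname]
            share1 = w11 + w12 / 2
            for li in (0, 5):
                copies = ds.genotypes[:, li, :].ravel()
                obs = np.bincount(copies, minlength=len(panels.freqs1[li]))
                obs = obs / obs.sum()
                expected = share1 * panels.freqs1[li] + (1 - share1) * panels.freqs2[li]
                assert np.abs(obs - expected).max() < 0.03

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            simulate_hybrids(fixed_difference_panels(), {"F3": 5})


class TestClassifySixclass:
    def test_posteriors_sum_to_one(self):
        panels = diverged_panels(seed=1)
        ds, _ = simulate_hybrids(panels, {c: 20 for c in HYBRID_CLASSES}, seed=5)
        post = classify_sixclass(ds, panels)
        np.testing.assert_allclose(post[HYBRID_CLASSES].sum(axis=1), 1.0)

    def test_all_het_fixed_pools_is_certain_f1(self):
        panels = fixed_difference_panels(n_loci=20)
        ds, _ = simulate_hybrids(panels, {"F1": 5}, seed=0)
        post = classify_sixclass(ds, panels)
        assert (post["F1"] > 0.999).all()

    def test_pure_genotype_recognized(self):
        panels = diverged_panels(fst=0.15, seed=2)
        ds, _ = simulate_hybrids(panels, {"Pure1": 40}, seed=6)
        post = classify_sixclass(ds, panels)
        assert (post["call"] == "Pure1").mean() > 0.5


class TestCalibration:
    def _calibration(self, seed=0):
        panels = diverged_panels(fst=0.12, seed=seed)
        rng = np.random.default_rng(seed)
        sets, adm = {}, {}
        for frac in (0.15, 0.33, 0.66):
            n = 200
            nh = int(n * frac)
            per = {"Pure1": (n - nh) // 2, "Pure2": (n - nh + 1) // 2,
                   "F1": nh // 4, "F2": nh // 4, "BC1": nh // 4,
                   "BC2": nh - 3 * (nh // 4)}
            sds, labels = simulate_hybrids(panels, per,
                                           seed=int(rng.integers(2 ** 31)))
            fit = fit_admixture(sds, 2, seed=int(rng.integers(2 ** 31)))
            f_cl = int(np.argmax([
                fit.q[np.asarray(labels) == "Pure2", c].mean() for c in range(2)]))
            sets[frac] = (sds, labels)
            adm[frac] = posterior_mean_q2(sds, fit, cluster=f_cl)
        return calibrate_thresholds(sets, panels, adm)

    def test_metric_definitions_forced_example(self):
        # 8 of 10 true hybrids called, 16 called in total of which 8 true
        from escapetrace.hybrids import _metrics
        eff, acc, perf = _metrics(8, 16, 10)
        assert (eff, acc, perf) == (0.8, 0.5, 0.4)

    def test_perfect_classifier_all_ones(self):
        panels = fixed_difference_panels(n_loci=20)
        sds, labels = simulate_hybrids(panels, {"Pure1": 30, "Pure2": 30,
                                                "F1": 30}, seed=3)
        q = np.where(np.asarray(labels) == "Pure2", 1.0,
                     np.where(np.asarray(labels) == "F1", 0.5, 0.0))
        table = calibrate_thresholds({"demo": (sds, labels)}, panels,
                                     {"demo": q}, thresholds=[0.8])
        adm = table[(table.route == "admixture") & table.group.isin(["hybrid", "pure"])]
        assert np.allclose(adm[["efficiency", "accuracy", "performance"]], 1.0)

    def test_performance_bounded_by_components(self):
        table = self._calibration(seed=1)
        ok = table.dropna(subset=["performance"])
        assert (ok.performance <= np.minimum(ok.efficiency, ok.accuracy) + 1e-9).all()

    def test_backcross_no_easier_than_f1(self):
        """Backcrosses overlap the parental classes, so their detection
        performance does not exceed the F1 class's (averaged over the grid)."""
        table = self._calibration(seed=2)
        adm = table[table.route == "admixture"]
        f1 = adm[adm.group == "F1"].performance.mean()
        bc = adm[adm.group.isin(["BC1", "BC2"])].performance.mean()
        assert bc <= f1 + 0.02

    def test_selected_threshold_on_grid(self):
        table = self._calibration(seed=3)
        sel = table.attrs["selected_threshold"]
        assert sel in np.round(np.arange(0.60, 0.951, 0.05), 2)


class TestSelectPureReference:
    def test_selection_and_consistency(self):
        ds = clustered_dataset(2, 120, 0.2, seed=4)
        fit = fit_admixture(ds, 2, seed=0)
        cl1 = int(np.argmax([fit.q[ds.pop_index == 0, c].mean() for c in range(2)]))
        panels = select_pure_reference(ds, fit, cl1, 1 - cl1, q_min=0.9,
                                       n_per_class=50)
        assert panels.pool1.n_individuals <= 50
        # panel pooled frequencies track the fitted cluster frequencies
        for li in (0, 3):
            assert np.abs(panels.freqs1[li] - fit.P[li][cl1]).max() < 0.08

    def test_too_few_qualifying_raises(self):
        from escapetrace.admixture import AdmixtureFit

        ds = clustered_dataset(2, 30, 0.02, seed=5)
        q = np.full((ds.n_individuals, 2), 0.5)
        flat = AdmixtureFit(2, q, [], 0.0, None, 1, True)
        with pytest.raises(ValueError, match="lower q_min"):
            select_pure_reference(ds, flat, 0, 1, q_min=0.95)


class TestApplyHybridCalls:
    def test_banding_rules(self):
        rows = [[(0, 0)]] * 3
        ds = make_dataset(rows, [2], [3])
        calls = apply_hybrid_calls(ds, np.array([0.95, 0.5, 0.02]), 0.9)
        assert list(calls["call"]) == ["farmed-origin", "hybrid", "pure-wild"]

    def test_planted_fraction_recovery(self):
        """10% escapees and 15% F1s planted in the impacted sample are
        recovered within five percentage points by supervised ancestry
        banding at a calibrated threshold."""
        esc_err, hyb_err = [], []
        for seed in (100, 101, 102):
            ds, truth = generate_scenario(escapee_mixture_scenario(seed))
            fit = fit_admixture(
                ds, 2, seed=3,
                supervised_sources={"wild_ref1": 0, "wild_ref2": 0,
                                    "farm_strain": 1})
            q = posterior_mean_q2(ds, fit, cluster=1)
            calls = apply_hybrid_calls(ds, q, 0.8)
            summary = calls.attrs["population_summary"]
            esc_err.append(summary.loc["impacted", "farmed-origin"] - 10.0)
            hyb_err.append(summary.loc["impacted", "hybrid"] - 15.0)
        assert np.abs(esc_err).max() < 5.0
        assert np.abs(hyb_err).max() < 5.0

    def test_sixclass_and_banding_agree_on_f1(self):
        """F1 detection agrees between the six-class posterior and the
        ancestry-band routes on well-separated pools (>= 90%)."""
        panels = diverged_panels(fst=0.25, n=80, seed=6)
        sds, labels = simulate_hybrids(panels, {"Pure1": 60, "Pure2": 60,
                                                "F1": 60}, seed=7)
        post = classify_sixclass(sds, panels)
        argmax_class = post[HYBRID_CLASSES].idxmax(axis=1)
        six_f1 = argmax_class.isin(["F1", "F2", "BC1", "BC2"]).to_numpy()
        fit = fit_admixture(sds, 2, seed=8)
        f_cl = int(np.argmax([fit.q[np.asarray(labels) == "Pure2", c].mean()
                              for c in range(2)]))
        q = posterior_mean_q2(sds, fit, cluster=f_cl)
        band_hybrid = (q > 0.1) & (q < 0.9)
        is_f1 = np.asarray(labels) == "F1"
        agree = (six_f1[is_f1] == band_hybrid[is_f1]).mean()
        assert agree >= 0.9
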