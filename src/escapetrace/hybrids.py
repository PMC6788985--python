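"""Hybrid-class simulation, six-class likelihood classification, and
threshold calibration for wild x farmed admixture calling.

The six genotype classes are defined by their allele-origin pair
proportions (both copies from pool 1, one from each, both from pool 2):

    Pure1 (1, 0, 0)    Pure2 (0, 0, 1)    F1 (0, 1, 0)
    F2 (1/4, 1/2, 1/4) BC1 (1/2, 1/2, 0)  BC2 (0, 1/2, 1/2)

Simulated individuals draw, per locus, an origin pattern from the class
proportions and then each allele from the corresponding pool's empirical
frequencies (loci independent).  The classifier evaluates each class's
likelihood with fixed pool frequencies (taken from the selected pure
reference panels) and assigns by posterior with a uniform prior, the
maximum-likelihood analogue of the six-class Bayesian classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .admixture import AdmixtureFit
from .dataset import MISSING, GenotypeDataset, Locus, allele_frequencies

__all__ = [
    "HYBRID_CLASSES",
    "CLASS_ORIGIN_PROPORTIONS",
    "select_pure_reference",
    "simulate_hybrids",
    "classify_sixclass",
    "calibrate_thresholds",
    "apply_hybrid_calls",
]

HYBRID_CLASSES = ["Pure1", "Pure2", "F1", "F2", "BC1", "BC2"]

# (both-from-1, one-each, both-from-2)
CLASS_ORIGIN_PROPORTIONS = {
    "Pure1": (1.0, 0.0, 0.0),
    "Pure2": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC1": (0.5, 0.5, 0.0),
    "BC2": (0.0, 0.5, 0.5),
}


@dataclass
class PurePanels:
    """Reference panels and pool allele frequencies for the two parental pools."""
    pool1: GenotypeDataset            # e.g. pure wild
    pool2: GenotypeDataset            # e.g. pure farmed
    freqs1: list                      # per locus frequency vector
    freqs2: list
    loci: list

    @classmethod
    def from_datasets(cls, pool1: GenotypeDataset, pool2: GenotypeDataset) -> "PurePanels":
        if pool1.locus_names != pool2.locus_names:
            raise ValueError("panels must share the locus panel")
        f1 = allele_frequencies(pool1).pooled()
        f2 = allele_frequencies(pool2).pooled()
        return cls(pool1, pool2,
                   [f1.vector(0, li) for li in range(pool1.n_loci)],
                   [f2.vector(0, li) for li in range(pool2.n_loci)],
                   list(pool1.loci))


def select_pure_reference(ds: GenotypeDataset, fit: AdmixtureFit, cluster1: int,
                          cluster2: int, q_min: float = 0.95,
                          n_per_class: int = 50) -> PurePanels:
    """Select up to ``n_per_class`` individuals per pool with q above ``q_min``.

    ``cluster1``/``cluster2`` identify the wild and farmed clusters in the
    admixture fit.  Raises when fewer than 10 individuals qualify for a
    pool, advising a lower threshold.
    """
    panels = []
    for cl in (cluster1, cluster2):
        qc = fit.q[:, cl]
        qualifying = np.flatnonzero(qc > q_min)
        if len(qualifying) < 10:
            raise ValueError(
                f"only {len(qualifying)} individuals exceed q={q_min} for cluster "
                f"{cl}; lower q_min"
            )
        top = qualifying[np.argsort(qc[qualifying])[::-1][:n_per_class]]
        panels.append(ds.subset_individuals(np.sort(top)))
    return PurePanels.from_datasets(*panels)


def simulate_hybrids(panels: PurePanels, class_counts: dict, seed=None,
                     ) -> tuple[GenotypeDataset, pd.Series]:
    """Simulate labelled individuals of the six classes from the pool frequencies.

    Per individual and locus, each of the two allele copies' origin pool is
    drawn according to the class's origin-pair proportions, then the allele
    is drawn from that pool's empirical frequencies; loci are independent.
    Returns the simulated dataset (one population per class) and the
    true-class labels.
    """
    rng = np.random.default_rng(seed)
    loci = panels.loci
    L = len(loci)
    rows, labels, pop_index, pop_names = [], [], [], []
    for cname, count in class_counts.items():
        if count < 0:
            raise ValueError("negative class count")
        if count == 0:
            continue
        if cname not in CLASS_ORIGIN_PROPORTIONS:
            raise ValueError(f"unknown class {cname!r}")
        w11, w12, w22 = CLASS_ORIGIN_PROPORTIONS[cname]
        pop_names.append(cname)
        for _ in range(count):
            geno = np.zeros((L, 2), dtype=np.int16)
            pattern = rng.choice(3, size=L, p=[w11, w12, w22])
            for li in range(L):
                p1 = panels.freqs1[li]
                p2 = panels.freqs2[li]
                if pattern[li] == 0:
                    pools = (p1, p1)
                elif pattern[li] == 2:
                    pools = (p2, p2)
                else:
                    pools = (p1, p2)
                geno[li, 0] = rng.choice(len(pools[0]), p=pools[0])
                geno[li, 1] = rng.choice(len(pools[1]), p=pools[1])
            rows.append(geno)
            labels.append(cname)
            pop_index.append(len(pop_names) - 1)
    ds = GenotypeDataset(loci, pop_names, np.array(pop_index), np.stack(rows))
    return ds, pd.Series(labels, name="true_class")


def _genotype_class_loglik(ds: GenotypeDataset, panels: PurePanels) -> pd.DataFrame:
    """Log-likelihood of each hybrid class per individual."""
    n = ds.n_individuals
    L = ds.n_loci
    out = np.zeros((n, len(HYBRID_CLASSES)))
    eps = 1e-9
    for li in range(L):
        p1 = np.maximum(panels.freqs1[li], eps)
        p2 = np.maximum(panels.freqs2[li], eps)
        p1 = p1 / p1.sum()
        p2 = p2 / p2.sum()
        g = ds.genotypes[:, li, :]
        ok = g[:, 0] != MISSING
        a, b = g[ok, 0], g[ok, 1]
        het = a != b
        # genotype probability under each origin pattern
        pr11 = np.where(het, 2 * p1[a] * p1[b], p1[a] ** 2)
        pr22 = np.where(het, 2 * p2[a] * p2[b], p2[a] ** 2)
        pr12 = np.where(het, p1[a] * p2[b] + p1[b] * p2[a], p1[a] * p2[a])
        for ci, cname in enumerate(HYBRID_CLASSES):
            w11, w12, w22 = CLASS_ORIGIN_PROPORTIONS[cname]
            lik = w11 * pr11 + w12 * pr12 + w22 * pr22
            out[ok, ci] += np.log(np.maximum(lik, 1e-300))
    return pd.DataFrame(out, columns=HYBRID_CLASSES)


def classify_sixclass(ds: GenotypeDataset, panels: PurePanels,
                      threshold: float = 0.5) -> pd.DataFrame:
    """Posterior over the six genotype classes per individual (uniform prior).

    The ``call`` column holds the class whose posterior exceeds
    ``threshold`` (the conventional 0.5), else ``ambiguous``.  Individuals
    untyped at every locus get NA posteriors.
    """
    ll = _genotype_class_loglik(ds, panels).to_numpy()
    untyped = (ds.genotypes[:, :, 0] == MISSING).all(axis=1)
    m = ll.max(axis=1, keepdims=True)
    post = np.exp(ll - m)
    post /= post.sum(axis=1, keepdims=True)
    post[untyped] = np.nan
    out = pd.DataFrame(post, columns=HYBRID_CLASSES)
    best = out.idxmax(axis=1)
    best_p = out.max(axis=1)
    call = np.where(best_p > threshold, best, "ambiguous")
    call = np.where(untyped, "NA", call)
    out["call"] = call
    return out


def _metrics(true_pos: int, called: int, truth: int):
    eff = true_pos / truth if truth else np.nan
    acc = true_pos / called if called else np.nan
    perf = eff * acc if called and truth else np.nan
    return eff, acc, perf


def calibrate_thresholds(simulated_sets: dict, panels: PurePanels,
                         admixture_q: dict | None = None,
                         thresholds=None, aggregate: str = "all") -> pd.DataFrame:
    """Efficiency / accuracy / performance over the threshold grid.

    ``simulated_sets`` maps a set label (e.g. hybrid proportion) to a
    ``(dataset, true_labels)`` pair; ``admixture_q`` optionally maps the
    same labels to each individual's farmed-cluster admixture coefficient
    (from a K = 2 fit), enabling the admixture-threshold route alongside
    the six-class posterior route.

    Admixture route per threshold t: an individual is called admixed
    (hybrid) when its max-cluster q < t, pure otherwise.  Efficiency is the
    proportion of a true group recovered, accuracy the proportion of calls
    that are correct, performance their product.  ``aggregate`` chooses the
    hybrid definition: ``all`` (F1+F2+BC1+BC2) or ``f1f2``.

    The report carries group-level rows (``hybrid`` / ``pure``) and
    class-level rows (per genotype class, with the class's own efficiency
    against the called side's accuracy).  The selected threshold
    (``.attrs['selected_threshold']``) maximizes the admixture-route mean
    performance over the six genotype classes, averaged across sets.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.60, 0.951, 0.05), 2)
    hybrid_classes = {"F1", "F2", "BC1", "BC2"} if aggregate == "all" else {"F1", "F2"}
    rows = []
    for label, (ds, truth) in simulated_sets.items():
        truth = np.asarray(truth)
        is_hybrid_true = np.isin(truth, list(hybrid_classes))
        consider = is_hybrid_true | np.isin(truth, ["Pure1", "Pure2"])
        # six-class route (threshold-free at posterior > 0.5)
        post = classify_sixclass(ds, panels)
        call = post["call"].to_numpy()
        is_hybrid_called = np.isin(call, list(hybrid_classes))

        def emit(route, t, group, true_mask, called_mask, eff_mask=None):
            """Group metrics; ``eff_mask`` restricts efficiency to a class."""
            tp = int(np.sum(true_mask & called_mask))
            eff, acc, perf = _metrics(tp, int(called_mask.sum()), int(true_mask.sum()))
            if eff_mask is not None:
                sub_tp = int(np.sum(eff_mask & called_mask))
                eff = sub_tp / int(eff_mask.sum()) if eff_mask.sum() else np.nan
                perf = eff * acc if np.isfinite(eff) and np.isfinite(acc) else np.nan
            rows.append({"set": label, "route": route, "threshold": t,
                         "group": group, "efficiency": eff, "accuracy": acc,
                         "performance": perf})

        pure_called = np.isin(call, ["Pure1", "Pure2"])
        emit("sixclass", 0.5, "hybrid", is_hybrid_true, is_hybrid_called)
        emit("sixclass", 0.5, "pure", ~is_hybrid_true & consider, pure_called)
        for cname in sorted(hybrid_classes):
            emit("sixclass", 0.5, cname, is_hybrid_true, is_hybrid_called,
                 eff_mask=(truth == cname))
        for cname in ("Pure1", "Pure2"):
            emit("sixclass", 0.5, cname, ~is_hybrid_true & consider, pure_called,
                 eff_mask=(truth == cname))
        if admixture_q is None:
            continue
        q_farm = np.asarray(admixture_q[label])
        q_max = np.maximum(q_farm, 1 - q_farm)
        for t in thresholds:
            admixed = q_max < t
            emit("admixture", float(t), "hybrid", is_hybrid_true, admixed)
            emit("admixture", float(t), "pure", ~is_hybrid_true & consider, ~admixed)
            for cname in sorted(hybrid_classes):
                emit("admixture", float(t), cname, is_hybrid_true, admixed,
                     eff_mask=(truth == cname))
            for cname in ("Pure1", "Pure2"):
                emit("admixture", float(t), cname, ~is_hybrid_true & consider,
                     ~admixed, eff_mask=(truth == cname))
    table = pd.DataFrame(rows)
    sel = None
    class_names = set(CLASS_ORIGIN_PROPORTIONS)
    adm = table[(table["route"] == "admixture") & table["group"].isin(class_names)]
    if len(adm):
        mean_perf = adm.groupby("threshold")["performance"].mean()
        sel = float(mean_perf.idxmax())
    table.attrs["selected_threshold"] = sel
    return table


def apply_hybrid_calls(ds: GenotypeDataset, farmed_q: np.ndarray,
                       q_threshold: float = 0.9) -> pd.DataFrame:
    """Band individuals by farmed-cluster admixture coefficient.

    farmed-origin when q_farm > threshold; pure wild when
    q_farm < 1 - threshold; hybrid (aquaculture ancestry) in between.
    Returns the per-individual call plus a per-population percentage
    summary in ``.attrs['population_summary']``.
    """
    q = np.asarray(farmed_q, dtype=float)
    if q.shape[0] != ds.n_individuals:
        raise ValueError("farmed_q length mismatch")
    call = np.where(q > q_threshold, "farmed-origin",
                    np.where(q < 1 - q_threshold, "pure-wild", "hybrid"))
    out = pd.DataFrame({
        "individual": ds.ids,
        "population": [ds.pop_names[p] for p in ds.pop_index],
        "q_farmed": q,
        "call": call,
    })
    summary = (
        out.groupby("population")["call"]
        .value_counts(normalize=True).unstack(fill_value=0.0) * 100.0
    )
    for col in ("pure-wild", "hybrid", "farmed-origin"):
        if col not in summary:
            summary[col] = 0.0
    out.attrs["population_summary"] = summary[["pure-wild", "hybrid", "farmed-origin"]]
    return out
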