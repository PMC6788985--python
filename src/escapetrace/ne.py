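"""Single-sample effective population size from linkage disequilibrium.

Unlinked loci in a finite population carry excess between-locus association
(Burrows composite disequilibrium) whose expectation under random mating is
1/(3 Ne) after removing the sampling contribution E[r^2 | n].  The
estimator averages the squared composite correlation r^2 over all allele
pairs across locus pairs (alleles at frequency <= the cutoff excluded),
subtracts the Waples sample-size expectation (1/n + 3.19/n^2 for n >= 30),
and inverts

    Ne = (1/3 + sqrt(1/9 - 2.76 r2')) / (2 r2')

with Ne = infinity when the adjusted r2' is <= 0.  Confidence limits come
from a jackknife over locus pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataset import MISSING, GenotypeDataset

__all__ = ["NeEstimate", "ne_ld"]


@dataclass
class NeEstimate:
    ne: float                       # may be inf
    ci95: tuple                     # (low, high); high may be inf
    r2_mean: float
    r2_prime: float
    n_allele_pairs: int
    n_locus_pairs: int
    freq_cutoff: float
    harmonic_n: float


def _expected_r2(n: float) -> float:
    # Waples (2006) second-order approximation, random mating, n >= 30
    return 1.0 / n + 3.19 / (n * n)


def _ne_from_r2prime(r2p: float) -> float:
    if r2p <= 0:
        return float("inf")
    disc = max(0.0, 1.0 / 9.0 - 2.76 * r2p)
    return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2p)


def ne_ld(ds: GenotypeDataset, pop, freq_cutoff: float = 0.02,
          min_n: int = 30) -> NeEstimate:
    """LD-method Ne for one population sample.

    Refuses samples of ``min_n`` or fewer individuals (small samples make
    the sampling correction unreliable).  Allele-pair r^2 values are
    weighted equally; the jackknife leaves out one locus pair at a time.
    """
    pi = ds.pop_position(pop) if isinstance(pop, str) else pop
    work = ds.active_view()
    sub = work.subset_individuals(np.flatnonzero(work.pop_index == pi))
    if sub.n_individuals <= min_n:
        raise ValueError(
            f"sample size {sub.n_individuals} <= {min_n}; LD-Ne not estimated"
        )
    L = sub.n_loci

    # per-locus allele dosage matrices restricted to alleles above the cutoff
    dosages = []
    for li, locus in enumerate(sub.loci):
        g = sub.genotypes[:, li, :]
        ok = g[:, 0] != MISSING
        k = locus.n_alleles
        dose = np.zeros((sub.n_individuals, k))
        np.add.at(dose, (np.repeat(np.arange(sub.n_individuals), 2)[np.repeat(ok, 2)],
                         g[ok].ravel()), 1.0)
        freqs = dose[ok].sum(axis=0) / (2 * ok.sum()) if ok.sum() else np.zeros(k)
        keep = np.flatnonzero(freqs > freq_cutoff)
        dosages.append((dose[:, keep], ok, freqs[keep]))

    pair_r2 = []     # mean r2 per locus pair
    pair_w = []      # allele-pair count per locus pair
    pair_n = []
    for i in range(L):
        di, oki, _ = dosages[i]
        if di.shape[1] < 2:
            continue
        for j in range(i + 1, L):
            dj, okj, _ = dosages[j]
            if dj.shape[1] < 2:
                continue
            both = oki & okj
            n = int(both.sum())
            if n <= min_n:
                continue
            x = di[both]
            y = dj[both]
            px = x.sum(axis=0) / (2 * n)
            py = y.sum(axis=0) / (2 * n)
            # Burrows composite covariance per allele pair
            cov = (x.T @ y) / n / 2.0 - 2.0 * np.outer(px, py) / 1.0
            cov *= n / (n - 1.0)
            denom = np.outer(px * (1 - px), py * (1 - py))
            r2 = (cov ** 2) / denom
            pair_r2.append(float(r2.mean()))
            pair_w.append(r2.size)
            pair_n.append(n)
    if not pair_r2:
        raise ValueError("no usable locus pairs after filtering")
    pair_r2 = np.asarray(pair_r2)
    pair_w = np.asarray(pair_w, dtype=float)
    pair_n = np.asarray(pair_n, dtype=float)
    w = pair_w / pair_w.sum()
    r2_mean = float(np.sum(w * pair_r2))
    harm_n = float(1.0 / np.sum(w / pair_n))
    r2p = r2_mean - _expected_r2(harm_n)
    ne = _ne_from_r2prime(r2p)

    # jackknife over locus pairs on the weighted mean
    if len(pair_r2) > 2:
        jk = []
        total_w = pair_w.sum()
        total = float(np.sum(pair_w * pair_r2))
        total_invn = float(np.sum(pair_w / pair_n))
        for m in range(len(pair_r2)):
            ww = total_w - pair_w[m]
            mean_m = (total - pair_w[m] * pair_r2[m]) / ww
            hn_m = ww / (total_invn - pair_w[m] / pair_n[m])
            jk.append(mean_m - _expected_r2(hn_m))
        jk = np.asarray(jk)
        m = len(jk)
        theta_bar = jk.mean()
        se = math.sqrt((m - 1) / m * float(np.sum((jk - theta_bar) ** 2)))
        lo_r2p = r2p - 1.96 * se
        hi_r2p = r2p + 1.96 * se
        ci = (_ne_from_r2prime(hi_r2p), _ne_from_r2prime(lo_r2p))
    else:
        ci = (float("nan"), float("nan"))
    return NeEstimate(ne, ci, r2_mean, r2p, int(pair_w.sum()), len(pair_r2),
                      freq_cutoff, harm_n)


def harmonic_mean_ne(estimates) -> float:
    """Harmonic-mean group summary; infinite estimates drop their term."""
    es = list(estimates)
    inv = [1.0 / e.ne for e in es if math.isfinite(e.ne) and e.ne > 0]
    if not inv:
        return float("inf")
    return len(inv) / sum(inv)
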