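"""Power assessment of a marker panel for detecting weak differentiation.

Populations diverge by pure drift: starting from common base allele
frequencies, each population drifts t generations at effective size Ne
(binomial resampling of 2Ne gene copies per generation), yielding an
expected differentiation of FST = 1 - (1 - 1/(2Ne))^t.  Observed samples
are then drawn at the study's sample sizes and tested for homogeneity with
a per-locus conditional exact test (Monte Carlo permutation of gene copies
over populations, chi-square statistic) combined across loci by Fisher's
method; power is the fraction of replicates significant at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["PowerScenario", "expected_fst", "simulate_power", "default_panel_frequencies"]


@dataclass
class PowerScenario:
    base_freqs: list                  # per locus: ancestral allele frequency vector
    sample_sizes: list                # individuals per population sample
    ne: int
    t: int
    replicates: int = 1000
    alpha: float = 0.05
    mc_permutations: int = 99
    per_locus_test: str = "mc_exact"   # or "chi2" (asymptotic)

    @property
    def expected_fst(self) -> float:
        return expected_fst(self.ne, self.t)


def expected_fst(ne: float, t: float) -> float:
    """Pure-drift expectation 1 - (1 - 1/(2 Ne))^t."""
    if ne < 1 or t < 0:
        raise ValueError("need Ne >= 1 and t >= 0")
    return 1.0 - (1.0 - 1.0 / (2.0 * ne)) ** t


def drift_for_target_fst(target: float, ne: int) -> int:
    """Smallest generation count whose drift expectation reaches ``target``."""
    t = int(np.ceil(np.log1p(-target) / np.log1p(-1.0 / (2 * ne))))
    return max(t, 0)


def default_panel_frequencies(n_loci: int = 19, allele_range=(7, 14),
                              target_he: float = 0.8, seed=0) -> list:
    """A synthetic microsatellite panel matched to a high-diversity survey:
    7-14 alleles per locus with geometric-decay frequencies scaled so each
    locus's expected heterozygosity is close to ``target_he``."""
    rng = np.random.default_rng(seed)
    freqs = []
    for _ in range(n_loci):
        k = int(rng.integers(allele_range[0], allele_range[1] + 1))
        # geometric shape p_i ~ x^i; solve decay x so that 1 - sum p^2 = He
        best = None
        for x in np.linspace(0.4, 0.999, 120):
            p = x ** np.arange(k)
            p = p / p.sum()
            he = 1 - np.sum(p ** 2)
            if best is None or abs(he - target_he) < best[0]:
                best = (abs(he - target_he), p)
        p = best[1]
        freqs.append(rng.permutation(p))
    return freqs


def _drift(freq: np.ndarray, ne: int, t: int, n_pops: int, rng) -> np.ndarray:
    """Drift one locus's frequencies independently in n_pops populations."""
    k = freq.size
    f = np.tile(freq, (n_pops, 1))
    copies = 2 * ne
    for _ in range(t):
        for pi in range(n_pops):
            f[pi] = rng.multinomial(copies, f[pi]) / copies
    return f


def _mc_exact_p(counts: np.ndarray, permutations: int, rng) -> float:
    """Monte Carlo conditional exact test on a pops x alleles count table.

    Gene copies are shuffled over populations (margins fixed); the
    chi-square statistic orders tables.  The returned p-value is the
    randomized version (#extreme + U)/(B + 1), which is exactly uniform
    under the null despite the discreteness of the Monte Carlo tail, so
    Fisher's combination across loci stays calibrated.
    """
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    keep_r = row > 0
    keep_c = col > 0
    counts = counts[np.ix_(keep_r, keep_c)]
    row = row[keep_r]
    col = col[keep_c]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return 1.0
    N = int(row.sum())
    expected = np.outer(row, col) / N
    obs_stat = float(np.sum((counts - expected) ** 2 / expected))
    pop_of_copy = np.repeat(np.arange(row.size), row.astype(int))
    alleles = np.repeat(np.arange(col.size), col.astype(int))
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(alleles)
        table = np.zeros_like(expected)
        np.add.at(table, (pop_of_copy, perm), 1.0)
        stat = float(np.sum((table - expected) ** 2 / expected))
        if stat >= obs_stat - 1e-12:
            hits += 1
    return (hits + rng.random()) / (permutations + 1)


def _chi2_p(counts: np.ndarray) -> float:
    """Asymptotic chi-square test on the allele-count table (rare allele
    columns pooled so expected counts stay reasonable)."""
    col = counts.sum(axis=0)
    keep = counts[:, col > 0]
    col = col[col > 0]
    # pool columns with total count < 5 into one
    rare = col < 5
    if rare.sum() > 1:
        pooled = keep[:, rare].sum(axis=1, keepdims=True)
        keep = np.concatenate([keep[:, ~rare], pooled], axis=1)
    row = keep.sum(axis=1)
    keep = keep[row > 0]
    if keep.shape[0] < 2 or keep.shape[1] < 2:
        return 1.0
    return float(stats.chi2_contingency(keep)[1])


def simulate_power(scenario: PowerScenario, seed=None) -> dict:
    """Estimate power (with a binomial 95% CI) for the drift scenario.

    Per replicate: drift each population's frequencies, draw multinomial
    allele-count samples at the stated sizes, test each locus by the Monte
    Carlo exact test and combine with Fisher's -2 sum ln p (chi-square with
    2 L df).  A locus fixed in all populations contributes p = 1.
    Also returns the realized mean Weir-like FST of the drifted frequencies
    as a check on the drift parameterization.
    """
    if scenario.replicates < 100:
        raise ValueError("need >= 100 replicates")
    rng = np.random.default_rng(seed)
    n_pops = len(scenario.sample_sizes)
    sizes = np.asarray(scenario.sample_sizes, dtype=int)
    L = len(scenario.base_freqs)
    sig = 0
    realized_fst = []
    for _ in range(scenario.replicates):
        pvals = []
        fst_num = fst_den = 0.0
        for freq in scenario.base_freqs:
            drifted = _drift(np.asarray(freq, dtype=float), scenario.ne,
                             scenario.t, n_pops, rng)
            pbar = drifted.mean(axis=0)
            var = drifted.var(axis=0, ddof=1)
            fst_num += float(var.sum())
            fst_den += float((pbar * (1 - pbar)).sum())
            counts = np.zeros((n_pops, freq.size))
            for pi in range(n_pops):
                counts[pi] = rng.multinomial(2 * sizes[pi], drifted[pi])
            if scenario.per_locus_test == "chi2":
                pvals.append(_chi2_p(counts))
            else:
                pvals.append(_mc_exact_p(counts, scenario.mc_permutations, rng))
        realized_fst.append(fst_num / fst_den if fst_den > 0 else 0.0)
        combined = -2.0 * np.sum(np.log(np.maximum(pvals, 1e-300)))
        p_comb = float(stats.chi2.sf(combined, df=2 * L))
        if p_comb <= scenario.alpha:
            sig += 1
    power = sig / scenario.replicates
    lo, hi = stats.binomtest(sig, scenario.replicates).proportion_ci(0.95)
    return {
        "power": power,
        "ci95": (float(lo), float(hi)),
        "replicates": scenario.replicates,
        "alpha": scenario.alpha,
        "expected_fst": scenario.expected_fst,
        "realized_mean_fst": float(np.mean(realized_fst)),
    }
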