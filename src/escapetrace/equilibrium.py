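"""Exact tests for Hardy-Weinberg and linkage equilibrium, and Holm correction.

Both tests are conditional exact tests evaluated by Markov-chain Monte
Carlo.  The chain state is an explicit arrangement of allele copies (HWE)
or of between-locus genotype pairings (LD); random transpositions give a
symmetric, always-accepted proposal whose uniform stationary distribution
over arrangements induces exactly the null conditional distribution of the
table given its margins.  The p-value is the fraction of visited states
whose conditional probability is <= the observed table's, with a Monte
Carlo standard error estimated from batch means.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .dataset import MISSING, GenotypeDataset

__all__ = [
    "ExactTestResult",
    "hwe_exact_test",
    "hwe_exact_enumeration",
    "ld_exact_test",
    "sequential_bonferroni",
]


@dataclass
class ExactTestResult:
    p_value: float
    se: float
    dememorization: int
    batches: int
    iterations_per_batch: int
    test: str = "hwe"
    note: str | None = None

    @property
    def is_na(self) -> bool:
        return math.isnan(self.p_value)


def _na_result(test, note, demem, batches, iters):
    return ExactTestResult(float("nan"), float("nan"), demem, batches, iters, test, note)


def _cell_genotypes(ds: GenotypeDataset, pop, locus) -> np.ndarray:
    pi = ds.pop_position(pop) if isinstance(pop, str) else pop
    li = ds.locus_position(locus) if isinstance(locus, str) else locus
    g = ds.genotypes[ds.pop_index == pi, li, :]
    return g[g[:, 0] != MISSING]


def hwe_exact_test(ds: GenotypeDataset, pop, locus, dememorization: int = 10000,
                   batches: int = 100, iterations_per_batch: int = 5000,
                   seed=None) -> ExactTestResult:
    """Markov-chain exact test of Hardy-Weinberg proportions for one cell.

    The chain performs random transpositions of allele copies between
    individuals, which leaves the allele counts fixed and samples genotype
    tables from their conditional distribution under HWE.  The p-value is
    the probability-ordering tail: the fraction of sampled tables at most
    as probable as the observed one.
    """
    g = _cell_genotypes(ds, pop, locus)
    n = g.shape[0]
    if n == 0:
        return _na_result("hwe", "no genotypes", dememorization, batches, iterations_per_batch)
    labels = np.unique(g)
    if labels.size < 2:
        return _na_result("hwe", "monomorphic", dememorization, batches, iterations_per_batch)

    k = int(g.max()) + 1
    counts = [[0] * k for _ in range(k)]
    geno = [[int(a), int(b)] for a, b in g]
    for a, b in geno:
        counts[a][b] += 1
    lg = [math.lgamma(i + 1) for i in range(2 * n + 1)]
    ln2 = math.log(2.0)

    def stat_full():
        s = 0.0
        for a in range(k):
            for b in range(a, k):
                c = counts[a][b]
                if c:
                    s -= lg[c]
                    if a != b:
                        s += c * ln2
        return s

    stat = stat_full()
    obs = stat + 1e-9
    rng = random.Random(seed)
    randrange = rng.randrange
    two_n = 2 * n

    def step():
        nonlocal stat
        s1 = randrange(two_n)
        s2 = randrange(two_n)
        i1, j1 = divmod(s1, 2)
        i2, j2 = divmod(s2, 2)
        if i1 == i2:
            return
        x = geno[i1][j1]
        y = geno[i2][j2]
        if x == y:
            return
        # remove both old genotypes, insert the swapped ones
        for (a, b), sgn in (
            (geno[i1], -1), (geno[i2], -1),
        ):
            lo, hi = (a, b) if a <= b else (b, a)
            c = counts[lo][hi]
            stat += lg[c]
            if lo != hi:
                stat -= c * ln2
            counts[lo][hi] = c + sgn
            c += sgn
            stat -= lg[c]
            if lo != hi:
                stat += c * ln2
        geno[i1][j1] = y
        geno[i2][j2] = x
        for pair in (geno[i1], geno[i2]):
            a, b = pair
            lo, hi = (a, b) if a <= b else (b, a)
            c = counts[lo][hi]
            stat += lg[c]
            if lo != hi:
                stat -= c * ln2
            counts[lo][hi] = c + 1
            c += 1
            stat -= lg[c]
            if lo != hi:
                stat += c * ln2

    for _ in range(dememorization):
        step()
    batch_p = []
    for _ in range(batches):
        hits = 0
        for _ in range(iterations_per_batch):
            step()
            if stat <= obs:
                hits += 1
        batch_p.append(hits / iterations_per_batch)
    p = float(np.mean(batch_p))
    se = float(np.std(batch_p, ddof=1) / math.sqrt(batches)) if batches > 1 else float("nan")
    return ExactTestResult(p, se, dememorization, batches, iterations_per_batch, "hwe")


def hwe_exact_enumeration(genotype_counts) -> float:
    """Complete-enumeration exact HWE p-value for a biallelic sample.

    ``genotype_counts`` is ``(n11, n12, n22)``.  All tables compatible with
    the allele counts are enumerated; the p-value sums the conditional
    probabilities of tables no more probable than the observed one
    (Levene/Haldane distribution).  Serves as the independent oracle for
    the Markov-chain test.
    """
    n11, n12, n22 = (int(x) for x in genotype_counts)
    n1 = 2 * n11 + n12
    n2 = 2 * n22 + n12
    n = n11 + n12 + n22
    lg = math.lgamma

    def logprob(h):
        a = (n1 - h) // 2
        b = (n2 - h) // 2
        return (h * math.log(2.0) + lg(n + 1) - lg(a + 1) - lg(h + 1) - lg(b + 1)
                + lg(n1 + 1) + lg(n2 + 1) - lg(2 * n + 1))

    hs = [h for h in range(n1 % 2, min(n1, n2) + 1, 2)]
    logs = np.array([logprob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[hs.index(n12)]
    return float(probs[probs <= obs + 1e-12].sum())


def _genotype_codes(g: np.ndarray):
    """Map canonical genotype pairs to dense integer codes."""
    key = g[:, 0].astype(np.int64) * 10000 + g[:, 1]
    uniq, codes = np.unique(key, return_inverse=True)
    return codes, uniq.size


def ld_exact_test(ds: GenotypeDataset, pop, locus_pair, dememorization: int = 10000,
                  batches: int = 100, iterations_per_batch: int = 5000,
                  seed=None) -> ExactTestResult:
    """Markov-chain exact test of genotypic linkage disequilibrium.

    The two-locus genotype contingency table is tested against independence
    by randomly re-pairing individuals' genotypes at the second locus (a
    transposition chain over pairings; margins fixed).  The p-value is the
    probability-ordering tail of the conditional (multivariate
    hypergeometric) distribution.
    """
    la, lb = locus_pair
    pi = ds.pop_position(pop) if isinstance(pop, str) else pop
    ia = ds.locus_position(la) if isinstance(la, str) else la
    ib = ds.locus_position(lb) if isinstance(lb, str) else lb
    sel = ds.pop_index == pi
    ga = ds.genotypes[sel, ia, :]
    gb = ds.genotypes[sel, ib, :]
    ok = (ga[:, 0] != MISSING) & (gb[:, 0] != MISSING)
    ga, gb = ga[ok], gb[ok]
    n = ga.shape[0]
    if n == 0 or np.unique(ga).size < 2 or np.unique(gb).size < 2:
        return _na_result("ld", "monomorphic or empty", dememorization, batches,
                          iterations_per_batch)

    ca, ka = _genotype_codes(ga)
    cb, kb = _genotype_codes(gb)
    counts = [[0] * kb for _ in range(ka)]
    assign = list(map(int, cb))
    ca_l = list(map(int, ca))
    for i in range(n):
        counts[ca_l[i]][assign[i]] += 1
    lg = [math.lgamma(i + 1) for i in range(n + 1)]
    stat = -sum(lg[c] for row in counts for c in row if c)
    obs = stat + 1e-9
    rng = random.Random(seed)
    randrange = rng.randrange

    def step():
        nonlocal stat
        i = randrange(n)
        j = randrange(n)
        if i == j:
            return
        ai, aj = ca_l[i], ca_l[j]
        bi, bj = assign[i], assign[j]
        if ai == aj or bi == bj:
            if bi != bj:
                assign[i], assign[j] = bj, bi
            return
        for (r, c), sgn in (((ai, bi), -1), ((aj, bj), -1), ((ai, bj), +1), ((aj, bi), +1)):
            old = counts[r][c]
            stat += lg[old]
            counts[r][c] = old + sgn
            stat -= lg[old + sgn]
        assign[i], assign[j] = bj, bi

    for _ in range(dememorization):
        step()
    batch_p = []
    for _ in range(batches):
        hits = 0
        for _ in range(iterations_per_batch):
            step()
            if stat <= obs:
                hits += 1
        batch_p.append(hits / iterations_per_batch)
    p = float(np.mean(batch_p))
    se = float(np.std(batch_p, ddof=1) / math.sqrt(batches)) if batches > 1 else float("nan")
    return ExactTestResult(p, se, dememorization, batches, iterations_per_batch, "ld")


def sequential_bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm's sequential Bonferroni: boolean rejection flags at family level.

    Sort ascending and reject p_(i) while p_(i) <= alpha/(m-i+1); stop at
    the first failure.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject
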