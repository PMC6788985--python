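"""Per-population genetic-diversity summaries.

Implements the standard microsatellite panel statistics: allele counts (A),
effective allele number (Ae = 1/sum p_i^2), rarefied allelic richness (Ar),
observed and unbiased expected heterozygosity (Ho, He), Weir & Cockerham's
within-population inbreeding coefficient f (FIS) with permutation
significance, and polymorphic information content (PIC).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dataset import MISSING, AlleleFrequencyTable, GenotypeDataset, allele_frequencies

__all__ = [
    "heterozygosities",
    "effective_alleles",
    "allele_counts",
    "allelic_richness",
    "fis",
    "fis_permutation_test",
    "pic",
    "diversity_summary",
    "allele_frequency_correlation",
]


def _cell_iter(ds: GenotypeDataset):
    for pi in range(ds.n_populations):
        members = ds.pop_index == pi
        for li in range(ds.n_loci):
            yield pi, li, ds.genotypes[members, li, :]


def heterozygosities(freqs: AlleleFrequencyTable, ds: GenotypeDataset):
    """Observed and unbiased expected heterozygosity per (population, locus).

    He uses Nei's small-sample correction (2n/(2n-1)) (1 - sum p_i^2).
    Cells with < 2 non-missing individuals are NaN.
    """
    P, L = ds.n_populations, ds.n_loci
    ho = np.full((P, L), np.nan)
    he = np.full((P, L), np.nan)
    for pi, li, g in _cell_iter(ds):
        ok = g[:, 0] != MISSING
        n = int(ok.sum())
        if n < 2:
            continue
        ho[pi, li] = float((g[ok, 0] != g[ok, 1]).mean())
        p = freqs.freq[pi, li]
        n2 = freqs.gene_count[pi, li]
        he[pi, li] = (n2 / (n2 - 1)) * (1.0 - float(np.sum(p * p)))
    return ho, he


def effective_alleles(freqs: AlleleFrequencyTable) -> np.ndarray:
    """Ae = 1 / sum p_i^2 per (population, locus); NaN where undefined."""
    homo = np.sum(freqs.freq ** 2, axis=2)
    with np.errstate(divide="ignore"):
        ae = 1.0 / homo
    ae[freqs.undefined] = np.nan
    return ae


def allele_counts(freqs: AlleleFrequencyTable) -> np.ndarray:
    """Observed allele count A per (population, locus)."""
    a = (freqs.freq > 0).sum(axis=2).astype(float)
    a[freqs.undefined] = np.nan
    return a


def allelic_richness(ds: GenotypeDataset, g: int | None = None) -> np.ndarray:
    """Rarefied allelic richness at a standardized gene count ``g``.

    Ar = sum_i [1 - C(N - N_i, g) / C(N, g)] over alleles, the expected
    number of distinct alleles in a random subsample of g gene copies.
    ``g`` defaults to the smallest per-locus gene count over populations
    (the FSTAT convention); an explicit ``g`` exceeding some cell's gene
    count raises, naming the cell.
    """
    freqs = allele_frequencies(ds)
    counts = np.rint(freqs.freq * freqs.gene_count[:, :, None]).astype(np.int64)
    N = freqs.gene_count  # (P, L)
    if g is None:
        valid = N[N > 0]
        if valid.size == 0:
            raise ValueError("no genotyped cells")
        g = int(N[N > 0].min())
    bad = np.argwhere((N < g) & (N > 0))
    if bad.size:
        pi, li = bad[0]
        raise ValueError(
            f"g={g} exceeds gene count {N[pi, li]} in cell "
            f"({ds.pop_names[pi]}, {ds.locus_names[li]})"
        )
    P, L = N.shape
    ar = np.full((P, L), np.nan)
    for pi in range(P):
        for li in range(L):
            n = N[pi, li]
            if n == 0:
                continue
            ni = counts[pi, li][counts[pi, li] > 0].astype(float)
            # log C(n - ni, g) - log C(n, g), with C(m, g) = 0 when m < g
            keep = (n - ni) >= g
            term = np.zeros_like(ni)
            if keep.any():
                m = n - ni[keep]
                term[keep] = np.exp(
                    gammaln(m + 1) - gammaln(g + 1) - gammaln(m - g + 1)
                    - (gammaln(n + 1) - gammaln(g + 1) - gammaln(n - g + 1))
                )
            ar[pi, li] = float(np.sum(1.0 - term))
    return ar


def _fis_components(g: np.ndarray, n_alleles: int):
    """Weir & Cockerham within-population variance components (b, c sums).

    Returns (sum_b_plus_c, sum_c) over alleles for one (pop, locus) cell, or
    None when the cell is monomorphic/undersized.
    """
    ok = g[:, 0] != MISSING
    gg = g[ok]
    n = gg.shape[0]
    if n < 2:
        return None
    counts = np.bincount(gg.ravel(), minlength=n_alleles).astype(float)
    p = counts / (2 * n)
    if np.count_nonzero(p) < 2:
        return None
    het = gg[:, 0] != gg[:, 1]
    sum_bc = 0.0
    sum_c = 0.0
    for a in np.flatnonzero(p):
        pa = p[a]
        ha = float(np.mean(het & ((gg[:, 0] == a) | (gg[:, 1] == a))))
        b = (n / (n - 1.0)) * (pa * (1 - pa) - (2 * n - 1) / (4.0 * n) * ha)
        c = ha / 2.0
        sum_bc += b + c
        sum_c += c
    return sum_bc, sum_c


def fis(ds: GenotypeDataset, freqs: AlleleFrequencyTable | None = None):
    """Weir & Cockerham's f (FIS) per (population, locus) and multilocus.

    The multilocus value per population is the ratio of summed variance
    components across loci (monomorphic cells excluded).  Returns
    ``(per_cell, multilocus)`` arrays of shape (P, L) and (P,).
    """
    P, L = ds.n_populations, ds.n_loci
    per_cell = np.full((P, L), np.nan)
    num = np.zeros(P)
    den = np.zeros(P)
    for pi, li, g in _cell_iter(ds):
        comp = _fis_components(g, ds.loci[li].n_alleles)
        if comp is None:
            continue
        sum_bc, sum_c = comp
        if sum_bc > 0:
            per_cell[pi, li] = 1.0 - sum_c / sum_bc
        num[pi] += sum_c
        den[pi] += sum_bc
    with np.errstate(invalid="ignore", divide="ignore"):
        multi = 1.0 - num / den
    multi[den == 0] = np.nan
    return per_cell, multi


def fis_permutation_test(ds: GenotypeDataset, pop, n_permutations: int = 1000,
                         seed=None) -> dict:
    """Permutation significance of multilocus FIS for one population.

    Alleles are shuffled among individuals within the population at each
    locus independently (destroying within-individual correlation while
    preserving allele frequencies).  The p-value is the fraction of
    permuted multilocus f values >= the observed one (heterozygote-deficit
    test); the excess-side p is also reported.
    """
    rng = np.random.default_rng(seed)
    pi = ds.pop_position(pop) if isinstance(pop, str) else pop
    members = np.flatnonzero(ds.pop_index == pi)
    sub = ds.subset_individuals(members)

    def multilocus_f(geno):
        num = den = 0.0
        for li in range(sub.n_loci):
            comp = _fis_components(geno[:, li, :], sub.loci[li].n_alleles)
            if comp is None:
                continue
            sum_bc, sum_c = comp
            num += sum_c
            den += sum_bc
        return 1.0 - num / den if den > 0 else np.nan

    obs = multilocus_f(sub.genotypes)
    geq = leq = 0
    work = sub.genotypes.copy()
    for _ in range(n_permutations):
        for li in range(sub.n_loci):
            col = work[:, li, :]
            ok = col[:, 0] != MISSING
            copies = col[ok].ravel()
            rng.shuffle(copies)
            col[ok] = np.sort(copies.reshape(-1, 2), axis=1)
        f = multilocus_f(work)
        if not np.isnan(f):
            geq += f >= obs
            leq += f <= obs
    return {
        "fis": obs,
        "p_deficit": (geq + 1) / (n_permutations + 1),
        "p_excess": (leq + 1) / (n_permutations + 1),
        "n_permutations": n_permutations,
    }


def pic(freqs: AlleleFrequencyTable, pooled: bool = True) -> pd.Series:
    """Polymorphic information content per locus.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.  With ``pooled=True``
    (default) frequencies are pooled over populations first; otherwise the
    per-population PICs are averaged.
    """
    table = freqs.pooled() if pooled else freqs

    def _pic(p):
        s2 = np.sum(p ** 2)
        s4 = np.sum(p ** 4)
        cross = (s2 ** 2 - s4)  # sum_{i != j} p_i^2 p_j^2
        return 1.0 - s2 - cross

    L = len(freqs.loci)
    vals = np.zeros((table.freq.shape[0], L))
    for pi in range(table.freq.shape[0]):
        for li in range(L):
            vals[pi, li] = _pic(table.freq[pi, li])
    vals = np.where(table.undefined, np.nan, vals)
    out = np.nanmean(vals, axis=0)
    return pd.Series(out, index=[l.name for l in freqs.loci], name="PIC")


def diversity_summary(ds: GenotypeDataset, g: int | None = None,
                      fis_permutations: int = 0, seed=None) -> pd.DataFrame:
    """Population summary table: mean +- SD over loci of A, Ae, Ar, Ho, He, FIS.

    Mirrors the conventional per-population presentation of microsatellite
    survey tables.  With ``fis_permutations > 0`` a heterozygote-deficit
    p-value per population is appended.
    """
    freqs = allele_frequencies(ds)
    ho, he = heterozygosities(freqs, ds)
    ae = effective_alleles(freqs)
    a = allele_counts(freqs)
    ar = allelic_richness(ds, g)
    _, multi_f = fis(ds, freqs)

    rows = []
    for pi, pop in enumerate(ds.pop_names):
        row = {
            "population": pop,
            "group": ds.group_labels.get(pop),
            "n": int((ds.pop_index == pi).sum()),
        }
        for label, arr in (("A", a), ("Ae", ae), ("Ar", ar), ("Ho", ho), ("He", he)):
            row[label] = float(np.nanmean(arr[pi]))
            row[f"{label}_sd"] = float(np.nanstd(arr[pi], ddof=1))
        row["FIS"] = float(multi_f[pi])
        if fis_permutations > 0:
            res = fis_permutation_test(ds, pi, fis_permutations, seed=seed)
            row["FIS_p_deficit"] = res["p_deficit"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("population")


def allele_frequency_correlation(freqs: AlleleFrequencyTable, pop_a, pop_b) -> float:
    """Pearson correlation of allele frequencies between two samples.

    Utility for temporal-stability checks between adjacent sampling years.
    """
    ia = freqs.pop_names.index(pop_a) if isinstance(pop_a, str) else pop_a
    ib = freqs.pop_names.index(pop_b) if isinstance(pop_b, str) else pop_b
    xs, ys = [], []
    for li, locus in enumerate(freqs.loci):
        k = locus.n_alleles
        xs.append(freqs.freq[ia, li, :k])
        ys.append(freqs.freq[ib, li, :k])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return float(np.corrcoef(x, y)[0, 1])
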