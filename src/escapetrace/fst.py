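"""Population differentiation: Weir-Cockerham theta, ENA correction, Nei
distance, principal coordinates, and hierarchical AMOVA.

theta is estimated from the variance components a (among populations),
b (among individuals within populations) and c (within individuals),
summed over alleles and loci: theta = sum(a) / sum(a + b + c).  The ENA
("excluding null alleles") variant recomputes theta after replacing each
cell's raw allele frequencies with the EM-adjusted visible-allele
frequencies, which removes the upward bias that null alleles induce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, AlleleFrequencyTable, GenotypeDataset
from .nullalleles import null_allele_em

__all__ = [
    "FstResult",
    "AmovaResult",
    "weir_cockerham_fst",
    "pairwise_fst",
    "fst_ena",
    "nei_distance",
    "nei_distance_matrix",
    "pcoa",
    "amova",
]

NEI_INF_SENTINEL = float("inf")


@dataclass
class FstResult:
    theta: float
    per_locus: pd.DataFrame          # columns a, abc, theta per locus
    p_value: float | None = None
    permutations: int = 0
    ci95: tuple | None = None
    ena: bool = False


@dataclass
class AmovaResult:
    components: pd.Series            # sigma2 for among_groups / among_pops / within_pops
    percentages: pd.Series
    p_values: pd.Series | None = None
    permutations: int = 0


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

def _locus_components_from_summaries(n_i, p_ia, h_ia):
    """WC84 a, b, c summed over alleles for one locus.

    n_i: individuals per population (length r, all > 0);
    p_ia: (r, k) allele frequencies; h_ia: (r, k) frequency of heterozygous
    individuals carrying allele a.
    """
    n_i = np.asarray(n_i, dtype=float)
    r = n_i.size
    if r < 2:
        return 0.0, 0.0
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0
    nc = (r * nbar - np.sum(n_i ** 2) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return 0.0, 0.0
    w = n_i[:, None]
    pbar = np.sum(w * p_ia, axis=0) / (r * nbar)
    s2 = np.sum(w * (p_ia - pbar[None, :]) ** 2, axis=0) / ((r - 1) * nbar)
    hbar = np.sum(w * h_ia, axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    return float(np.sum(a)), float(np.sum(a + b + c))


def _locus_summaries(geno_col: np.ndarray, pop_index: np.ndarray, n_pops: int, k: int):
    """Per-population sample sizes, allele and heterozygote-carrier
    frequencies for one locus (populations with no data dropped)."""
    ok = geno_col[:, 0] != MISSING
    g = geno_col[ok]
    pops = pop_index[ok]
    n_i_full = np.bincount(pops, minlength=n_pops).astype(float)
    present = n_i_full > 0
    if present.sum() < 2:
        return None
    remap = -np.ones(n_pops, dtype=np.int64)
    remap[present] = np.arange(int(present.sum()))
    pp = remap[pops]
    r = int(present.sum())
    counts = np.zeros((r, k))
    np.add.at(counts, (np.repeat(pp, 2), g.ravel()), 1.0)
    n_i = n_i_full[present]
    p_ia = counts / (2 * n_i[:, None])
    het = g[:, 0] != g[:, 1]
    hc = np.zeros((r, k))
    np.add.at(hc, (pp[het], g[het, 0]), 1.0)
    np.add.at(hc, (pp[het], g[het, 1]), 1.0)
    h_ia = hc / n_i[:, None]
    return present, n_i, p_ia, h_ia


def _locus_components(geno_col: np.ndarray, pop_index: np.ndarray, n_pops: int, k: int):
    """Variance components for one locus from raw genotypes."""
    summ = _locus_summaries(geno_col, pop_index, n_pops, k)
    if summ is None:
        return 0.0, 0.0
    _, n_i, p_ia, h_ia = summ
    return _locus_components_from_summaries(n_i, p_ia, h_ia)


def _theta_from_dataset(ds: GenotypeDataset, pop_index=None):
    pop_index = ds.pop_index if pop_index is None else pop_index
    rows = []
    for li, locus in enumerate(ds.loci):
        a, abc = _locus_components(ds.genotypes[:, li, :], pop_index,
                                   ds.n_populations, locus.n_alleles)
        rows.append((locus.name, a, abc))
    per_locus = pd.DataFrame(rows, columns=["locus", "a", "abc"]).set_index("locus")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus["theta"] = per_locus["a"] / per_locus["abc"]
    denom = per_locus["abc"].sum()
    theta = per_locus["a"].sum() / denom if denom != 0 else float("nan")
    return theta, per_locus


def weir_cockerham_fst(ds: GenotypeDataset, pops=None, permutations: int = 1000,
                       seed=None) -> FstResult:
    """Global multilocus Weir-Cockerham theta over the active locus panel.

    Significance is assessed by shuffling individuals among populations
    (``permutations`` replicates): p = fraction of permuted datasets with
    theta >= the observed value.  Set ``permutations=0`` to skip.
    """
    work = ds.active_view()
    if pops is not None:
        work = work.subset_populations(list(pops))
    if work.n_populations < 2:
        raise ValueError("need at least two populations")
    theta, per_locus = _theta_from_dataset(work)
    if math.isnan(theta):
        return FstResult(theta, per_locus)
    p_value = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(work.pop_index)
            t, _ = _theta_from_dataset(work, pop_index=perm)
            if t >= theta:
                hits += 1
        p_value = (hits + 1) / (permutations + 1)
    return FstResult(theta, per_locus, p_value, permutations)


def pairwise_fst(ds: GenotypeDataset, permutations: int = 0, seed=None) -> pd.DataFrame:
    """Pairwise theta matrix over all population pairs.

    Negative estimates are reported as-is (not truncated to zero).  With
    ``permutations > 0`` a parallel matrix of permutation p-values is
    attached as ``.attrs['p_values']``.  The number of pairs evaluated is
    recorded in ``.attrs['n_pairs']``.
    """
    work = ds.active_view()
    P = work.n_populations
    mat = np.zeros((P, P))
    pmat = np.full((P, P), np.nan)
    rng = np.random.default_rng(seed)
    n_pairs = 0
    for i in range(P):
        for j in range(i + 1, P):
            n_pairs += 1
            sub = work.subset_populations([work.pop_names[i], work.pop_names[j]])
            res = weir_cockerham_fst(
                sub, permutations=permutations,
                seed=int(rng.integers(2 ** 31)) if permutations else None,
            )
            mat[i, j] = mat[j, i] = res.theta
            if permutations:
                pmat[i, j] = pmat[j, i] = res.p_value
    out = pd.DataFrame(mat, index=work.pop_names, columns=work.pop_names)
    out.attrs["n_pairs"] = n_pairs
    if permutations:
        out.attrs["p_values"] = pd.DataFrame(pmat, index=work.pop_names,
                                             columns=work.pop_names)
    return out


def fst_ena(ds: GenotypeDataset, null_estimates: dict | None = None,
            bootstrap_reps: int = 50000, seed=None) -> FstResult:
    """Theta recomputed with null-adjusted allele frequencies (ENA), with a
    percentile bootstrap 95% CI over loci.

    ``null_estimates`` maps (population, locus) name pairs to
    NullAlleleEstimate; when omitted the EM is run for every cell.  Each
    cell's frequency vector is replaced by the EM visible-allele
    frequencies left on the full-allele-set scale (they sum to 1 - r): the
    null allele's mass is excluded from the per-allele variance components
    rather than redistributed, which undoes the inflation that
    renormalizing over visible alleles introduces when the null frequency
    drifts between populations.  Observed heterozygote frequencies are
    kept (visible-visible heterozygotes are scored correctly even with
    nulls).  When every estimated null frequency is zero the EM
    frequencies equal the raw counts, so ENA theta equals plain theta
    exactly.
    """
    work = ds.active_view()
    rows = []
    for li, locus in enumerate(work.loci):
        k = locus.n_alleles
        summ = _locus_summaries(work.genotypes[:, li, :], work.pop_index,
                                work.n_populations, k)
        if summ is None:
            rows.append((locus.name, 0.0, 0.0))
            continue
        present, n_i, p_ia, h_ia = summ
        present_pops = [work.pop_names[pi] for pi in np.flatnonzero(present)]
        for row_i, pop in enumerate(present_pops):
            if null_estimates is not None and (pop, locus.name) in null_estimates:
                est = null_estimates[(pop, locus.name)]
            else:
                est = null_allele_em(work, pop, locus.name)
            p = np.asarray(est.visible_freqs, dtype=float)
            if p.size < k:
                p = np.pad(p, (0, k - p.size))
            p_ia[row_i] = p
        a, abc = _locus_components_from_summaries(n_i, p_ia, h_ia)
        rows.append((locus.name, a, abc))
    per_locus = pd.DataFrame(rows, columns=["locus", "a", "abc"]).set_index("locus")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus["theta"] = per_locus["a"] / per_locus["abc"]
    theta = per_locus["a"].sum() / per_locus["abc"].sum()
    ci = None
    if len(per_locus) >= 3 and bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        L = len(per_locus)
        idx = rng.integers(0, L, size=(bootstrap_reps, L))
        a_arr = per_locus["a"].to_numpy()
        abc_arr = per_locus["abc"].to_numpy()
        num = a_arr[idx].sum(axis=1)
        den = abc_arr[idx].sum(axis=1)
        boot = num[den != 0] / den[den != 0]
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return FstResult(float(theta), per_locus, ci95=ci, ena=True)


# ---------------------------------------------------------------------------
# Nei distance and PCoA
# ---------------------------------------------------------------------------

def nei_distance(freqs: AlleleFrequencyTable, pop_a, pop_b) -> float:
    """Nei's (1972) standard genetic distance between two populations.

    D = -ln( Jxy / sqrt(Jx * Jy) ) with the identity sums averaged over
    loci.  Fully disjoint allele sets give +inf (flagged sentinel).
    """
    ia = freqs.pop_names.index(pop_a) if isinstance(pop_a, str) else pop_a
    ib = freqs.pop_names.index(pop_b) if isinstance(pop_b, str) else pop_b
    jx = jy = jxy = 0.0
    L = len(freqs.loci)
    for li, locus in enumerate(freqs.loci):
        k = locus.n_alleles
        x = freqs.freq[ia, li, :k]
        y = freqs.freq[ib, li, :k]
        jx += float(np.sum(x * x))
        jy += float(np.sum(y * y))
        jxy += float(np.sum(x * y))
    if jxy == 0:
        return NEI_INF_SENTINEL
    ident = (jxy / L) / math.sqrt((jx / L) * (jy / L))
    return max(0.0, -math.log(ident))


def nei_distance_matrix(freqs: AlleleFrequencyTable) -> pd.DataFrame:
    P = len(freqs.pop_names)
    mat = np.zeros((P, P))
    flags = np.zeros((P, P), dtype=bool)
    for i in range(P):
        for j in range(i + 1, P):
            d = nei_distance(freqs, i, j)
            if math.isinf(d):
                flags[i, j] = flags[j, i] = True
            mat[i, j] = mat[j, i] = d
    out = pd.DataFrame(mat, index=freqs.pop_names, columns=freqs.pop_names)
    out.attrs["infinite"] = flags
    return out


def pcoa(distance_matrix) -> dict:
    """Classical multidimensional scaling (principal coordinates analysis).

    Double-centres -D^2/2 and eigendecomposes.  Returns coordinates for
    axes with positive eigenvalues, the full eigenvalue spectrum (negative
    eigenvalues are reported, not dropped) and explained-variance
    fractions over the positive part.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        D = distance_matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(distance_matrix, dtype=float)
        labels = list(range(D.shape[0]))
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.isfinite(D).all():
        raise ValueError("distance matrix contains non-finite entries "
                         "(infinite Nei distances must be resolved first)")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > 1e-12
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    explained = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    coord_df = pd.DataFrame(coords, index=labels,
                            columns=[f"PCo{i+1}" for i in range(coords.shape[1])])
    return {"coordinates": coord_df, "eigenvalues": eigvals, "explained": explained}


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _amova_components(ds: GenotypeDataset, group_of_pop: np.ndarray, n_groups: int,
                      pop_index=None):
    """Summed (over loci) variance components of the three-level AMOVA."""
    pop_index = ds.pop_index if pop_index is None else pop_index
    sig_a = sig_b = sig_c = 0.0
    for li, locus in enumerate(ds.loci):
        col = ds.genotypes[:, li, :]
        ok = col[:, 0] != MISSING
        g = col[ok]
        pops = pop_index[ok]
        groups = group_of_pop[pops]
        copies_pop = np.repeat(pops, 2)
        copies_group = np.repeat(groups, 2)
        alleles = g.ravel()
        k = locus.n_alleles
        P = ds.n_populations
        G = n_groups
        N = alleles.size
        if N == 0:
            continue

        def ss(labels, n_labels):
            cnt = np.zeros((n_labels, k))
            np.add.at(cnt, (labels, alleles), 1.0)
            sizes = cnt.sum(axis=1)
            nz = sizes > 0
            val = float(np.sum((sizes[nz] - (cnt[nz] ** 2).sum(axis=1) / sizes[nz]) / 2.0))
            return val, sizes

        ss_tot, _ = ss(np.zeros(N, dtype=np.int64), 1)
        ss_wg, g_sizes = ss(copies_group, G)
        ss_wp, p_sizes = ss(copies_pop, P)
        ssd_ag = ss_tot - ss_wg
        ssd_ap = ss_wg - ss_wp
        ssd_wp = ss_wp

        Pn = int((p_sizes > 0).sum())
        Gn = int((g_sizes > 0).sum())
        if Gn < 2 or Pn <= Gn:
            df_wp = N - Pn
            if df_wp > 0:
                sig_c += ssd_wp / df_wp
            continue
        df_ag, df_ap, df_wp = Gn - 1, Pn - Gn, N - Pn
        sum_np2_over_ng = 0.0
        for gi in range(G):
            if g_sizes[gi] > 0:
                npg = p_sizes[group_of_pop == gi]
                sum_np2_over_ng += float(np.sum(npg ** 2)) / g_sizes[gi]
        sum_np2_over_n = float(np.sum(p_sizes ** 2)) / N
        sum_ng2_over_n = float(np.sum(g_sizes ** 2)) / N
        n1 = (N - sum_np2_over_ng) / df_ap
        n2 = (sum_np2_over_ng - sum_np2_over_n) / df_ag
        n3 = (N - sum_ng2_over_n) / df_ag

        ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
        ms_ap = ssd_ap / df_ap
        ms_ag = ssd_ag / df_ag
        c = ms_wp
        b = (ms_ap - c) / n1 if n1 > 0 else 0.0
        a = (ms_ag - c - n2 * b) / n3 if n3 > 0 else 0.0
        sig_a += a
        sig_b += b
        sig_c += c
    return sig_a, sig_b, sig_c


def amova(ds: GenotypeDataset, grouping: dict, permutations: int = 20000,
          seed=None) -> AmovaResult:
    """Hierarchical analysis of molecular variance (groups / populations /
    individuals) from allele-identity sums of squares.

    ``grouping`` maps population name -> group label.  Percentages are the
    variance components floored at zero and normalized to 100 (the
    conventional presentation; the raw, possibly negative, components are
    returned unchanged).  Permutation p-values: among-groups by permuting
    populations among groups; among-populations-within-groups by permuting
    individuals among populations within their group; total population
    differentiation by permuting individuals among all populations.
    """
    work = ds.active_view()
    group_names = sorted(set(grouping.values()))
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    gidx = {name: i for i, name in enumerate(group_names)}
    group_of_pop = np.array([gidx[grouping[p]] for p in work.pop_names])
    G = len(group_names)

    sa, sb, sc = _amova_components(work, group_of_pop, G)
    comps = pd.Series({"among_groups": sa, "among_pops_within_groups": sb,
                       "within_pops": sc})
    clipped = comps.clip(lower=0.0)
    pct = 100.0 * clipped / clipped.sum()

    p_values = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        hits = pd.Series(0.0, index=comps.index)
        ind_group = group_of_pop[work.pop_index]
        for _ in range(permutations):
            perm_gop = rng.permutation(group_of_pop)
            a1, _, _ = _amova_components(work, perm_gop, G)
            if a1 >= sa:
                hits["among_groups"] += 1
            perm_pops = work.pop_index.copy()
            for gi in range(G):
                sel = np.flatnonzero(ind_group == gi)
                perm_pops[sel] = rng.permutation(perm_pops[sel])
            _, b2, _ = _amova_components(work, group_of_pop, G, pop_index=perm_pops)
            if b2 >= sb:
                hits["among_pops_within_groups"] += 1
            a3, b3, _ = _amova_components(work, group_of_pop, G,
                                          pop_index=rng.permutation(work.pop_index))
            if (a3 + b3) >= (sa + sb):
                hits["within_pops"] += 1
        p_values = (hits + 1) / (permutations + 1)
    return AmovaResult(comps, pct, p_values, permutations)
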