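"""Maximum-likelihood admixture model (EM analogue of the Structure model).

Each individual i carries a membership vector q_i over K clusters and each
cluster k carries allele frequencies P_kla; every allele copy is drawn by
first choosing an ancestry cluster from q_i and then an allele from that
cluster's frequencies.  The likelihood

    L = prod_i prod_l prod_{copies c} sum_k q_ik P_{k,l,a(i,l,c)}

is maximized by EM block updates on q and P.  This is the same likelihood
Structure samples from; point estimation replaces the MCMC, so replicate
maximized log-likelihoods stand in for lnP(D) in the Evanno delta-K rule.
For choosing K programmatically (e.g. in the hierarchical recursion) a
held-out-copies cross-validation score is used, which - unlike delta-K -
can select K = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .dataset import MISSING, GenotypeDataset

__all__ = [
    "AdmixtureFit",
    "DEFAULT_MEMBERSHIP_ALPHA",
    "fit_admixture",
    "fit_replicates",
    "delta_k",
    "align_labels",
    "select_k",
    "cross_validation_scores",
    "posterior_mean_q2",
    "plot_admixture_bars",
    "hierarchical_structure",
    "StructureNode",
]

_P_FLOOR = 1e-12

# Beta/Dirichlet concentration of the membership prior used by the
# posterior-mean q of the hybrid-detection pipeline; the sampler-based
# admixture model infers a small alpha on strongly structured data, which
# concentrates pure individuals' q near the simplex corners
DEFAULT_MEMBERSHIP_ALPHA = 0.2


@dataclass
class AdmixtureFit:
    K: int
    q: np.ndarray                    # (n, K) membership simplex rows
    P: list                          # per locus (K, k_l) cluster allele freqs
    log_likelihood: float
    seed: int | None
    iterations: int
    converged: bool
    degenerate: bool = False
    loglik_trace: list = field(default_factory=list)

    def modal_cluster(self) -> np.ndarray:
        return np.argmax(self.q, axis=1)

    def n_parameters(self, n_individuals: int) -> int:
        freq_params = self.K * sum(p.shape[1] - 1 for p in self.P)
        return freq_params + n_individuals * (self.K - 1)


def _flatten(ds: GenotypeDataset):
    """Stack all non-missing allele copies into gather arrays.

    Returns (ind_idx, allele_idx, offsets, k_sizes): ``allele_idx`` indexes
    columns of a (K, total_alleles) stacked frequency matrix with one block
    per locus.
    """
    L = ds.n_loci
    k_sizes = [loc.n_alleles for loc in ds.loci]
    offsets = np.concatenate([[0], np.cumsum(k_sizes)])
    ind_parts, allele_parts = [], []
    for li in range(L):
        g = ds.genotypes[:, li, :]
        m = g[:, 0] != MISSING
        idx = np.flatnonzero(m)
        ind_parts.append(np.repeat(idx, 2))
        allele_parts.append(g[m].ravel().astype(np.int64) + offsets[li])
    return (np.concatenate(ind_parts), np.concatenate(allele_parts),
            offsets, k_sizes)


def _em(ind_idx, allele_idx, n, K, offsets, k_sizes, rng, tol, max_iter,
        fixed=None, freq_prior: float = 0.0, alpha: float = 1.0):
    """Core EM on a copy table; returns (q, P, loglik, iters, converged, trace).

    ``freq_prior`` adds a Dirichlet pseudocount per allele to the frequency
    update (MAP-EM under the flat-ish prior the Bayesian model uses);
    ``alpha`` is the Dirichlet concentration of the membership prior
    (alpha < 1 sparsifies q, zeroing spurious minor memberships of pure
    individuals, as the sampler-based model does with its inferred small
    alpha).  With freq_prior = 0 and alpha = 1 the updates are pure
    maximum likelihood and the log-likelihood trace is guaranteed
    non-decreasing.
    """
    total_alleles = int(offsets[-1])
    L = len(k_sizes)
    copies_per_ind = np.bincount(ind_idx, minlength=n).astype(float)
    q = rng.dirichlet(np.ones(K), size=n) if K > 1 else np.ones((n, 1))
    is_fixed = None
    if fixed is not None:
        is_fixed = fixed >= 0
        q[is_fixed] = np.eye(K)[fixed[is_fixed]]
    pooled = np.bincount(allele_idx, minlength=total_alleles).astype(float)
    P = np.empty((K, total_alleles))
    for li in range(L):
        sl = slice(offsets[li], offsets[li + 1])
        base = pooled[sl] / max(pooled[sl].sum(), 1.0)
        noise = rng.dirichlet(np.ones(k_sizes[li]), size=K)
        pk = 0.8 * base[None, :] + 0.2 * noise
        P[:, sl] = pk / pk.sum(axis=1, keepdims=True)

    def renormalize(mat):
        mat = np.maximum(mat, _P_FLOOR)
        for li in range(L):
            sl = slice(offsets[li], offsets[li + 1])
            mat[:, sl] /= mat[:, sl].sum(axis=1, keepdims=True)
        return mat

    prev_ll = -np.inf
    trace = []
    converged = False
    it = 0
    untyped = copies_per_ind == 0
    for it in range(1, max_iter + 1):
        w = q[ind_idx] * P[:, allele_idx].T          # (M, K)
        denom = w.sum(axis=1)
        ll = float(np.log(np.maximum(denom, 1e-300)).sum())
        z = w / np.maximum(denom[:, None], 1e-300)
        trace.append(ll)
        q_num = np.zeros((n, K))
        np.add.at(q_num, ind_idx, z)
        if alpha != 1.0:
            q_num = np.maximum(q_num + (alpha - 1.0), 0.0)
        denom_q = q_num.sum(axis=1, keepdims=True)
        q = np.where(denom_q > 0, q_num / np.maximum(denom_q, 1e-300), 1.0 / K)
        q[untyped] = 1.0 / K
        if is_fixed is not None and is_fixed.any():
            q[is_fixed] = np.eye(K)[fixed[is_fixed]]
        P_num = np.zeros((total_alleles, K))
        np.add.at(P_num, allele_idx, z)
        P = renormalize(P_num.T + freq_prior)
        if ll - prev_ll < tol and it > 1:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return q, P, float(prev_ll), it, converged, trace


def fit_admixture(ds: GenotypeDataset, K: int, seed=None, tol: float = 1e-4,
                  max_iter: int = 500, supervised_sources: dict | None = None,
                  alpha: float = 1.0, freq_prior: float = 0.0) -> AdmixtureFit:
    """Fit the K-cluster admixture model by EM.

    ``supervised_sources`` maps population name -> cluster index; individuals
    of those populations have q fixed to pure membership of that cluster
    (they anchor the cluster frequencies), all others are estimated freely.
    The EM log-likelihood is non-decreasing per iteration; convergence is
    declared when the improvement drops below ``tol`` (log-likelihood
    units).
    """
    n = ds.n_individuals
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError("K exceeds the number of individuals")
    rng = np.random.default_rng(seed)
    ind_idx, allele_idx, offsets, k_sizes = _flatten(ds)
    if np.bincount(ind_idx, minlength=n).min() == 0:
        raise ValueError("individual with no typed loci")
    fixed = None
    if supervised_sources:
        fixed = np.full(n, -1, dtype=np.int64)
        for pop, cl in supervised_sources.items():
            if not 0 <= cl < K:
                raise ValueError("supervised cluster index out of range")
            fixed[ds.pop_index == ds.pop_position(pop)] = cl
    q, P, ll, it, converged, trace = _em(ind_idx, allele_idx, n, K, offsets,
                                         k_sizes, rng, tol, max_iter, fixed,
                                         freq_prior=freq_prior, alpha=alpha)
    degenerate = bool(K > 1 and np.any(q.max(axis=0) < 0.01))
    L = ds.n_loci
    P_list = [P[:, offsets[li]:offsets[li + 1]].copy() for li in range(L)]
    return AdmixtureFit(K, q, P_list, ll, seed, it, converged, degenerate, trace)


def fit_replicates(ds: GenotypeDataset, k_values, replicates: int = 10, seed=None,
                   **kwargs) -> dict:
    """Replicate fits per K with distinct seeds; returns {K: [fits]}."""
    rng = np.random.default_rng(seed)
    out = {}
    for K in k_values:
        out[K] = [
            fit_admixture(ds, K, seed=int(rng.integers(2 ** 31)), **kwargs)
            for _ in range(replicates)
        ]
    return out


def best_fit(fits_by_k: dict, K: int) -> AdmixtureFit:
    return max(fits_by_k[K], key=lambda f: f.log_likelihood)


def delta_k(fits_by_k: dict) -> pd.DataFrame:
    """Evanno's delta-K table over replicate log-likelihoods.

    delta K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / SD(L(K)),
    defined for interior K only; the selected K (``.attrs['selected_K']``)
    is the argmax of delta K over the K where it is defined.  Zero-SD rows
    are excluded with a warning note in the table.
    """
    ks = sorted(fits_by_k)
    if len(ks) < 3 or any(len(fits_by_k[k]) < 1 for k in ks):
        raise ValueError("need at least three consecutive K values")
    means = {k: float(np.mean([f.log_likelihood for f in fits_by_k[k]])) for k in ks}
    sds = {k: float(np.std([f.log_likelihood for f in fits_by_k[k]], ddof=1))
           if len(fits_by_k[k]) > 1 else 0.0 for k in ks}
    rows = []
    for i, k in enumerate(ks):
        dk = np.nan
        note = ""
        if 0 < i < len(ks) - 1:
            if ks[i - 1] == k - 1 and ks[i + 1] == k + 1:
                second = abs(means[k + 1] - 2 * means[k] + means[k - 1])
                if sds[k] > 0:
                    dk = second / sds[k]
                else:
                    note = "zero SD; delta K undefined"
        rows.append({"K": k, "mean_lnL": means[k], "sd_lnL": sds[k],
                     "delta_K": dk, "note": note})
    table = pd.DataFrame(rows).set_index("K")
    defined = table["delta_K"].dropna()
    table.attrs["selected_K"] = int(defined.idxmax()) if len(defined) else None
    return table


def align_labels(fits: list) -> tuple:
    """Align cluster labels of replicate fits at one K to the first replicate.

    Cluster permutations are matched by maximizing the summed correlation
    between q columns (optimal assignment).  Returns (aligned fits, mean q).
    """
    if len({f.K for f in fits}) != 1:
        raise ValueError("replicates must share K")
    ref = fits[0]
    K = ref.K
    aligned = [ref]
    for f in fits[1:]:
        if K == 1:
            aligned.append(f)
            continue
        corr = np.zeros((K, K))
        for i in range(K):
            for j in range(K):
                ci = np.corrcoef(ref.q[:, i], f.q[:, j])[0, 1]
                corr[i, j] = 0.0 if np.isnan(ci) else ci
        _, perm = linear_sum_assignment(-corr)
        aligned.append(AdmixtureFit(
            K, f.q[:, perm], [p[perm] for p in f.P], f.log_likelihood,
            f.seed, f.iterations, f.converged, f.degenerate, f.loglik_trace,
        ))
    mean_q = np.mean([f.q for f in aligned], axis=0)
    mean_q = mean_q / mean_q.sum(axis=1, keepdims=True)
    return aligned, mean_q


def cross_validation_scores(ds: GenotypeDataset, k_values, holdout: float = 0.15,
                            restarts: int = 2, seed=None, tol: float = 1e-4,
                            max_iter: int = 300) -> dict:
    """Held-out log-likelihood per K.

    A random ``holdout`` fraction of allele copies is masked once (shared
    across K); the model is fitted on the remainder (best of ``restarts``
    by training likelihood) and scored by the mean log-probability of the
    held-out copies under the fitted q and P.  Overfitted K drop in
    held-out score, and K = 1 is selectable.
    """
    rng = np.random.default_rng(seed)
    n = ds.n_individuals
    ind_idx, allele_idx, offsets, k_sizes = _flatten(ds)
    M = ind_idx.size
    held = np.zeros(M, dtype=bool)
    # hold out copies while keeping every individual in training
    order = rng.permutation(M)
    target = int(holdout * M)
    counts = np.bincount(ind_idx, minlength=n)
    taken = np.zeros(n, dtype=np.int64)
    chosen = 0
    for pos in order:
        if chosen >= target:
            break
        i = ind_idx[pos]
        if counts[i] - taken[i] > 2:   # keep at least one typed locus
            held[pos] = True
            taken[i] += 1
            chosen += 1
    scores = {}
    for K in k_values:
        best = None
        for _ in range(max(restarts, 1)):
            q, P, ll, *_ = _em(ind_idx[~held], allele_idx[~held], n, K, offsets,
                               k_sizes, rng, tol, max_iter, freq_prior=0.5)
            if best is None or ll > best[0]:
                best = (ll, q, P)
        _, q, P = best
        probs = np.sum(q[ind_idx[held]] * P[:, allele_idx[held]].T, axis=1)
        scores[K] = float(np.mean(np.log(np.maximum(probs, 1e-300))))
    return scores


def select_k(fits_by_k: dict, ds: GenotypeDataset, seed=None) -> int:
    """Choose the number of clusters by held-out cross-validation.

    The replicate fits supply the K range; the decision comes from
    ``cross_validation_scores`` (delta-K is reported separately via
    ``delta_k`` but cannot select K = 1 and is noisy for point-estimated
    likelihoods, so the held-out score is the programmatic criterion).
    """
    ks = sorted(fits_by_k)
    scores = cross_validation_scores(ds, ks, seed=seed)
    return max(sorted(scores), key=lambda k: scores[k])


def posterior_mean_q2(ds: GenotypeDataset, fit: AdmixtureFit, cluster: int = 1,
                      alpha: float = DEFAULT_MEMBERSHIP_ALPHA,
                      n_grid: int = 201) -> np.ndarray:
    """Bayesian posterior mean of the two-cluster membership coefficient.

    With the cluster frequencies fixed at the fitted values, each
    individual's posterior over q (its ancestry fraction from ``cluster``)
    under a Beta(alpha, alpha) prior is integrated on a grid:

        p(q | g) ~ q^(alpha-1) (1-q)^(alpha-1) prod_copies [q P_c + (1-q) P_o]

    The posterior mean reproduces the behaviour of the sampler-based
    admixture model: pure individuals concentrate near the corners without
    the boundary collapse a MAP point estimate with alpha < 1 suffers,
    while genuinely admixed individuals stay near their ancestry fraction.
    Only defined for K = 2 fits.
    """
    if fit.K != 2:
        raise ValueError("posterior_mean_q2 requires a K = 2 fit")
    ind_idx, allele_idx, offsets, _k = _flatten(ds)
    P = np.concatenate([p.T for p in fit.P])       # (total_alleles, 2)
    pc = np.maximum(P[allele_idx, cluster], 1e-12)
    po = np.maximum(P[allele_idx, 1 - cluster], 1e-12)
    # interior grid (open interval; the alpha-1 < 0 prior is integrable)
    q = (np.arange(1, n_grid + 1) - 0.5) / n_grid
    log_prior = (alpha - 1.0) * (np.log(q) + np.log(1.0 - q))
    n = ds.n_individuals
    loglik = np.zeros((n, n_grid))
    # accumulate per-copy log(q pc + (1-q) po) into each individual's row
    for j, qj in enumerate(q):
        contrib = np.log(qj * pc + (1.0 - qj) * po)
        loglik[:, j] = np.bincount(ind_idx, weights=contrib, minlength=n)
    logpost = loglik + log_prior[None, :]
    logpost -= logpost.max(axis=1, keepdims=True)
    w = np.exp(logpost)
    w /= w.sum(axis=1, keepdims=True)
    return w @ q


def plot_admixture_bars(fit: AdmixtureFit, ds: GenotypeDataset, ax=None,
                        sort_within_pop: bool = True):
    """Stacked membership bar plot (one vertical bar per individual,
    populations separated by black lines), the conventional admixture
    visualization.  Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(max(6, ds.n_individuals / 40), 2.5))
    order = []
    boundaries = []
    for pi in range(ds.n_populations):
        members = np.flatnonzero(ds.pop_index == pi)
        if sort_within_pop and len(members):
            members = members[np.argsort(-fit.q[members, :].max(axis=1))]
        order.extend(members.tolist())
        boundaries.append(len(order))
    q = fit.q[order]
    bottom = np.zeros(len(order))
    x = np.arange(len(order))
    for k in range(fit.K):
        ax.bar(x, q[:, k], bottom=bottom, width=1.0)
        bottom += q[:, k]
    for b in boundaries[:-1]:
        ax.axvline(b - 0.5, color="black", linewidth=0.8)
    ax.set_xlim(-0.5, len(order) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("membership q")
    ax.set_xticks([])
    return ax


@dataclass
class StructureNode:
    """One node of the hierarchical clustering tree."""
    individuals: np.ndarray
    selected_K: int
    fit: AdmixtureFit | None
    children: list = field(default_factory=list)
    note: str = ""

    def leaves(self) -> list:
        if not self.children:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


def hierarchical_structure(ds: GenotypeDataset, max_depth: int = 4,
                           replicates: int = 5, min_subset: int = 10,
                           assignment_threshold: float = 0.5, seed=None,
                           k_cap: int = 8) -> StructureNode:
    """Successive clustering of modal-cluster subsets.

    At each node the admixture model is fitted for K = 1..min(number of
    source populations in the subset, ``k_cap``); individuals are assigned
    to their modal cluster when its q exceeds ``assignment_threshold`` and
    each cluster subset is re-analysed, until the selected K is 1, the
    subset spans a single locality, or the subset is smaller than
    ``min_subset``.
    """
    rng = np.random.default_rng(seed)

    def analyse(indices: np.ndarray, depth: int) -> StructureNode:
        sub = ds.subset_individuals(indices)
        n_local = len(set(sub.pop_index.tolist()))
        if n_local <= 1:
            return StructureNode(indices, 1, None, note="single locality")
        if len(indices) < min_subset:
            return StructureNode(indices, 1, None, note="subset too small")
        kmax = min(n_local, k_cap)
        fits = fit_replicates(sub, range(1, kmax + 1), replicates=replicates,
                              seed=int(rng.integers(2 ** 31)))
        k_sel = select_k(fits, sub, seed=int(rng.integers(2 ** 31)))
        node = StructureNode(indices, k_sel, best_fit(fits, k_sel) if k_sel else None)
        if k_sel <= 1 or depth >= max_depth:
            return node
        modal = node.fit.modal_cluster()
        qmax = node.fit.q.max(axis=1)
        for cl in range(k_sel):
            members = indices[(modal == cl) & (qmax >= assignment_threshold)]
            if len(members) == 0:
                continue
            node.children.append(analyse(members, depth + 1))
        return node

    return analyse(np.arange(ds.n_individuals), 0)
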