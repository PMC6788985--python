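"""EM estimation of null-allele frequencies and the locus QC rule.

A null allele is a microsatellite allele that fails to amplify: carriers of
one null copy appear as homozygotes for their visible allele, and null
homozygotes appear as missing data.  Under Hardy-Weinberg proportions with
one unobservable null allele at frequency r, the apparent homozygote count
for visible allele i mixes true i/i genotypes (p_i^2) and i/null
heterozygotes (2 p_i r).  The EM algorithm below maximizes the likelihood
of the observed (non-missing) genotype classes, conditioning on a genotype
being visible (null/null individuals are truncated, matching the choice of
excluding missing calls from the likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

__all__ = ["NullAlleleEstimate", "null_allele_em", "null_allele_table", "locus_qc"]


@dataclass
class NullAlleleEstimate:
    r: float
    visible_freqs: np.ndarray       # over the locus's allele list; sums to 1 - r
    iterations: int
    converged: bool
    log_likelihood: float
    loglik_trace: list = field(default_factory=list)
    no_homozygote_excess: bool = False


def _cell_counts(ds: GenotypeDataset, pop, locus):
    pi = ds.pop_position(pop) if isinstance(pop, str) else pop
    li = ds.locus_position(locus) if isinstance(locus, str) else locus
    g = ds.genotypes[ds.pop_index == pi, li, :]
    g = g[g[:, 0] != MISSING]
    k = ds.loci[li].n_alleles
    homo = np.zeros(k)
    het = np.zeros((k, k))
    hom_mask = g[:, 0] == g[:, 1]
    np.add.at(homo, g[hom_mask, 0], 1.0)
    hh = g[~hom_mask]
    np.add.at(het, (hh[:, 0], hh[:, 1]), 1.0)
    return homo, het, k


def null_allele_em(ds: GenotypeDataset, pop, locus, tol: float = 1e-8,
                   max_iter: int = 10000) -> NullAlleleEstimate:
    """Estimate the null-allele frequency r for one (population, locus) cell.

    Returns the fitted r together with the EM-adjusted visible-allele
    frequencies (these sum to 1 - r).  The observed-data log-likelihood is
    tracked per iteration and is non-decreasing; convergence is declared
    when the largest frequency change drops below ``tol``.
    """
    homo, het, k = _cell_counts(ds, pop, locus)
    n_obs = homo.sum() + het.sum()
    if n_obs == 0:
        raise ValueError("empty cell")
    if homo.sum() == 0:
        # no homozygote class at all: heterozygote excess, r -> 0
        counts = het.sum(axis=0) + het.sum(axis=1)
        p = counts / counts.sum()
        return NullAlleleEstimate(0.0, p, 0, True, _loglik(homo, het, p, 0.0),
                                  no_homozygote_excess=True)

    # initialize from raw counts with a small null mass
    counts = 2 * homo + het.sum(axis=0) + het.sum(axis=1)
    p = counts / counts.sum()
    r = 0.05
    p = p * (1 - r)
    trace = []
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split apparent homozygotes; impute truncated null/null mass
        denom = p + 2 * r
        with np.errstate(invalid="ignore", divide="ignore"):
            w_true = np.where(denom > 0, p / denom, 1.0)  # share that is true i/i
        exp_nullnull = n_obs * r * r / (1.0 - r * r) if r > 0 else 0.0
        # M-step: expected allele-copy counts
        vis = 2 * homo * w_true + homo * (1 - w_true) + het.sum(axis=0) + het.sum(axis=1)
        null_copies = float(np.sum(homo * (1 - w_true))) + 2 * exp_nullnull
        total = vis.sum() + null_copies
        p_new = vis / total
        r_new = null_copies / total
        delta = max(float(np.max(np.abs(p_new - p))), abs(r_new - r))
        p, r = p_new, float(r_new)
        trace.append(_loglik(homo, het, p, r))
        if delta < tol:
            break
    converged = delta < tol
    return NullAlleleEstimate(r, p, it, converged, trace[-1], trace,
                              no_homozygote_excess=(r < 1e-4))


def _loglik(homo, het, p, r):
    """Observed-data log-likelihood, conditioned on visibility (no null/null)."""
    norm = 1.0 - r * r
    ll = 0.0
    prob_homo = (p * p + 2 * p * r) / norm
    nz = homo > 0
    ll += float(np.sum(homo[nz] * np.log(np.maximum(prob_homo[nz], 1e-300))))
    idx = np.argwhere(het > 0)
    for i, j in idx:
        ll += het[i, j] * np.log(max(2 * p[i] * p[j] / norm, 1e-300))
    return ll


def null_allele_table(ds: GenotypeDataset, tol: float = 1e-8,
                      max_iter: int = 10000) -> pd.DataFrame:
    """Null-allele EM estimates for every (population, locus) cell."""
    rows = []
    for pop in ds.pop_names:
        for locus in ds.locus_names:
            try:
                est = null_allele_em(ds, pop, locus, tol=tol, max_iter=max_iter)
                rows.append({"population": pop, "locus": locus, "r": est.r,
                             "iterations": est.iterations, "converged": est.converged})
            except ValueError:
                rows.append({"population": pop, "locus": locus, "r": np.nan,
                             "iterations": 0, "converged": False})
    return pd.DataFrame(rows)


def locus_qc(estimates: pd.DataFrame, drop_threshold: float = 0.1) -> pd.DataFrame:
    """Flag loci whose mean null frequency across populations reaches the threshold.

    The default 0.1 sits between the conventional retain (<0.08) and drop
    (up to ~0.3) regimes for microsatellite panels.  Returns a per-locus
    table with ``mean_r`` and a ``drop`` flag; the retained panel is
    ``table.index[~table.drop]``.
    """
    mean_r = estimates.groupby("locus", sort=False)["r"].mean()
    out = pd.DataFrame({"mean_r": mean_r})
    out["drop"] = out["mean_r"] >= drop_threshold
    return out


def apply_locus_qc(ds: GenotypeDataset, qc: pd.DataFrame) -> GenotypeDataset:
    """Set the dataset's active panel to the QC-retained loci."""
    keep = [name for name in ds.locus_names if not bool(qc.loc[name, "drop"])]
    ds.active_loci = keep
    return ds
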