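"""Synthetic genotype scenarios with known ground truth.

The generator emulates the statistical structure of a coastal
microsatellite survey of wild and farmed gilthead seabream: a panel of
highly polymorphic loci (7-14 alleles, expected heterozygosity near 0.8),
hierarchically structured samples (a wild migratory pool, a farm-
associated/nursery resident pool, and several farmed hatchery strains with
bottlenecked diversity), planted farm escapees, F1 hybrids,
parent-offspring trios, null alleles, and random missingness.

Population allele frequencies follow the Balding-Nichols model: a
population at divergence F from ancestral frequencies p has frequencies
drawn from Dirichlet(p (1-F)/F), so the target FST is controlled directly
- the quantity every downstream estimator consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, Locus

__all__ = [
    "PopulationSpec",
    "ScenarioSpec",
    "panel_frequencies",
    "balding_nichols_freqs",
    "balding_nichols_dataset",
    "hardy_weinberg_sample",
    "generate_scenario",
    "escapee_mixture_scenario",
    "default_survey_scenario",
    "wright_fisher_sample",
]


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def panel_frequencies(n_loci: int = 19, allele_range=(7, 14), target_he: float = 0.8,
                      rng=None) -> list:
    """Ancestral frequency vectors: geometric-decay shapes scaled to the
    target expected heterozygosity, allele counts uniform in the range."""
    rng = np.random.default_rng(rng)
    out = []
    for _ in range(n_loci):
        k = int(rng.integers(allele_range[0], allele_range[1] + 1))
        best = None
        for x in np.linspace(0.35, 0.999, 150):
            p = x ** np.arange(k)
            p /= p.sum()
            he = 1 - float(np.sum(p ** 2))
            if best is None or abs(he - target_he) < best[0]:
                best = (abs(he - target_he), p)
        out.append(rng.permutation(best[1]))
    return out


def balding_nichols_freqs(ancestral: np.ndarray, fst: float, rng) -> np.ndarray:
    """One population's frequencies at divergence ``fst`` from ``ancestral``."""
    if fst <= 0:
        return ancestral.copy()
    alpha = ancestral * (1 - fst) / fst
    return rng.dirichlet(np.maximum(alpha, 1e-6))


def hardy_weinberg_sample(freqs: list, n: int, rng) -> np.ndarray:
    """(n, L, 2) genotypes drawn from per-locus frequency vectors."""
    L = len(freqs)
    g = np.zeros((n, L, 2), dtype=np.int16)
    for li, p in enumerate(freqs):
        g[:, li, 0] = rng.choice(p.size, size=n, p=p)
        g[:, li, 1] = rng.choice(p.size, size=n, p=p)
    return np.sort(g, axis=2)


def balding_nichols_dataset(n_pops: int, n_per_pop: int, fst: float,
                            n_loci: int = 19, allele_range=(7, 14),
                            target_he: float = 0.8, seed=None) -> GenotypeDataset:
    """A flat island-model dataset: every population at the same divergence
    from a shared ancestral panel.  The expectation of Weir-Cockerham theta
    equals ``fst`` up to sampling noise."""
    rng = np.random.default_rng(seed)
    anc = panel_frequencies(n_loci, allele_range, target_he, rng)
    loci = [Locus(f"L{li+1:02d}", tuple(range(1, p.size + 1))) for li, p in enumerate(anc)]
    rows, pop_index = [], []
    for pi in range(n_pops):
        pf = [balding_nichols_freqs(p, fst, rng) for p in anc]
        rows.append(hardy_weinberg_sample(pf, n_per_pop, rng))
        pop_index.extend([pi] * n_per_pop)
    return GenotypeDataset(loci, [f"pop{p+1}" for p in range(n_pops)],
                           np.array(pop_index), np.concatenate(rows))


def wright_fisher_sample(ne: int, n_sample: int, n_loci: int = 19,
                         generations: int = 20, allele_range=(7, 14),
                         target_he: float = 0.8, seed=None) -> GenotypeDataset:
    """Sample from a finite Wright-Fisher population of size ``ne``.

    The population of Ne diploids is propagated ``generations`` steps with
    random union of gametes (loci unlinked), building up the drift LD that
    the LD-Ne estimator measures; ``n_sample`` individuals are then drawn
    without replacement.
    """
    rng = np.random.default_rng(seed)
    anc = panel_frequencies(n_loci, allele_range, target_he, rng)
    pop = hardy_weinberg_sample(anc, ne, rng)
    L = len(anc)
    for _ in range(generations):
        mothers = rng.integers(0, ne, size=ne)
        fathers = rng.integers(0, ne, size=ne)
        child = np.zeros_like(pop)
        pick_m = rng.integers(0, 2, size=(ne, L))
        pick_f = rng.integers(0, 2, size=(ne, L))
        child[:, :, 0] = pop[mothers[:, None], np.arange(L)[None, :], pick_m]
        child[:, :, 1] = pop[fathers[:, None], np.arange(L)[None, :], pick_f]
        pop = np.sort(child, axis=2)
    take = rng.choice(ne, size=n_sample, replace=False)
    loci = [Locus(f"L{li+1:02d}", tuple(range(1, p.size + 1))) for li, p in enumerate(anc)]
    return GenotypeDataset(loci, ["wf"], np.zeros(n_sample, dtype=int), pop[take])


def clustered_dataset(n_clusters: int, n_per: int, fst: float, n_loci: int = 19,
                      allele_range=(7, 14), target_he: float = 0.8,
                      seed=None) -> GenotypeDataset:
    """One population sample per Balding-Nichols cluster (recovery fixtures)."""
    rng = np.random.default_rng(seed)
    anc = panel_frequencies(n_loci, allele_range, target_he, rng)
    loci = [Locus(f"L{li+1:02d}", tuple(range(1, p.size + 1))) for li, p in enumerate(anc)]
    rows, pops = [], []
    for k in range(n_clusters):
        cf = [balding_nichols_freqs(p, fst, rng) for p in anc]
        rows.append(hardy_weinberg_sample(cf, n_per, rng))
        pops += [k] * n_per
    return GenotypeDataset(loci, [f"c{k+1}" for k in range(n_clusters)],
                           np.array(pops), np.concatenate(rows))


def null_biased_dataset(fst: float = 0.02, n_pops: int = 16, n_per: int = 50,
                        null_r: float = 0.2, n_loci: int = 19, n_null: int = 10,
                        target_he: float = 0.8, seed=None):
    """An island-model dataset with a drifting null allele on ``n_null`` loci.

    Returns ``(dataset, realized_fst)`` where the truth is the realized
    differentiation of the latent frequencies (all alleles, null included):
    sum of among-population variances over sum of pbar(1-pbar).
    """
    rng = np.random.default_rng(seed)
    anc = panel_frequencies(n_loci, (7, 14), target_he, rng)
    anc_full = [np.concatenate([p * (1 - null_r), [null_r]]) if li < n_null else p
                for li, p in enumerate(anc)]
    loci = [Locus(f"L{li+1:02d}", tuple(range(1, anc[li].size + 1))) for li in range(n_loci)]
    rows, pops, latent = [], [], []
    for k in range(n_pops):
        cf = [balding_nichols_freqs(p, fst, rng) for p in anc_full]
        latent.append(cf)
        rows.append(hardy_weinberg_sample(cf, n_per, rng))
        pops += [k] * n_per
    g = np.concatenate(rows)
    for li in range(n_null):
        kv = anc[li].size
        is_null = g[:, li, :] == kv
        both = is_null.all(axis=1)
        one = is_null.any(axis=1) & ~both
        g[both, li, :] = MISSING
        vis = np.where(is_null[one, 0], g[one, li, 1], g[one, li, 0])
        g[one, li, 0] = vis
        g[one, li, 1] = vis
    g = np.sort(g, axis=2)
    num = den = 0.0
    for li in range(n_loci):
        mat = np.stack([latent[k][li] for k in range(n_pops)])
        pbar = mat.mean(axis=0)
        num += float(mat.var(axis=0, ddof=1).sum())
        den += float((pbar * (1 - pbar)).sum())
    ds = GenotypeDataset(loci, [f"p{k+1}" for k in range(n_pops)],
                         np.array(pops), g)
    return ds, num / den


# ---------------------------------------------------------------------------
# Full survey scenarios
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    name: str
    size: int
    group: str                        # wild | farm-associated | YoY | farmed
    cluster: str                      # which frequency pool the sample draws from
    escapee_fraction: float = 0.0     # planted pure-farmed individuals
    f1_fraction: float = 0.0          # planted wild x farmed F1 hybrids
    escapee_source: str | None = None # farmed cluster supplying escapees/F1 gametes


@dataclass
class ScenarioSpec:
    populations: list
    cluster_fst: dict                 # cluster -> divergence from ancestral
    pop_fst: float = 0.005            # extra within-cluster drift per sample
    n_loci: int = 19
    allele_range: tuple = (7, 14)
    target_he: float = 0.8
    null_loci: dict = field(default_factory=dict)   # locus index -> null freq
    missing_rate: float = 0.003
    trios: list = field(default_factory=list)       # (parent_pop, offspring_pop, count)
    ne_by_group: dict = field(default_factory=dict) # documented drift rationale
    seed: int | None = None

    def validate(self):
        for p in self.populations:
            if not (0 <= p.escapee_fraction <= 1 and 0 <= p.f1_fraction <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        for c, f in self.cluster_fst.items():
            if not (0 < f < 1):
                raise ValueError(f"cluster FST for {c!r} must lie in (0, 1)")
        if self.target_he >= 1 - 1 / self.allele_range[1]:
            raise ValueError("He target unreachable with the allele range")
        return self


def generate_scenario(spec: ScenarioSpec, seed=None) -> tuple[GenotypeDataset, dict]:
    """Draw a labelled dataset from the scenario.

    Returns ``(dataset, truth)`` where truth carries: ``individuals`` (a
    DataFrame with population, group, cluster, origin class, parents),
    ``null_freqs`` per locus, ``cluster_freqs`` and ``pop_freqs`` (the
    latent Balding-Nichols frequencies).  Null alleles are injected as a
    hidden allele: a null/visible draw shows as an apparent homozygote and
    null/null as a missing call, matching the EM model's assumptions;
    random missingness is applied last.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    anc = panel_frequencies(spec.n_loci, spec.allele_range, spec.target_he, rng)
    loci = [Locus(f"L{li+1:02d}", tuple(range(1, p.size + 1))) for li, p in enumerate(anc)]
    L = spec.n_loci

    # the null allele is appended as a hidden extra allele on the affected
    # loci BEFORE population divergence, so its frequency drifts between
    # populations like any real allele (the regime in which null alleles
    # bias differentiation estimates)
    n_visible = [p.size for p in anc]
    anc_full = list(anc)
    for li, r in spec.null_loci.items():
        anc_full[li] = np.concatenate([anc_full[li] * (1 - r), [r]])

    cluster_freqs = {
        c: [balding_nichols_freqs(p, f, rng) for p in anc_full]
        for c, f in spec.cluster_fst.items()
    }
    pop_freqs = {}
    for p in spec.populations:
        base = cluster_freqs[p.cluster]
        pop_freqs[p.name] = [balding_nichols_freqs(b, spec.pop_fst, rng) for b in base]

    rows, pop_index, records = [], [], []
    counter = 0
    trios_by_parent: dict = {}
    for parent_pop, off_pop, count in spec.trios:
        trios_by_parent.setdefault(parent_pop, []).append((off_pop, count))
    pending_offspring = []   # (offspring_pop, genotype, parent_id, parent2_id)

    for pi, p in enumerate(spec.populations):
        pf = pop_freqs[p.name]
        n = p.size
        n_esc = int(round(p.escapee_fraction * n))
        n_f1 = int(round(p.f1_fraction * n))
        n_native = n - n_esc - n_f1
        if n_native < 0:
            raise ValueError(f"fractions exceed population size in {p.name}")
        blocks = []
        classes = []
        if n_native:
            blocks.append(hardy_weinberg_sample(pf, n_native, rng))
            classes += ["native"] * n_native
        if n_esc or n_f1:
            src = p.escapee_source
            if src is None:
                raise ValueError(f"{p.name} plants hybrids but has no escapee_source")
            sf = cluster_freqs[src]
            if n_esc:
                blocks.append(hardy_weinberg_sample(sf, n_esc, rng))
                classes += ["escapee"] * n_esc
            if n_f1:
                g = np.zeros((n_f1, L, 2), dtype=np.int16)
                for li in range(L):
                    g[:, li, 0] = rng.choice(pf[li].size, size=n_f1, p=pf[li])
                    g[:, li, 1] = rng.choice(sf[li].size, size=n_f1, p=sf[li])
                blocks.append(np.sort(g, axis=2))
                classes += ["F1"] * n_f1
        geno = np.concatenate(blocks) if blocks else np.zeros((0, L, 2), dtype=np.int16)
        perm = rng.permutation(n)
        geno = geno[perm]
        classes = [classes[i] for i in perm]
        ids = [f"{p.name}_{i+1}" for i in range(n)]
        for i in range(n):
            records.append({
                "individual": ids[i], "population": p.name, "group": p.group,
                "cluster": p.cluster, "origin": classes[i],
                "parent1": None, "parent2": None,
            })
        rows.append(geno)
        pop_index.extend([pi] * n)
        counter += n

        # parent-offspring trios seeded from this population's native members
        for off_pop, count in trios_by_parent.get(p.name, []):
            native_idx = [i for i, c in enumerate(classes) if c == "native"]
            pairs = rng.choice(native_idx, size=(count, 2), replace=False)
            for par_a, par_b in pairs:
                child = np.zeros((L, 2), dtype=np.int16)
                for li in range(L):
                    child[li, 0] = geno[par_a, li, rng.integers(2)]
                    child[li, 1] = geno[par_b, li, rng.integers(2)]
                pending_offspring.append(
                    (off_pop, np.sort(child), ids[par_a], ids[par_b])
                )

    # place trio offspring, replacing native members of the target population
    name_to_pi = {p.name: i for i, p in enumerate(spec.populations)}
    geno_all = np.concatenate(rows)
    pop_index = np.array(pop_index)
    offsets = np.cumsum([0] + [p.size for p in spec.populations])
    used = set()
    for off_pop, child, par1, par2 in pending_offspring:
        pi = name_to_pi[off_pop]
        cands = [i for i in range(offsets[pi], offsets[pi + 1])
                 if records[i]["origin"] == "native" and i not in used]
        if not cands:
            raise ValueError(f"no native slot left in {off_pop} for a trio offspring")
        slot = int(rng.choice(cands))
        used.add(slot)
        geno_all[slot] = child
        records[slot]["origin"] = "trio_offspring"
        records[slot]["parent1"] = par1
        records[slot]["parent2"] = par2

    # mask the hidden null allele: null/null -> missing call, null/visible ->
    # apparent homozygote for the visible copy
    null_freqs = pd.Series(0.0, index=[l.name for l in loci])
    for li, r in spec.null_loci.items():
        null_freqs.iloc[li] = r
        is_null = geno_all[:, li, :] == n_visible[li]
        both = is_null.all(axis=1)
        one = is_null.any(axis=1) & ~both
        geno_all[both, li, :] = MISSING
        vis = np.where(is_null[one, 0], geno_all[one, li, 1], geno_all[one, li, 0])
        geno_all[one, li, 0] = vis
        geno_all[one, li, 1] = vis

    if spec.missing_rate > 0:
        drop = rng.random((geno_all.shape[0], L)) < spec.missing_rate
        geno_all[drop] = MISSING

    ds = GenotypeDataset(
        loci, [p.name for p in spec.populations], pop_index, geno_all,
        ids=[r["individual"] for r in records],
        group_labels={p.name: p.group for p in spec.populations},
    )
    truth = {
        "individuals": pd.DataFrame(records),
        "null_freqs": null_freqs,
        "cluster_freqs": cluster_freqs,
        "pop_freqs": pop_freqs,
        "spec": spec,
    }
    return ds, truth


def escapee_mixture_scenario(seed: int = 0) -> ScenarioSpec:
    """A four-sample benchmark for escapee/hybrid-fraction recovery.

    Two clean wild reference samples, one impacted wild sample carrying 10%
    planted farm escapees and 15% F1 hybrids, and one strongly diverged
    farmed strain (the well-differentiated regime in which ancestry-band
    calling is informative at a 19-locus panel)."""
    pops = [
        PopulationSpec("wild_ref1", 150, "wild", "wild"),
        PopulationSpec("wild_ref2", 150, "wild", "wild"),
        PopulationSpec("impacted", 200, "wild", "wild", 0.10, 0.15, "farm"),
        PopulationSpec("farm_strain", 150, "farmed", "farm"),
    ]
    return ScenarioSpec(pops, {"wild": 0.02, "farm": 0.25}, pop_fst=0.003,
                        missing_rate=0.0, seed=seed)


def default_survey_scenario(seed: int = 2016) -> ScenarioSpec:
    """The frozen survey-shaped scenario: 27 samples totalling 1586
    individuals in four groups (wild adults, wild young-of-the-year,
    farm-associated adults, farmed strains from four hatchery origins),
    19 active loci with He near 0.8, global differentiation near 0.02 and
    stronger farmed-strain divergence, roughly 10% escapees and 15% F1
    hybrids planted in the farm-impacted samples."""
    wild = [("09WH", 41), ("15WT", 80), ("15WN", 90), ("16WR", 89), ("16WU", 47),
            ("16WV", 86), ("16WK", 29), ("16WD", 19)]
    yoy = [("15JP", 124), ("15JN", 71), ("16JP", 25), ("16JR", 34), ("16JB", 30)]
    fa = [("15AK", 56), ("15AB", 44), ("15AV", 21), ("16AK", 50), ("16AB", 46),
          ("17AK", 60), ("17AB", 70)]
    farmed = [("15FC", 96, "F-CRO"), ("15FF", 97, "F-FRA"), ("15FI", 57, "F-ITA"),
              ("16FI", 15, "F-ITA"), ("16FG", 71, "F-GRE"), ("16FFa", 59, "F-FRA"),
              ("16FFb", 79, "F-FRA")]
    pops = []
    for name, size in wild:
        pops.append(PopulationSpec(name, size, "wild", "wild_migratory"))
    for name, size in yoy:
        esc, f1 = (0.10, 0.13) if name == "16JB" else (0.0, 0.05)
        pops.append(PopulationSpec(name, size, "YoY", "resident", esc, f1, "F-FRA"))
    for name, size in fa:
        esc, f1 = (0.10, 0.15) if name.startswith("17") else (0.02, 0.05)
        pops.append(PopulationSpec(name, size, "farm-associated", "resident",
                                   esc, f1, "F-CRO"))
    for name, size, strain in farmed:
        pops.append(PopulationSpec(name, size, "farmed", strain))
    cluster_fst = {
        "wild_migratory": 0.012,
        "resident": 0.012,
        "F-CRO": 0.05,
        "F-FRA": 0.05,
        "F-ITA": 0.05,
        "F-GRE": 0.05,
    }
    return ScenarioSpec(
        populations=pops,
        cluster_fst=cluster_fst,
        pop_fst=0.004,
        n_loci=19,
        null_loci={2: 0.05, 6: 0.05},
        missing_rate=0.003,
        trios=[("15AK", "15JN", 3), ("15AB", "15JP", 1), ("16AB", "16JR", 2)],
        ne_by_group={"wild": 550, "YoY": 2800, "farm-associated": 1140, "farmed": 160},
        seed=seed,
    )
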