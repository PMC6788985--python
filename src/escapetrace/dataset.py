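"""Core data model for multilocus diploid microsatellite genotypes.

The pipeline operates on co-dominant genotypes scored as fragment-size
integers (microsatellite allele calls), partitioned into named population
samples.  Genotypes are stored as indices into each locus's sorted allele
list, canonicalized so that ``(a, b) == (b, a)``; a missing genotype is
``(-1, -1)``.  GENEPOP text (2- or 3-digit dialect) is the exchange format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "Locus",
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_population_metadata",
    "missing_summary",
    "allele_frequencies",
]


class GenepopParseError(ValueError):
    """Raised when a GENEPOP file violates the dialect."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker: a name and its ordered distinct allele labels."""

    name: str
    alleles: tuple[int, ...]

    def __post_init__(self):
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name!r} has no alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name!r} has duplicate allele labels")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def index_of(self, label: int) -> int:
        return self.alleles.index(label)


class GenotypeDataset:
    """Diploid multilocus genotypes grouped into named population samples.

    Parameters
    ----------
    loci : list of Locus
    pop_names : list of str
        Population sample names, in file/definition order.
    pop_index : array of int, shape (n_individuals,)
        Population membership of each individual.
    genotypes : array of int, shape (n_individuals, n_loci, 2)
        Allele *indices* into each locus's allele tuple; ``MISSING`` (-1) in
        both slots marks an untyped call.  Stored canonically as (min, max).
    ids : list of str, optional
        Individual identifiers.
    group_labels : dict, optional
        Population name -> group tag (e.g. ``wild``, ``farm-associated``,
        ``YoY``, ``farmed``).
    active_loci : list of str, optional
        The locus subset used by downstream estimators (after QC); defaults
        to all loci.
    """

    def __init__(self, loci, pop_names, pop_index, genotypes, ids=None,
                 group_labels=None, active_loci=None):
        self.loci = list(loci)
        self.pop_names = list(pop_names)
        self.pop_index = np.asarray(pop_index, dtype=np.int64)
        g = np.asarray(genotypes, dtype=np.int16)
        if g.ndim != 3 or g.shape[2] != 2 or g.shape[1] != len(self.loci):
            raise ValueError("genotypes must have shape (n, n_loci, 2)")
        # canonicalize unordered pairs and missing coding
        g = np.sort(g, axis=2)
        half = (g == MISSING).any(axis=2)
        g[half] = MISSING
        self.genotypes = g
        self.ids = list(ids) if ids is not None else [f"ind_{i}" for i in range(len(g))]
        self.group_labels = dict(group_labels or {})
        self.active_loci = list(active_loci) if active_loci is not None else [l.name for l in self.loci]
        if self.pop_index.shape[0] != g.shape[0]:
            raise ValueError("pop_index length mismatch")
        if self.pop_index.size and (self.pop_index.min() < 0 or self.pop_index.max() >= len(self.pop_names)):
            raise ValueError("pop_index out of range")
        for li, locus in enumerate(self.loci):
            col = g[:, li, :]
            valid = col[col != MISSING]
            if valid.size and valid.max() >= locus.n_alleles:
                raise ValueError(f"allele index out of range at locus {locus.name}")

    # -- basic shape ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_populations(self) -> int:
        return len(self.pop_names)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def locus_position(self, name: str) -> int:
        return self.locus_names.index(name)

    def pop_position(self, name: str) -> int:
        return self.pop_names.index(name)

    def population_sizes(self) -> pd.Series:
        counts = np.bincount(self.pop_index, minlength=self.n_populations)
        return pd.Series(counts, index=self.pop_names, name="n")

    # -- views ----------------------------------------------------------
    def subset_populations(self, names) -> "GenotypeDataset":
        names = list(names)
        keep = np.isin(self.pop_index, [self.pop_position(n) for n in names])
        remap = {self.pop_position(n): i for i, n in enumerate(names)}
        new_index = np.array([remap[p] for p in self.pop_index[keep]], dtype=np.int64)
        return GenotypeDataset(
            self.loci, names, new_index, self.genotypes[keep],
            ids=[self.ids[i] for i in np.flatnonzero(keep)],
            group_labels={n: self.group_labels.get(n) for n in names if n in self.group_labels},
            active_loci=self.active_loci,
        )

    def subset_individuals(self, indices) -> "GenotypeDataset":
        indices = np.asarray(indices, dtype=np.int64)
        return GenotypeDataset(
            self.loci, self.pop_names, self.pop_index[indices],
            self.genotypes[indices], ids=[self.ids[i] for i in indices],
            group_labels=self.group_labels, active_loci=self.active_loci,
        )

    def restrict_loci(self, names) -> "GenotypeDataset":
        names = list(names)
        pos = [self.locus_position(n) for n in names]
        return GenotypeDataset(
            [self.loci[i] for i in pos], self.pop_names, self.pop_index,
            self.genotypes[:, pos, :], ids=self.ids,
            group_labels=self.group_labels, active_loci=names,
        )

    def active_view(self) -> "GenotypeDataset":
        """The dataset restricted to the active (post-QC) locus panel."""
        if self.active_loci == self.locus_names:
            return self
        return self.restrict_loci(self.active_loci)

    # -- label access ----------------------------------------------------
    def allele_labels(self, individual: int, locus: int) -> tuple:
        a, b = self.genotypes[individual, locus]
        if a == MISSING:
            return (None, None)
        loc = self.loci[locus]
        return (loc.alleles[a], loc.alleles[b])

    def to_label_array(self) -> np.ndarray:
        """Genotypes as allele labels (0 = missing), shape (n, n_loci, 2)."""
        out = np.zeros_like(self.genotypes, dtype=np.int64)
        for li, locus in enumerate(self.loci):
            labels = np.asarray(locus.alleles, dtype=np.int64)
            col = self.genotypes[:, li, :]
            ok = col != MISSING
            out[:, li, :][ok] = labels[col[ok]]
        return out

    def equals(self, other: "GenotypeDataset") -> bool:
        """Structural identity: same loci, populations and genotype labels.

        Compared at the allele-label level, so two datasets are equal even
        if one carries extra allele labels that no individual carries
        (which a GENEPOP round trip cannot preserve).
        """
        return (
            self.locus_names == other.locus_names
            and self.pop_names == other.pop_names
            and np.array_equal(self.pop_index, other.pop_index)
            and np.array_equal(self.to_label_array(), other.to_label_array())
        )


@dataclass
class AlleleFrequencyTable:
    """Per-(population, locus) allele frequency vectors.

    ``freq[p, l, :n_alleles(l)]`` holds the frequency vector for population
    ``p`` at locus ``l`` (zero-padded beyond the locus's allele count);
    ``gene_count[p, l]`` is the number of non-missing gene copies (2n).
    Cells with zero non-missing calls are flagged in ``undefined``.
    """

    pop_names: list
    loci: list
    freq: np.ndarray         # (P, L, Amax)
    gene_count: np.ndarray   # (P, L)
    undefined: np.ndarray    # (P, L) bool
    drop_below: float = 0.0

    def vector(self, pop, locus) -> np.ndarray:
        p = self.pop_names.index(pop) if isinstance(pop, str) else pop
        l = [lc.name for lc in self.loci].index(locus) if isinstance(locus, str) else locus
        return self.freq[p, l, : self.loci[l].n_alleles]

    def pooled(self) -> "AlleleFrequencyTable":
        """Frequencies over all populations pooled into one sample."""
        w = self.gene_count[:, :, None].astype(float)
        tot = self.gene_count.sum(axis=0)
        pooled = (self.freq * w).sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore"):
            pooled = pooled / np.maximum(tot[None, :, None], 1)
        return AlleleFrequencyTable(
            ["pooled"], self.loci, pooled, tot[None, :],
            (tot == 0)[None, :], self.drop_below,
        )


# ---------------------------------------------------------------------------
# GENEPOP I/O
# ---------------------------------------------------------------------------

def _parse_genotype_token(tok: str, lineno: int):
    """Return (a, b, width) integer allele labels; 0 codes missing."""
    if len(tok) == 4:
        w = 2
    elif len(tok) == 6:
        w = 3
    else:
        raise GenepopParseError(f"line {lineno}: genotype token {tok!r} is not 4 or 6 digits")
    if not tok.isdigit():
        raise GenepopParseError(f"line {lineno}: non-numeric genotype token {tok!r}")
    return int(tok[:w]), int(tok[w:]), w


def read_genepop(path) -> GenotypeDataset:
    """Read a GENEPOP file (2- or 3-digit dialect) into a GenotypeDataset.

    Population names follow the GENEPOP convention: each POP block is named
    after its last individual's identifier (deduplicated if repeated).
    Alleles coded 0 (``00``/``000``) mark the whole genotype as missing.
    Individuals missing at every locus are rejected with a warning.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty file")
    it = iter(enumerate(lines[1:], start=2))

    locus_names: list[str] = []
    pop_rows: list[list] = []   # one list of (id, [(a,b)...], lineno) per POP
    current: list | None = None
    for lineno, raw in it:
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            current = []
            pop_rows.append(current)
            continue
        if current is None:
            # still in the locus-name header; comma-separated or one per line
            parts = [p.strip() for p in line.split(",") if p.strip()]
            locus_names.extend(parts)
            continue
        if "," not in line:
            raise GenepopParseError(f"line {lineno}: expected 'id , genotypes'")
        ind_id, _, geno_part = line.partition(",")
        toks = geno_part.split()
        if len(toks) != len(locus_names):
            raise GenepopParseError(
                f"line {lineno}: {len(toks)} genotypes for {len(locus_names)} loci"
            )
        pairs = [_parse_genotype_token(t, lineno) for t in toks]
        current.append((ind_id.strip(), pairs, lineno))

    if not locus_names:
        raise GenepopParseError("no locus names found")
    if not pop_rows or not any(pop_rows):
        raise GenepopParseError("no POP blocks found")

    n_loci = len(locus_names)
    widths = [set() for _ in range(n_loci)]
    observed = [set() for _ in range(n_loci)]
    for block in pop_rows:
        for _, pairs, lineno in block:
            for li, (a, b, w) in enumerate(pairs):
                widths[li].add(w)
                if len(widths[li]) > 1:
                    raise GenepopParseError(
                        f"line {lineno}: mixed 2/3-digit coding at locus {locus_names[li]}"
                    )
                for al in (a, b):
                    if al != 0:
                        observed[li].add(al)

    loci = [
        Locus(name, tuple(sorted(obs)) if obs else (0,))
        for name, obs in zip(locus_names, observed)
    ]
    lookup = [{lab: i for i, lab in enumerate(l.alleles)} for l in loci]

    pop_names, ids, pop_index, rows = [], [], [], []
    kept_any = False
    for pi, block in enumerate(pop_rows):
        if not block:
            continue
        name = block[-1][0]
        if name in pop_names:
            name = f"{name}_{pi + 1}"
        pop_names.append(name)
        for ind_id, pairs, lineno in block:
            row = np.full((n_loci, 2), MISSING, dtype=np.int16)
            for li, (a, b, _w) in enumerate(pairs):
                if a != 0 and b != 0:
                    row[li, 0] = lookup[li][a]
                    row[li, 1] = lookup[li][b]
            if (row == MISSING).all():
                warnings.warn(
                    f"individual {ind_id!r} (line {lineno}) missing at all loci; dropped",
                    stacklevel=2,
                )
                continue
            kept_any = True
            ids.append(ind_id)
            pop_index.append(len(pop_names) - 1)
            rows.append(row)
    if not kept_any:
        raise GenepopParseError("no individuals with at least one genotype")
    return GenotypeDataset(loci, pop_names, np.array(pop_index), np.stack(rows), ids=ids)


def write_genepop(ds: GenotypeDataset, path, title="escapetrace export", digits=3) -> None:
    """Write a dataset as GENEPOP text (one locus name per line)."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    fmt = f"{{:0{digits}d}}"
    out = [title]
    out.extend(ds.locus_names)
    for pi, pop in enumerate(ds.pop_names):
        out.append("POP")
        members = np.flatnonzero(ds.pop_index == pi)
        for j, i in enumerate(members):
            toks = []
            for li, locus in enumerate(ds.loci):
                a, b = ds.genotypes[i, li]
                if a == MISSING:
                    toks.append(fmt.format(0) * 2)
                else:
                    toks.append(fmt.format(locus.alleles[a]) + fmt.format(locus.alleles[b]))
            # last individual of the block carries the population name
            ind_id = pop if j == len(members) - 1 else ds.ids[i]
            out.append(f"{ind_id} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


def read_population_metadata(path) -> pd.DataFrame:
    """Read the population metadata CSV (pop_id, group, latitude, longitude, year)."""
    meta = pd.read_csv(path)
    required = {"pop_id", "group"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    return meta


def attach_metadata(ds: GenotypeDataset, meta: pd.DataFrame) -> GenotypeDataset:
    ds.group_labels = dict(zip(meta["pop_id"], meta["group"]))
    return ds


# ---------------------------------------------------------------------------
# Summaries and frequencies
# ---------------------------------------------------------------------------

def missing_summary(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-locus missing-call fraction plus the unweighted overall mean.

    Returns a DataFrame indexed by locus name with a trailing ``overall``
    row (mean across loci).
    """
    miss = (ds.genotypes[:, :, 0] == MISSING).mean(axis=0)
    out = pd.DataFrame({"missing_fraction": miss}, index=ds.locus_names)
    out.loc["overall"] = miss.mean()
    return out


def allele_frequencies(ds: GenotypeDataset, drop_below: float = 0.0) -> AlleleFrequencyTable:
    """Per-(population, locus) allele frequencies over non-missing gene copies.

    With ``drop_below > 0``, alleles at frequency <= the threshold are
    removed from each cell's vector and the remainder renormalized (the
    rare-allele exclusion used by the LD-Ne stage).
    """
    if not (0 <= drop_below < 0.5):
        raise ValueError("drop_below must be in [0, 0.5)")
    P, L = ds.n_populations, ds.n_loci
    amax = max(l.n_alleles for l in ds.loci)
    freq = np.zeros((P, L, amax))
    gene_count = np.zeros((P, L), dtype=np.int64)
    for li, locus in enumerate(ds.loci):
        g = ds.genotypes[:, li, :]
        ok = g[:, 0] != MISSING
        pops = np.repeat(ds.pop_index[ok], 2)
        alleles = g[ok].ravel()
        counts = np.zeros((P, locus.n_alleles))
        np.add.at(counts, (pops, alleles), 1.0)
        tot = counts.sum(axis=1)
        gene_count[:, li] = tot
        with np.errstate(invalid="ignore", divide="ignore"):
            f = counts / tot[:, None]
        f[tot == 0] = 0.0
        if drop_below > 0:
            f[(f > 0) & (f <= drop_below)] = 0.0
            s = f.sum(axis=1, keepdims=True)
            np.divide(f, s, out=f, where=s > 0)
        freq[:, li, : locus.n_alleles] = f
    return AlleleFrequencyTable(
        list(ds.pop_names), list(ds.loci), freq, gene_count,
        gene_count == 0, drop_below,
    )
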