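"""Core domain types for unphased-genotype marker data.

A marker locus carries ``m >= 2`` alleles with frequencies ``p_j``.  An
individual's unphased genotype is an unordered pair of alleles; parental
origin is unknown, so the pair ``a/b`` is identical to ``b/a``.  The types
here hold loci, per-individual genotypes at one or two loci, genotype count
tables ``n_jk`` / ``n_jkrs`` and genotypic group means, which are the
sufficient statistics for all least-squares estimation downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FREQ_SUM_TOL = 1e-12


@dataclass
class Locus:
    """A marker locus with ordered allele labels and an optional frequency set.

    Alleles are internally reordered so the reference allele ``A_m`` is last.
    If no reference is given, the most frequent allele (when frequencies are
    known) or the last listed allele is used; a common reference improves the
    accuracy of the least-squares estimates of the fixed allelic effects.
    """

    name: str
    alleles: Sequence[str]
    freqs: np.ndarray | None = None
    ref_allele: str | None = None

    def __post_init__(self) -> None:
        alleles = tuple(str(a) for a in self.alleles)
        if len(alleles) < 2:
            raise ValueError(f"locus {self.name!r} needs >= 2 alleles")
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"locus {self.name!r} has duplicate allele labels")
        freqs = None
        if self.freqs is not None:
            freqs = np.asarray(self.freqs, dtype=float)
            if freqs.shape != (len(alleles),):
                raise ValueError("freqs length must match allele count")
            if abs(freqs.sum() - 1.0) > FREQ_SUM_TOL:
                raise ValueError(f"allele frequencies must sum to 1, got {freqs.sum()!r}")
            if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
                raise ValueError("every allele frequency must lie in (0, 1)")
        ref = self.ref_allele
        if ref is None:
            ref = alleles[int(np.argmax(freqs))] if freqs is not None else alleles[-1]
        else:
            ref = str(ref)
            if ref not in alleles:
                raise ValueError(f"reference allele {ref!r} not among alleles of {self.name!r}")
        order = [a for a in alleles if a != ref] + [ref]
        if freqs is not None:
            freqs = freqs[[alleles.index(a) for a in order]]
        self.alleles = tuple(order)
        self.freqs = freqs
        self.ref_allele = ref

    @property
    def m(self) -> int:
        return len(self.alleles)

    def index(self, allele: str) -> int:
        try:
            return self.alleles.index(str(allele))
        except ValueError:
            raise KeyError(
                f"allele {allele!r} is not declared for locus {self.name!r} "
                f"(alleles: {self.alleles})"
            ) from None


def _symmetrize_pair_table(raw: np.ndarray) -> np.ndarray:
    """Mirror a table indexed by sorted pairs into a fully symmetric table."""
    if raw.ndim == 2:
        return raw + raw.T - np.diag(np.diag(raw))
    m1, _, m2, _ = raw.shape
    j, k, r, s = np.meshgrid(
        np.arange(m1), np.arange(m1), np.arange(m2), np.arange(m2), indexing="ij"
    )
    return raw[np.minimum(j, k), np.maximum(j, k), np.minimum(r, s), np.maximum(r, s)]


@dataclass
class GenotypeCounts:
    """Symmetric genotype count table: ``n_jk`` (one locus) or ``n_jkrs`` (two).

    ``table[j, k] == table[k, j]`` holds the count of individuals with
    unordered genotype ``{A_j, A_k}``; summing over ``j <= k`` gives ``N``.
    """

    table: np.ndarray
    N: int

    @classmethod
    def from_genotypes(cls, genotypes: Sequence[np.ndarray], ms: Sequence[int]) -> "GenotypeCounts":
        n = len(genotypes[0])
        if len(genotypes) == 1:
            g = genotypes[0]
            raw = np.zeros((ms[0], ms[0]))
            np.add.at(raw, (g[:, 0], g[:, 1]), 1.0)
        else:
            g1, g2 = genotypes
            raw = np.zeros((ms[0], ms[0], ms[1], ms[1]))
            np.add.at(raw, (g1[:, 0], g1[:, 1], g2[:, 0], g2[:, 1]), 1.0)
        return cls(table=_symmetrize_pair_table(raw), N=n)

    def allele_counts(self, locus: int = 0) -> np.ndarray:
        """Allele tallies ``n_j. = 2 n_jj + sum_{k != j} n_jk`` (sum = 2N)."""
        tab = self.marginal(locus)
        return tab.sum(axis=1) + np.diag(tab)

    def marginal(self, locus: int = 0) -> np.ndarray:
        if self.table.ndim == 2:
            if locus != 0:
                raise IndexError("one-locus counts have a single locus")
            return self.table
        raw = _upper_pair_mask_sum(self.table)
        return raw if locus == 0 else _upper_pair_mask_sum_second(self.table)


def _upper_pair_mask_sum(table4: np.ndarray) -> np.ndarray:
    """Sum a 4-index symmetric table over unordered second-locus cells."""
    m2 = table4.shape[2]
    iu = np.triu_indices(m2)
    return table4[:, :, iu[0], iu[1]].sum(axis=2)


def _upper_pair_mask_sum_second(table4: np.ndarray) -> np.ndarray:
    m1 = table4.shape[0]
    iu = np.triu_indices(m1)
    return table4[iu[0], iu[1], :, :].sum(axis=0)


@dataclass
class GroupMeans:
    """Genotypic group means with an attached frequency set.

    ``means[j, k]`` (or ``means[j, k, r, s]``) is the mean phenotype of the
    genotype cell; empty cells are NaN.  The attached allele frequencies
    (estimated from the same data by default) are the weights used for the
    allele-weighted means that enter the closed-form LSE.
    """

    means: np.ndarray
    freqs: list[np.ndarray]
    counts: GenotypeCounts | None = None

    @property
    def n_loci(self) -> int:
        return 1 if self.means.ndim == 2 else 2

    def allele_weighted(self) -> np.ndarray:
        """One-locus weighted means ``ybar_j.* = sum_k p_k ybar_jk``."""
        if self.n_loci != 1:
            raise ValueError("allele_weighted is defined for one locus")
        return self.means @ self.freqs[0]

    def weighted_overall(self) -> float:
        """``ybar..* = sum_jk p_j p_k ybar_jk`` (and the 4-index analogue)."""
        if self.n_loci == 1:
            p = self.freqs[0]
            return float(p @ self.means @ p)
        p1, p2 = self.freqs
        return float(np.einsum("jkrs,j,k,r,s->", self.means, p1, p1, p2, p2))

    def empty_cells(self) -> list[tuple[int, ...]]:
        idx = np.argwhere(np.isnan(self.means))
        out = []
        for cell in idx:
            if self.means.ndim == 2:
                j, k = cell
                if j <= k:
                    out.append((int(j), int(k)))
            else:
                j, k, r, s = cell
                if j <= k and r <= s:
                    out.append((int(j), int(k), int(r), int(s)))
        return out


def _canonicalize(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=np.int64)
    if g.ndim != 2 or g.shape[1] != 2:
        raise ValueError("genotype array must have shape (N, 2)")
    return np.sort(g, axis=1)


@dataclass
class GenotypeDataset:
    """Per-individual unordered genotypes at 1-2 loci plus phenotype/covariates.

    Genotypes are stored as allele indices into each locus's allele list and
    canonically sorted within the pair, so ``a/b`` and ``b/a`` are identical.
    """

    loci: list[Locus]
    genotypes: list[np.ndarray]
    phenotype: np.ndarray | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.loci) <= 2:
            raise ValueError("datasets support 1 or 2 loci")
        if len(self.genotypes) != len(self.loci):
            raise ValueError("one genotype array per locus required")
        self.genotypes = [_canonicalize(g) for g in self.genotypes]
        n = len(self.genotypes[0])
        for locus, g in zip(self.loci, self.genotypes):
            if len(g) != n:
                raise ValueError("genotype arrays must share the sample size")
            if g.size and (g.min() < 0 or g.max() >= locus.m):
                raise ValueError(f"allele index out of range for locus {locus.name!r}")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=float)
            if len(self.phenotype) != n:
                raise ValueError("phenotype length must match sample size")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariate rows must match sample size")

    @property
    def N(self) -> int:
        return len(self.genotypes[0])

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def counts(self) -> GenotypeCounts:
        return GenotypeCounts.from_genotypes(self.genotypes, [l.m for l in self.loci])

    def estimated_freqs(self) -> list[np.ndarray]:
        from . import freqs as _freqs

        est = _freqs.mle_frequencies(self.counts())
        return list(est.p)

    def group_means(self, freqs: list[np.ndarray] | None = None) -> GroupMeans:
        if self.phenotype is None:
            raise ValueError("dataset has no phenotype")
        counts = self.counts()
        if len(self.loci) == 1:
            g = self.genotypes[0]
            m = self.loci[0].m
            sums = np.zeros((m, m))
            np.add.at(sums, (g[:, 0], g[:, 1]), self.phenotype)
        else:
            g1, g2 = self.genotypes
            sums = np.zeros((self.loci[0].m,) * 2 + (self.loci[1].m,) * 2)
            np.add.at(sums, (g1[:, 0], g1[:, 1], g2[:, 0], g2[:, 1]), self.phenotype)
        sums = _symmetrize_pair_table(sums)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts.table > 0, sums / np.maximum(counts.table, 1), np.nan)
        if freqs is None:
            freqs = self.estimated_freqs()
        return GroupMeans(means=means, freqs=[np.asarray(p, float) for p in freqs], counts=counts)

    def subset(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            loci=self.loci,
            genotypes=[g[mask] for g in self.genotypes],
            phenotype=None if self.phenotype is None else self.phenotype[mask],
            covariates=None if self.covariates is None else self.covariates.loc[mask].reset_index(drop=True),
        )

    def genotype_labels(self, locus: int = 0) -> list[str]:
        """Per-individual genotype strings ``a/b`` in canonical order."""
        loc = self.loci[locus]
        g = self.genotypes[locus]
        return [f"{loc.alleles[a]}/{loc.alleles[b]}" for a, b in g]
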