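"""Allele/genotype frequency MLEs and Hardy-Weinberg disequilibrium measures.

Estimates are computed in exact rational arithmetic from the integer genotype
counts and converted to float once, so that datasets constructed to sit
exactly at Hardy-Weinberg proportions yield ``D_jk = 0.0`` exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .data import GenotypeCounts

logger = logging.getLogger(__name__)


@dataclass
class FrequencyEstimate:
    """MLE allele frequencies per locus and the genotype frequency table.

    ``p[i]`` is the allele-frequency vector of locus ``i`` (``p_j = n_j./2N``);
    ``p_geno`` mirrors the count table layout (``p_jk = n_jk / N`` stored
    symmetrically, summing to 1 over ``j <= k``).
    """

    p: list[np.ndarray]
    p_geno: np.ndarray
    N: int


def _int_table(table: np.ndarray) -> np.ndarray:
    it = np.rint(table).astype(np.int64)
    if not np.allclose(table, it):
        raise ValueError("genotype counts must be integers")
    return it


def mle_frequencies(counts: GenotypeCounts) -> FrequencyEstimate:
    """Maximum-likelihood allele and genotype frequencies from counts."""
    if counts.N <= 0:
        raise ValueError("cannot estimate frequencies from an empty sample")
    n_loci = 1 if counts.table.ndim == 2 else 2
    p_list: list[np.ndarray] = []
    for locus in range(n_loci):
        tallies = _int_table(counts.allele_counts(locus))
        p = np.array([nj / (2 * counts.N) for nj in tallies], dtype=float)
        if np.any(p == 1.0):
            logger.warning("locus is monomorphic (an allele has frequency 1)")
        p_list.append(p)
    p_geno = counts.table / counts.N
    return FrequencyEstimate(p=p_list, p_geno=p_geno, N=counts.N)


def hwd_coefficients(counts: GenotypeCounts) -> np.ndarray:
    """One-locus HWD measures ``D_jj = p_jj - p_j^2``, ``D_jk = p_jk/2 - p_j p_k``.

    Rows and columns sum to zero: ``sum_j D_jk = 0`` for every ``k``.
    Computed exactly from integer counts, floated at the end.
    """
    if counts.table.ndim != 2:
        raise ValueError("hwd_coefficients expects one-locus counts; "
                         "use joint_hwd_coefficients for two loci")
    tab = _int_table(counts.table)
    m = tab.shape[0]
    N = counts.N
    tallies = tab.sum(axis=1) + np.diag(tab)
    p = [Fraction(int(t), 2 * N) for t in tallies]
    D = np.empty((m, m))
    for j in range(m):
        for k in range(j, m):
            if j == k:
                d = Fraction(int(tab[j, j]), N) - p[j] * p[j]
            else:
                d = Fraction(int(tab[j, k]), 2 * N) - p[j] * p[k]
            D[j, k] = D[k, j] = float(d)
    return D


def joint_hwd_coefficients(counts: GenotypeCounts) -> np.ndarray:
    """Two-locus joint disequilibrium ``D_jkrs``.

    ``D_jkrs = p_jkrs / ((2 - 1{j=k})(2 - 1{r=s})) - p_1j p_1k p_2r p_2s``;
    all zero when both loci are at exact HWE and independent.
    """
    if counts.table.ndim != 4:
        raise ValueError("joint_hwd_coefficients expects two-locus counts")
    tab = _int_table(counts.table)
    m1, _, m2, _ = tab.shape
    N = counts.N
    t1 = _int_table(counts.allele_counts(0))
    t2 = _int_table(counts.allele_counts(1))
    p1 = [Fraction(int(t), 2 * N) for t in t1]
    p2 = [Fraction(int(t), 2 * N) for t in t2]
    D = np.empty((m1, m1, m2, m2))
    for j in range(m1):
        for k in range(m1):
            for r in range(m2):
                for s in range(m2):
                    mult = (2 - (j == k)) * (2 - (r == s))
                    d = Fraction(int(tab[j, k, r, s]), N * mult) - p1[j] * p1[k] * p2[r] * p2[s]
                    D[j, k, r, s] = float(d)
    return D
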