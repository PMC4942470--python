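"""Genotype coding variables for unphased genotypes.

Two schemes are supported for a locus with alleles ``A_1..A_m`` (reference
``A_m`` last):

* GLM dummy coding: ``w_j`` counts copies of ``A_j`` (0/1/2) and ``v_jk`` is
  the indicator of genotype ``{A_j, A_k}``.
* GMA mean-corrected coding: ``w*_j = w_j - 2 p_j`` and the centered products
  ``v*_jj = v_jj - p_j w_j + p_j^2``,
  ``v*_jk = v_jk - p_j w_k - p_k w_j + 2 p_j p_k`` (j != k).

The latent per-parent allele indicators ``z_1j, z_2j`` (and their centered
versions ``x_1j, x_2j``) cannot be evaluated on unphased heterozygotes, so
they are never materialized; only the symmetric combinations above are.
Columns for the reference allele are redundant (``w*_m = -sum_{j<m} w*_j``,
``v*_mm = sum_{j<=k<m} v*_jk``) and are excluded from model matrices.

Two-locus epistatic codes are elementwise products of per-locus codes, in the
fixed block order A1, D1, A2, D2, A1A2, A1D2, D1A2, D1D2.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data import Locus

GLM = "glm"
GMA = "gma"
ONE_LOCUS_BLOCKS = ("A", "D")
TWO_LOCUS_BLOCKS = ("A1", "D1", "A2", "D2", "AA", "AD", "DA", "DD")


def pair_indices(q: int) -> list[tuple[int, int]]:
    """Unordered pairs ``(j, k)``, ``j <= k``, over ``range(q)`` in row order."""
    return [(j, k) for j in range(q) for k in range(j, q)]


def w_matrix(g: np.ndarray, m: int) -> np.ndarray:
    """Allele-count codes ``w_j`` for all m alleles; shape (N, m)."""
    g = np.asarray(g, dtype=np.int64)
    w = np.zeros((len(g), m))
    np.add.at(w, (np.arange(len(g)), g[:, 0]), 1.0)
    np.add.at(w, (np.arange(len(g)), g[:, 1]), 1.0)
    return w


def v_matrix(g: np.ndarray, m: int) -> np.ndarray:
    """Genotype indicator codes ``v_jk`` for all m alleles; shape (N, m, m).

    ``v[i, j, k] = v[i, k, j] = 1`` iff individual i's genotype is ``{A_j, A_k}``.
    """
    g = np.asarray(g, dtype=np.int64)
    v = np.zeros((len(g), m, m))
    idx = np.arange(len(g))
    v[idx, g[:, 0], g[:, 1]] = 1.0
    v[idx, g[:, 1], g[:, 0]] = 1.0
    return v


def star_codes(w: np.ndarray, v: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-corrected codes from dummy codes via the algebraic identities."""
    p = np.asarray(p, dtype=float)
    wstar = w - 2.0 * p
    vstar = (
        v
        - p[None, :, None] * w[:, None, :]
        - p[None, None, :] * w[:, :, None]
        + 2.0 * np.outer(p, p)[None, :, :]
    )
    # the diagonal follows a different identity: v*_jj = v_jj - p_j w_j + p_j^2
    diag = v[:, np.arange(len(p)), np.arange(len(p))] - p * w + p**2
    vstar[:, np.arange(len(p)), np.arange(len(p))] = diag
    return wstar, vstar


def full_codes(
    g: np.ndarray, m: int, p: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """``(w, v)`` dummy codes, or ``(w*, v*)`` when frequencies are given."""
    w = w_matrix(g, m)
    v = v_matrix(g, m)
    if p is None:
        return w, v
    return star_codes(w, v, p)


def locus_blocks(
    g: np.ndarray, m: int, coding: str = GMA, p: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Reduced (reference-excluded) A and D code blocks for one locus.

    Returns ``(A, D)`` of shapes (N, m-1) and (N, m(m-1)/2) following the
    canonical pair order of :func:`pair_indices`.
    """
    if coding == GMA:
        if p is None:
            raise ValueError("GMA coding requires allele frequencies")
        w, v = full_codes(g, m, np.asarray(p, float))
    elif coding == GLM:
        w, v = full_codes(g, m)
    else:
        raise ValueError(f"unknown coding {coding!r}")
    q = m - 1
    pairs = pair_indices(q)
    A = w[:, :q]
    D = np.stack([v[:, j, k] for j, k in pairs], axis=1) if pairs else np.empty((len(g), 0))
    return A, D


def two_locus_blocks(
    g1: np.ndarray,
    g2: np.ndarray,
    ms: Sequence[int],
    coding: str = GMA,
    freqs: Sequence[np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """All eight code blocks for a two-locus model, keyed by block name."""
    p1 = p2 = None
    if coding == GMA:
        if freqs is None:
            raise ValueError("GMA coding requires allele frequencies")
        p1, p2 = freqs
    A1, D1 = locus_blocks(g1, ms[0], coding, p1)
    A2, D2 = locus_blocks(g2, ms[1], coding, p2)

    def cross(left: np.ndarray, right: np.ndarray) -> np.ndarray:
        return (left[:, :, None] * right[:, None, :]).reshape(len(left), -1)

    return {
        "A1": A1,
        "D1": D1,
        "A2": A2,
        "D2": D2,
        "AA": cross(A1, A2),
        "AD": cross(A1, D2),
        "DA": cross(D1, A2),
        "DD": cross(D1, D2),
    }


# ---------------------------------------------------------------------------
# scalar case-table evaluation (the piecewise definitions); used as an
# independent cross-check of the vectorized identity-based codes
# ---------------------------------------------------------------------------


def glm_codes(genotype: Sequence[str], locus: Locus) -> dict[str, float]:
    """Dummy codes ``w_j``, ``v_jk`` (j, k < m) for a single genotype."""
    a, b = (locus.index(x) for x in genotype)
    q = locus.m - 1
    out: dict[str, float] = {}
    for j in range(q):
        out[f"w_{locus.name}_{locus.alleles[j]}"] = float((a == j) + (b == j))
    for j, k in pair_indices(q):
        hit = {a, b} == {j, k} if j != k else (a == j and b == j)
        out[f"v_{locus.name}_{locus.alleles[j]}{locus.alleles[k]}"] = float(hit)
    return out


def gma_codes(
    genotype: Sequence[str], locus: Locus, freqs: Sequence[float]
) -> dict[str, float]:
    """Mean-corrected codes ``w*_j``, ``v*_jk`` via the piecewise case tables."""
    p = np.asarray(freqs, dtype=float)
    a, b = (locus.index(x) for x in genotype)
    q = locus.m - 1
    out: dict[str, float] = {}
    for j in range(q):
        copies = (a == j) + (b == j)
        if copies == 2:
            val = 2.0 * (1.0 - p[j])
        elif copies == 1:
            val = 1.0 - 2.0 * p[j]
        else:
            val = -2.0 * p[j]
        out[f"w*_{locus.name}_{locus.alleles[j]}"] = val
    for j, k in pair_indices(q):
        label = f"v*_{locus.name}_{locus.alleles[j]}{locus.alleles[k]}"
        if j == k:
            copies = (a == j) + (b == j)
            if copies == 2:
                val = (1.0 - p[j]) ** 2
            elif copies == 1:
                val = -p[j] * (1.0 - p[j])
            else:
                val = p[j] ** 2
        else:
            gset = {a, b}
            if gset == {j, k}:
                val = (1.0 - p[j]) * (1.0 - p[k]) + p[j] * p[k]
            elif a == j and b == j:
                val = -2.0 * p[k] * (1.0 - p[j])
            elif a == k and b == k:
                val = -2.0 * p[j] * (1.0 - p[k])
            elif j in gset:
                val = -p[k] * (1.0 - 2.0 * p[j])
            elif k in gset:
                val = -p[j] * (1.0 - 2.0 * p[k])
            else:
                val = 2.0 * p[j] * p[k]
        out[label] = val
    return out


def two_locus_codes(
    genotypes: Sequence[Sequence[str]],
    loci: Sequence[Locus],
    freqs: Sequence[Sequence[float]] | None = None,
    coding: str = GMA,
) -> dict[str, float]:
    """Full epistatic coding vector for one individual at two loci."""
    if coding == GMA:
        if freqs is None:
            raise ValueError("GMA coding requires allele frequencies")
        per = [gma_codes(g, loc, p) for g, loc, p in zip(genotypes, loci, freqs)]
    else:
        per = [glm_codes(g, loc) for g, loc in zip(genotypes, loci)]
    out: dict[str, float] = {}
    for d in per:
        out.update(d)
    for l1, v1 in per[0].items():
        for l2, v2 in per[1].items():
            out[f"{l1}:{l2}"] = v1 * v2
    return out


def block_labels(
    loci: Sequence[Locus], coding: str = GMA
) -> dict[str, list[str]]:
    """Canonical column labels per block, matching the design-matrix order."""
    star = "*" if coding == GMA else ""
    per: list[tuple[list[str], list[str]]] = []
    for loc in loci:
        q = loc.m - 1
        wlab = [f"w{star}_{loc.name}_{loc.alleles[j]}" for j in range(q)]
        vlab = [
            f"v{star}_{loc.name}_{loc.alleles[j]}{loc.alleles[k]}"
            for j, k in pair_indices(q)
        ]
        per.append((wlab, vlab))
    if len(loci) == 1:
        return {"A": per[0][0], "D": per[0][1]}
    (w1, v1), (w2, v2) = per

    def cross(left: list[str], right: list[str]) -> list[str]:
        return [f"{a}:{b}" for a in left for b in right]

    return {
        "A1": w1,
        "D1": v1,
        "A2": w2,
        "D2": v2,
        "AA": cross(w1, w2),
        "AD": cross(w1, v2),
        "DA": cross(v1, w2),
        "DD": cross(v1, v2),
    }
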