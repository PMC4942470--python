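"""Exact transformations among GLM, GMA and Fisher parameterizations.

All three parameterizations are full re-parameterizations of the genotypic
value table ``G_jk`` (one locus) or ``G_jkrs`` (two loci), so every map is
routed through that table:

* evaluation — build the table from a parameter set by evaluating the model
  at every genotype cell (using the coding module);
* extraction — recover a parameter set from the table.

Extraction is uniform across flavors.  Writing ``E_a`` for contraction of an
allele index with a weight vector and ``R_a`` for the reference difference
``f[j] - f[m-1]``, each GLM/GMA effect array is ``(prod_a R_a)`` applied to
the table contracted over all uninvolved indices, where the contraction
weights are the allele frequencies (GMA) or a point mass on the reference
allele (GLM; contraction then just slices at the reference).  For example the
one-locus additive effects are ``alpha*_j = ybar_j.* - ybar_m.*`` under GMA
and ``a_j = G_jm - G_mm`` under GLM.  The Fisher flavor instead performs the
frequency-weighted factorial ANOVA decomposition over all m alleles, which
satisfies the classical zero-sum constraints by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import coding
from .params import FisherParams, GLMParams, GMAParams, ModelParams


@dataclass
class GenotypicValueTable:
    """Expected genotypic values per genotype cell, with attached frequencies.

    ``values`` is an (m, m) or (m1, m1, m2, m2) array symmetric in each
    locus's allele pair.
    """

    values: np.ndarray
    freqs: list[np.ndarray]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 2:
            if not np.allclose(v, v.T, equal_nan=True):
                raise ValueError("G_jk must be symmetric")
        elif v.ndim == 4:
            if not np.allclose(v, np.swapaxes(v, 0, 1), equal_nan=True) or not np.allclose(
                v, np.swapaxes(v, 2, 3), equal_nan=True
            ):
                raise ValueError("G_jkrs must be symmetric within each locus")
        else:
            raise ValueError("values must be a 2- or 4-index array")
        self.values = v
        self.freqs = [np.asarray(p, dtype=float) for p in self.freqs]

    @property
    def n_loci(self) -> int:
        return 1 if self.values.ndim == 2 else 2


# ---------------------------------------------------------------------------
# evaluation: params -> genotypic values
# ---------------------------------------------------------------------------


def params_to_genotypic_values(
    params: ModelParams, freqs: Sequence[np.ndarray]
) -> GenotypicValueTable:
    """Evaluate a model at every genotype cell.

    ``freqs`` are the population allele frequencies; they enter the
    mean-corrected codes (GMA) and the constrained evaluation is independent
    of them (GLM, Fisher), but they are attached to the output table either
    way because downstream extraction needs a frequency set.
    """
    freqs = [np.asarray(p, dtype=float) for p in freqs]
    ms = params.m
    if params.flavor == "fisher":
        values = _evaluate_fisher(params)
        return GenotypicValueTable(values=values, freqs=freqs)
    vec = params.to_vector()
    if len(ms) == 1:
        cells = np.array(coding.pair_indices(ms[0]))
        A, D = coding.locus_blocks(cells, ms[0], params.flavor, freqs[0])
        X = np.column_stack([np.ones(len(cells)), A, D])
        vals = X @ vec
        table = np.full((ms[0],) * 2, np.nan)
        for (j, k), g in zip(cells, vals):
            table[j, k] = table[k, j] = g
    else:
        cells1 = coding.pair_indices(ms[0])
        cells2 = coding.pair_indices(ms[1])
        grid = [(c1, c2) for c1 in cells1 for c2 in cells2]
        g1 = np.array([c1 for c1, _ in grid])
        g2 = np.array([c2 for _, c2 in grid])
        blocks = coding.two_locus_blocks(g1, g2, ms, params.flavor, freqs)
        X = np.column_stack(
            [np.ones(len(grid))] + [blocks[b] for b in coding.TWO_LOCUS_BLOCKS]
        )
        vals = X @ vec
        table = np.full((ms[0], ms[0], ms[1], ms[1]), np.nan)
        for ((j, k), (r, s)), g in zip(grid, vals):
            for jj, kk in {(j, k), (k, j)}:
                for rr, ss in {(r, s), (s, r)}:
                    table[jj, kk, rr, ss] = g
    return GenotypicValueTable(values=table, freqs=freqs)


def _evaluate_fisher(params: FisherParams) -> np.ndarray:
    e = params.effects
    if params.n_loci == 1:
        a, d = e["A"], e["D"]
        return params.mu + a[:, None] + a[None, :] + d
    a1, d1, a2, d2 = e["A1"], e["D1"], e["A2"], e["D2"]
    aa, ad, da, dd = e["AA"], e["AD"], e["DA"], e["DD"]
    G = np.zeros((params.m[0],) * 2 + (params.m[1],) * 2)
    G += params.mu
    G += a1[:, None, None, None] + a1[None, :, None, None]
    G += d1[:, :, None, None]
    G += a2[None, None, :, None] + a2[None, None, None, :]
    G += d2[None, None, :, :]
    G += (
        aa[:, None, :, None]
        + aa[:, None, None, :]
        + aa[None, :, :, None]
        + aa[None, :, None, :]
    )
    G += ad[:, None, :, :] + ad[None, :, :, :]
    G += da[:, :, :, None] + da[:, :, None, :]
    G += dd
    return G


# ---------------------------------------------------------------------------
# extraction: genotypic values -> params
# ---------------------------------------------------------------------------


def _ref_diff(arr: np.ndarray, axis: int) -> np.ndarray:
    """Reference difference along one axis: ``f[..., j, ...] - f[..., m-1, ...]``.

    The result's axis runs over the m-1 non-reference alleles.
    """
    q = arr.shape[axis] - 1
    head = np.take(arr, np.arange(q), axis=axis)
    ref = np.take(arr, [q], axis=axis)
    return head - ref


def genotypic_values_to_params(
    G: GenotypicValueTable, target: str, freqs: Sequence[np.ndarray] | None = None
) -> ModelParams:
    """Extract a parameter set of the requested flavor from a complete table."""
    freqs = G.freqs if freqs is None else [np.asarray(p, float) for p in freqs]
    if np.isnan(G.values).any():
        raise ValueError("genotypic value table has empty (NaN) cells")
    if target == "fisher":
        return _extract_fisher(G.values, freqs)
    if target not in ("glm", "gma"):
        raise ValueError(f"unknown target flavor {target!r}")
    weights = []
    for p, msize in zip(freqs, (G.values.shape[0],) + ((G.values.shape[2],) if G.n_loci == 2 else ())):
        if target == "gma":
            weights.append(p)
        else:
            w = np.zeros(msize)
            w[-1] = 1.0  # point mass on the reference allele
            weights.append(w)
    cls = GMAParams if target == "gma" else GLMParams
    V = G.values
    if G.n_loci == 1:
        w = weights[0]
        mu = float(w @ V @ w)
        col = V @ w
        A = _ref_diff(col, 0)
        D = _ref_diff(_ref_diff(V, 0), 1)
        return cls(mu=mu, effects={"A": A, "D": D}, m=(V.shape[0],))
    w1, w2 = weights
    mu = float(np.einsum("jkrs,j,k,r,s->", V, w1, w1, w2, w2))
    cJ = np.einsum("jkrs,k,r,s->j", V, w1, w2, w2)
    cR = np.einsum("jkrs,j,k,s->r", V, w1, w1, w2)
    cJK = np.einsum("jkrs,r,s->jk", V, w2, w2)
    cRS = np.einsum("jkrs,j,k->rs", V, w1, w1)
    cJR = np.einsum("jkrs,k,s->jr", V, w1, w2)
    cJRS = np.einsum("jkrs,k->jrs", V, w1)
    cJKR = np.einsum("jkrs,s->jkr", V, w2)
    eff = {
        "A1": _ref_diff(cJ, 0),
        "A2": _ref_diff(cR, 0),
        "D1": _ref_diff(_ref_diff(cJK, 0), 1),
        "D2": _ref_diff(_ref_diff(cRS, 0), 1),
        "AA": _ref_diff(_ref_diff(cJR, 0), 1),
        "AD": _ref_diff(_ref_diff(_ref_diff(cJRS, 0), 1), 2),
        "DA": _ref_diff(_ref_diff(_ref_diff(cJKR, 0), 1), 2),
        "DD": _ref_diff(_ref_diff(_ref_diff(_ref_diff(V, 0), 1), 2), 3),
    }
    return cls(mu=mu, effects=eff, m=(V.shape[0], V.shape[2]))


def _extract_fisher(V: np.ndarray, freqs: Sequence[np.ndarray]) -> FisherParams:
    """Frequency-weighted factorial ANOVA decomposition of the value table."""
    if V.ndim == 2:
        p = freqs[0]
        mu = float(p @ V @ p)
        alpha = V @ p - mu
        delta = V - alpha[:, None] - alpha[None, :] - mu
        return FisherParams(mu=mu, effects={"A": alpha, "D": delta}, m=(V.shape[0],))
    p1, p2 = freqs
    mu = float(np.einsum("jkrs,j,k,r,s->", V, p1, p1, p2, p2))
    a1 = np.einsum("jkrs,k,r,s->j", V, p1, p2, p2) - mu
    a2 = np.einsum("jkrs,j,k,s->r", V, p1, p1, p2) - mu
    d1 = np.einsum("jkrs,r,s->jk", V, p2, p2) - a1[:, None] - a1[None, :] - mu
    d2 = np.einsum("jkrs,j,k->rs", V, p1, p1) - a2[:, None] - a2[None, :] - mu
    aa = np.einsum("jkrs,k,s->jr", V, p1, p2) - a1[:, None] - a2[None, :] - mu
    ad = (
        np.einsum("jkrs,k->jrs", V, p1)
        - mu
        - a1[:, None, None]
        - a2[None, :, None]
        - a2[None, None, :]
        - d2[None, :, :]
        - aa[:, :, None]
        - aa[:, None, :]
    )
    da = (
        np.einsum("jkrs,s->jkr", V, p2)
        - mu
        - a1[:, None, None]
        - a1[None, :, None]
        - d1[:, :, None]
        - a2[None, None, :]
        - aa[:, None, :]
        - aa[None, :, :]
    )
    dd = (
        V
        - mu
        - a1[:, None, None, None]
        - a1[None, :, None, None]
        - d1[:, :, None, None]
        - a2[None, None, :, None]
        - a2[None, None, None, :]
        - d2[None, None, :, :]
        - aa[:, None, :, None]
        - aa[:, None, None, :]
        - aa[None, :, :, None]
        - aa[None, :, None, :]
        - ad[:, None, :, :]
        - ad[None, :, :, :]
        - da[:, :, :, None]
        - da[:, :, None, :]
    )
    return FisherParams(
        mu=mu,
        effects={"A1": a1, "D1": d1, "A2": a2, "D2": d2, "AA": aa, "AD": ad, "DA": da, "DD": dd},
        m=(V.shape[0], V.shape[2]),
    )


# ---------------------------------------------------------------------------
# convenience maps
# ---------------------------------------------------------------------------


def convert(params: ModelParams, target: str, freqs: Sequence[np.ndarray]) -> ModelParams:
    """Convert between any two flavors via the genotypic-value table."""
    table = params_to_genotypic_values(params, freqs)
    return genotypic_values_to_params(table, target)


def glm_to_gma(params: GLMParams, freqs: Sequence[np.ndarray]) -> GMAParams:
    return convert(params, "gma", freqs)


def gma_to_glm(params: GMAParams, freqs: Sequence[np.ndarray]) -> GLMParams:
    return convert(params, "glm", freqs)


def glm_to_gma_one_locus_map(params: GLMParams, p: np.ndarray) -> GMAParams:
    """The printed one-locus closed-form map (cross-check for :func:`glm_to_gma`).

    ``mu* = mu_0 + 2 sum_j p_j a_j + sum_jk p_j p_k d_jk``,
    ``alpha*_j = a_j + sum_k p_k d_jk``, ``delta*_jk = d_jk`` with sums over
    the m-1 non-reference alleles and ``d`` symmetric.
    """
    if params.n_loci != 1:
        raise ValueError("closed-form map is one-locus")
    p = np.asarray(p, dtype=float)
    a = params.effects["A"]
    d = params.effects["D"]
    pq = p[: len(a)]
    mu = params.mu + 2.0 * pq @ a + pq @ d @ pq
    alpha = a + d @ pq
    return GMAParams(mu=mu, effects={"A": alpha, "D": d.copy()}, m=params.m)
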