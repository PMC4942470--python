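"""Genetic variance-component estimation.

Components are the per-individual block values of a fitted model, e.g. the
additive component ``A_i = sum_j alpha*_j w*_j(g_i)``.  Their sample
variances (denominator N) estimate the variance components, their pairwise
sample covariances the confounding between components, and

    V(E(G|g)) = sum_c V_c + 2 sum_{c<c'} Cov(c, c').

Under the GMA coding with all sample disequilibrium coefficients zero the
partition is orthogonal (covariances vanish) and ``V_Y = V_A + V_D + V_eps``
holds exactly; the GLM dummy coding leaves a large covariance share.  Exact
population values for a known genotypic-value table and genotype distribution
are computed by enumeration over genotype cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import coding
from .convert import GenotypicValueTable, genotypic_values_to_params
from .data import GenotypeDataset, GroupMeans
from .fit import FitResult


@dataclass
class VarCompResult:
    """Variance components, their covariances and derived totals.

    ``components`` maps block name to variance; ``cov`` is the full component
    covariance matrix in block order; ``V_G`` is the (estimated or exact)
    genotypic variance; ``covariance_fraction = 1 - sum(components)/V_G`` is
    the share of V_G attributable to confounding between components.
    """

    components: dict[str, float]
    cov: np.ndarray
    V_G: float
    V_eps: float | None = None
    V_Y: float | None = None

    @property
    def total_component_variance(self) -> float:
        return float(sum(self.components.values()))

    @property
    def covariance_fraction(self) -> float:
        return 1.0 - self.total_component_variance / self.V_G

    @property
    def shares(self) -> dict[str, float]:
        """Percentage of V_G contributed by each component."""
        return {b: 100.0 * v / self.V_G for b, v in self.components.items()}


def fitted_components(fit: FitResult) -> dict[str, np.ndarray]:
    """Per-individual fitted component values, one array per block."""
    out = {}
    for b in fit.design.spec.blocks:
        cols = fit.design.block_cols[b]
        out[b] = fit.design.X[:, cols] @ fit.beta[cols]
    return out


def varcomp_from_fit(fit: FitResult) -> VarCompResult:
    """Estimate variance/covariance components from a fitted model.

    Sample variances and covariances use denominator N, which is what makes
    the decomposition ``V_Y = V_A + V_D + V_eps`` exact for orthogonal fits.
    """
    comps = fitted_components(fit)
    names = list(comps)
    mat = np.column_stack([comps[b] for b in names])
    n = mat.shape[0]
    centered = mat - mat.mean(axis=0)
    cov = centered.T @ centered / n
    components = {b: float(cov[i, i]) for i, b in enumerate(names)}
    total_genetic = mat.sum(axis=1)
    V_G = float(np.var(total_genetic))
    y = fit.fitted + fit.residuals
    V_Y = float(np.var(y))
    if fit.design.spec.saturated:
        V_eps = fit.sse / n
    else:
        V_eps = fit.mse
    return VarCompResult(components=components, cov=cov, V_G=V_G, V_eps=float(V_eps), V_Y=V_Y)


def varcomp_hwe_closed_form(
    means: GroupMeans, freqs: np.ndarray | None = None
) -> tuple[float, float]:
    """Closed-form one-locus estimators valid at Hardy-Weinberg equilibrium.

    ``V_A = 2 sum_j p_j (ybar_j.* - ybar..*)^2`` and
    ``V_D = sum_jk p_j p_k (ybar_jk - ybar..*)^2 - V_A``; both non-negative.
    """
    if means.n_loci != 1:
        raise ValueError("one-locus means required")
    empty = means.empty_cells()
    if empty:
        raise ValueError(f"empty genotype cells: {empty}")
    p = means.freqs[0] if freqs is None else np.asarray(freqs, dtype=float)
    yj = means.means @ p
    ybar = float(p @ yj)
    V_A = 2.0 * float(p @ (yj - ybar) ** 2)
    V_D = float(np.einsum("j,k,jk->", p, p, (means.means - ybar) ** 2)) - V_A
    return V_A, V_D


def residual_and_total(fit: FitResult) -> tuple[float, float]:
    """``V_eps`` (within-cell SS / N for saturated fits, else MSE) and ``V_Y``."""
    y = fit.fitted + fit.residuals
    n = len(y)
    V_Y = float(np.var(y))
    V_eps = fit.sse / n if fit.design.spec.saturated else fit.mse
    return float(V_eps), V_Y


def _genotype_prob_vector(prob: np.ndarray) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Unordered genotype cells and their probabilities from a symmetric table."""
    if prob.ndim == 2:
        cells = coding.pair_indices(prob.shape[0])
        w = np.array([prob[j, k] for j, k in cells])
    else:
        c1 = coding.pair_indices(prob.shape[0])
        c2 = coding.pair_indices(prob.shape[2])
        cells = [(j, k, r, s) for j, k in c1 for r, s in c2]
        w = np.array([prob[c] for c in cells])
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("genotype probabilities must be non-negative and sum to 1")
    return cells, w


def allele_freqs_from_probs(prob: np.ndarray) -> list[np.ndarray]:
    """Marginal allele frequencies ``p_j = p_jj + sum_{k!=j} p_jk / 2``."""
    def one(tab: np.ndarray) -> np.ndarray:
        return (tab.sum(axis=1) + np.diag(tab)) / 2.0

    if prob.ndim == 2:
        return [one(prob)]
    iu2 = np.triu_indices(prob.shape[2])
    tab1 = prob[:, :, iu2[0], iu2[1]].sum(axis=2)
    iu1 = np.triu_indices(prob.shape[0])
    tab2 = prob[iu1[0], iu1[1], :, :].sum(axis=0)
    return [one(tab1), one(tab2)]


def true_varcomp_enumeration(
    G: GenotypicValueTable,
    prob: np.ndarray,
    flavor: str = coding.GMA,
    freqs: Sequence[np.ndarray] | None = None,
) -> VarCompResult:
    """Exact population variance components by enumeration over genotype cells.

    ``prob`` is a symmetric genotype probability table matching the layout of
    the count tables (``prob[j, k]`` is the probability of unordered genotype
    ``{A_j, A_k}``).  Components are defined by the parameters of the
    requested flavor extracted at ``freqs`` (the distribution's own allele
    frequencies by default), mirroring the sample-based estimators.
    """
    prob = np.asarray(prob, dtype=float)
    if prob.shape != G.values.shape:
        raise ValueError("probability table shape must match the value table")
    if freqs is None:
        freqs = allele_freqs_from_probs(prob)
    params = genotypic_values_to_params(G, flavor, freqs)
    cells, w = _genotype_prob_vector(prob)
    ms = params.m
    if len(ms) == 1:
        g = np.array([(j, k) for j, k in cells])
        A, D = coding.locus_blocks(g, ms[0], flavor, freqs[0])
        block_arrays = {"A": A, "D": D}
    else:
        g1 = np.array([(j, k) for j, k, _, _ in cells])
        g2 = np.array([(r, s) for _, _, r, s in cells])
        block_arrays = coding.two_locus_blocks(g1, g2, ms, flavor, freqs)
    names = list(params.blocks)
    vals = np.column_stack(
        [block_arrays[b] @ params.block_vector(b) for b in names]
    )
    mean = w @ vals
    centered = vals - mean
    cov = centered.T @ (w[:, None] * centered)
    components = {b: float(cov[i, i]) for i, b in enumerate(names)}
    gvals = np.array([G.values[c] for c in cells])
    V_G = float(w @ (gvals - w @ gvals) ** 2)
    return VarCompResult(components=components, cov=cov, V_G=V_G)
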