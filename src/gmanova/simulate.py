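"""Genotype/phenotype simulator matching the method's sampling assumptions.

Genotypes are i.i.d. multinomial draws from a genotype-frequency table —
Hardy-Weinberg proportions by default, optionally perturbed by disequilibrium
coefficients (``p_jj = p_j^2 + D_jj``, ``p_jk = 2(p_j p_k + D_jk)``) or given
directly.  Two loci are drawn independently unless a joint table is supplied.
Phenotypes are ``y_i = G(g_i) + eps_i`` with Gaussian residuals independent
of the genotypes.

``default_study_config`` returns the reference simulation design used
throughout the test suite: two biallelic loci with allele-1 frequencies 0.4
and 0.2 under HWE and independence, a GLM with mu_0 = 10 and the five unit
effects a_11 = a_21 = d_111 = d_211 = (aa)_11 = 1, and residual variance
V_eps = 17.51 (a broad-sense heritability of about 15%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .convert import params_to_genotypic_values
from .data import GenotypeDataset, Locus
from .params import GLMParams, ModelParams


@dataclass
class SimulationConfig:
    """Generative model: loci, genotype distribution, true params, residual.

    Exactly one of ``V_eps`` / ``H2`` must be set; ``H2`` is converted to a
    residual variance from the exact genotypic variance at run time.
    """

    loci: list[Locus]
    params: ModelParams
    V_eps: float | None = None
    H2: float | None = None
    n: int = 1000
    replicates: int = 1
    seed: int | None = None
    hwd: list[np.ndarray | None] | None = None
    joint_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.V_eps is None) == (self.H2 is None):
            raise ValueError("set exactly one of V_eps or H2")
        if self.V_eps is not None and self.V_eps < 0:
            raise ValueError("V_eps must be non-negative")
        if self.H2 is not None and not 0.0 < self.H2 < 1.0:
            raise ValueError("H2 must lie in (0, 1)")
        for locus in self.loci:
            if locus.freqs is None:
                raise ValueError(f"locus {locus.name!r} needs allele frequencies")

    def residual_variance(self) -> float:
        if self.V_eps is not None:
            return float(self.V_eps)
        from .varcomp import true_varcomp_enumeration

        prob = self.genotype_probs()
        table = params_to_genotypic_values(self.params, [l.freqs for l in self.loci])
        V_G = true_varcomp_enumeration(table, prob).V_G
        return heritability_to_residual(V_G, self.H2)

    def genotype_probs(self) -> np.ndarray:
        if self.joint_probs is not None:
            return np.asarray(self.joint_probs, dtype=float)
        tabs = []
        for i, locus in enumerate(self.loci):
            D = None if self.hwd is None else self.hwd[i]
            tabs.append(genotype_probs_one_locus(locus.freqs, D))
        if len(tabs) == 1:
            return tabs[0]
        return np.einsum("jk,rs->jkrs", tabs[0], tabs[1])


def genotype_probs_one_locus(
    p: np.ndarray, D: np.ndarray | None = None
) -> np.ndarray:
    """Symmetric genotype probability table from allele freqs (+ optional HWD).

    ``prob[j, j] = p_j^2 + D_jj`` and ``prob[j, k] = 2 (p_j p_k + D_jk)`` for
    ``j != k`` (the unordered heterozygote probability, stored in both cells
    halved so that the table mirrors the count-table layout: the full
    unordered probability sits at ``[j, k]`` with ``j <= k``).
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    prob = np.outer(p, p)
    if D is not None:
        D = np.asarray(D, dtype=float)
        if D.shape != (m, m):
            raise ValueError("D table must be (m, m)")
        if not np.allclose(D, D.T):
            raise ValueError("D table must be symmetric")
        if np.max(np.abs(D.sum(axis=0))) > 1e-9:
            raise ValueError("D rows/columns must sum to zero")
        prob = prob + D
    prob = prob * (2.0 - np.eye(m))
    sel = prob[np.triu_indices(m)]
    if np.any(sel < 0) or np.any(sel > 1):
        raise ValueError("allele frequencies and D do not form a valid distribution")
    return prob


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator
) -> GenotypeDataset:
    """Draw i.i.d. genotypes from the configured genotype distribution."""
    prob = config.genotype_probs()
    if len(config.loci) == 1:
        cells = [(j, k) for j in range(prob.shape[0]) for k in range(j, prob.shape[0])]
        w = np.array([prob[c] for c in cells])
        idx = rng.choice(len(cells), size=config.n, p=w / w.sum())
        g = np.array(cells)[idx]
        return GenotypeDataset(loci=list(config.loci), genotypes=[g])
    m1, _, m2, _ = prob.shape
    c1 = [(j, k) for j in range(m1) for k in range(j, m1)]
    c2 = [(r, s) for r in range(m2) for s in range(r, m2)]
    cells = [(jk, rs) for jk in c1 for rs in c2]
    w = np.array([prob[jk + rs] for jk, rs in cells])
    idx = rng.choice(len(cells), size=config.n, p=w / w.sum())
    g1 = np.array([cells[i][0] for i in range(len(cells))])[idx]
    g2 = np.array([cells[i][1] for i in range(len(cells))])[idx]
    return GenotypeDataset(loci=list(config.loci), genotypes=[g1, g2])


def simulate_phenotypes(
    dataset: GenotypeDataset,
    params: ModelParams,
    V_eps: float,
    rng: np.random.Generator,
    freqs: Sequence[np.ndarray] | None = None,
) -> GenotypeDataset:
    """Attach ``y_i = G(g_i) + eps_i`` with ``eps ~ N(0, V_eps)`` i.i.d."""
    if V_eps < 0:
        raise ValueError("V_eps must be non-negative")
    if freqs is None:
        freqs = [l.freqs for l in dataset.loci]
        if any(p is None for p in freqs):
            raise ValueError("population frequencies required to evaluate the model")
    table = params_to_genotypic_values(params, freqs).values
    if dataset.n_loci == 1:
        g = dataset.genotypes[0]
        gvals = table[g[:, 0], g[:, 1]]
    else:
        g1, g2 = dataset.genotypes
        gvals = table[g1[:, 0], g1[:, 1], g2[:, 0], g2[:, 1]]
    y = gvals + (rng.normal(0.0, np.sqrt(V_eps), size=dataset.N) if V_eps > 0 else 0.0)
    return GenotypeDataset(
        loci=dataset.loci, genotypes=dataset.genotypes,
        phenotype=np.asarray(y, dtype=float), covariates=dataset.covariates,
    )


def simulate_dataset(config: SimulationConfig, seed=None) -> GenotypeDataset:
    """One replicate: genotypes plus phenotypes under the configured model."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ds = simulate_genotypes(config, rng)
    return simulate_phenotypes(
        ds, config.params, config.residual_variance(), rng,
        freqs=[l.freqs for l in config.loci],
    )


def replicate_seeds(seed, replicates: int) -> list[np.random.SeedSequence]:
    """Deterministic per-replicate child seeds from one global seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(replicates)


def heritability_to_residual(V_G: float, H2: float) -> float:
    """Residual variance implied by a broad-sense heritability target."""
    if not 0.0 < H2 < 1.0:
        raise ValueError("H2 must lie in (0, 1)")
    return float(V_G) * (1.0 - H2) / H2


def default_study_config(n: int = 1000, seed: int | None = None) -> SimulationConfig:
    """The reference two-locus simulation design (see module docstring)."""
    loci = [
        Locus(name="L1", alleles=("1", "0"), freqs=np.array([0.4, 0.6]), ref_allele="0"),
        Locus(name="L2", alleles=("1", "0"), freqs=np.array([0.2, 0.8]), ref_allele="0"),
    ]
    params = GLMParams(
        mu=10.0,
        effects={
            "A1": [1.0], "D1": [[1.0]], "A2": [1.0], "D2": [[1.0]],
            "AA": [[1.0]], "AD": np.zeros((1, 1, 1)),
            "DA": np.zeros((1, 1, 1)), "DD": np.zeros((1, 1, 1, 1)),
        },
        m=(2, 2),
    )
    return SimulationConfig(loci=loci, params=params, V_eps=17.51, n=n, seed=seed)
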