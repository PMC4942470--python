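"""Design-matrix construction, OLS fitting, closed-form LSE, Type III SS.

The model matrix is ``X = (1_N, Z, X_blocks...)`` with covariates ``Z`` first
and component blocks in canonical order (A, D for one locus; A1, D1, A2, D2,
AA, AD, DA, DD for two).  Under the GMA coding with all sample disequilibrium
coefficients zero, ``X'X`` is block diagonal, so dropping a block leaves the
remaining estimates unchanged; the GLM dummy coding does not share this
property.

Type III sums of squares are computed transparently by refitting the model
without the block (SSR(full) - SSR(reduced)), and the block F-test is
``F = (SS3 / df_block) / MSE`` on (df_block, residual df).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from . import coding
from .convert import GenotypicValueTable, genotypic_values_to_params
from .data import GenotypeDataset, GroupMeans
from .params import GLMParams, GMAParams, ModelParams

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Which model to fit: coding flavor, loci, component blocks, covariates.

    ``freqs`` selects the frequency source for the GMA codes: the string
    ``"estimate"`` (MLE from the same dataset, the default) or an explicit
    list of allele-frequency vectors.
    """

    coding: str = coding.GMA
    n_loci: int = 1
    blocks: tuple[str, ...] | None = None
    covariates: tuple[str, ...] = ()
    freqs: str | Sequence[np.ndarray] = "estimate"

    def __post_init__(self) -> None:
        if self.coding not in (coding.GLM, coding.GMA):
            raise ValueError(f"unknown coding {self.coding!r}")
        all_blocks = coding.ONE_LOCUS_BLOCKS if self.n_loci == 1 else coding.TWO_LOCUS_BLOCKS
        if self.blocks is None:
            self.blocks = tuple(all_blocks)
        else:
            self.blocks = tuple(self.blocks)
            unknown = set(self.blocks) - set(all_blocks)
            if unknown:
                raise ValueError(f"unknown blocks for {self.n_loci} locus model: {sorted(unknown)}")
            # keep canonical order regardless of user order
            self.blocks = tuple(b for b in all_blocks if b in self.blocks)

    @property
    def saturated(self) -> bool:
        full = coding.ONE_LOCUS_BLOCKS if self.n_loci == 1 else coding.TWO_LOCUS_BLOCKS
        return self.blocks == tuple(full) and not self.covariates

    def block_df(self, block: str, ms: Sequence[int]) -> int:
        """Degrees of freedom of a component block (reduced parameterization)."""
        q1 = ms[0] - 1
        q2 = ms[-1] - 1 if len(ms) > 1 else None
        npair1 = q1 * (q1 + 1) // 2
        if self.n_loci == 1:
            return {"A": q1, "D": npair1}[block]
        npair2 = q2 * (q2 + 1) // 2
        return {
            "A1": q1, "D1": npair1, "A2": q2, "D2": npair2,
            "AA": q1 * q2, "AD": q1 * npair2, "DA": npair1 * q2, "DD": npair1 * npair2,
        }[block]


@dataclass
class Design:
    """A labeled design matrix with block column bookkeeping."""

    X: np.ndarray
    labels: list[str]
    block_cols: dict[str, np.ndarray]
    spec: ModelSpec
    freqs: list[np.ndarray]
    dataset: GenotypeDataset


def build_design(dataset: GenotypeDataset, spec: ModelSpec) -> Design:
    """Build the model matrix: intercept, covariates, then component blocks."""
    if spec.n_loci != dataset.n_loci:
        raise ValueError(
            f"spec requests {spec.n_loci} locus/loci but dataset has {dataset.n_loci}"
        )
    freqs: list[np.ndarray]
    if isinstance(spec.freqs, str):
        if spec.freqs != "estimate":
            raise ValueError(f"unknown frequency source {spec.freqs!r}")
        freqs = dataset.estimated_freqs()
    else:
        freqs = [np.asarray(p, dtype=float) for p in spec.freqs]
    n = dataset.N
    cols: list[np.ndarray] = [np.ones((n, 1))]
    labels = ["intercept"]
    block_cols: dict[str, np.ndarray] = {}
    for cov in spec.covariates:
        if dataset.covariates is None or cov not in dataset.covariates:
            raise ValueError(f"covariate {cov!r} not present in dataset")
        cols.append(np.asarray(dataset.covariates[cov], dtype=float)[:, None])
        labels.append(cov)
    if dataset.n_loci == 1:
        A, D = coding.locus_blocks(dataset.genotypes[0], dataset.loci[0].m, spec.coding, freqs[0])
        block_arrays = {"A": A, "D": D}
    else:
        block_arrays = coding.two_locus_blocks(
            dataset.genotypes[0],
            dataset.genotypes[1],
            [l.m for l in dataset.loci],
            spec.coding,
            freqs,
        )
    all_labels = coding.block_labels(dataset.loci, spec.coding)
    pos = sum(c.shape[1] for c in cols)
    for b in spec.blocks:
        arr = block_arrays[b]
        cols.append(arr)
        labels.extend(all_labels[b])
        block_cols[b] = np.arange(pos, pos + arr.shape[1])
        pos += arr.shape[1]
    return Design(
        X=np.hstack(cols), labels=labels, block_cols=block_cols,
        spec=spec, freqs=freqs, dataset=dataset,
    )


@dataclass
class FitResult:
    """OLS fit: coefficients, SSR/MSE, fitted values, per-block Type III SS."""

    design: Design
    beta: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    sse: float
    ssr: float
    mse: float
    df_resid: int
    cov_beta: np.ndarray | None = None
    type3: dict[str, float] = field(default_factory=dict)

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.design.labels, self.beta))

    def block_coefs(self, block: str) -> np.ndarray:
        return self.beta[self.design.block_cols[block]]

    def to_params(self) -> ModelParams:
        """Coefficients as a parameter container (saturated, no covariates)."""
        if not self.design.spec.saturated:
            raise ValueError("parameter extraction requires a saturated no-covariate fit")
        ms = [l.m for l in self.design.dataset.loci]
        cls = GMAParams if self.design.spec.coding == coding.GMA else GLMParams
        return cls.from_vector(self.beta, ms)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), rank


def fit_ols(
    design: Design,
    y: np.ndarray | None = None,
    allow_rank_deficient: bool = False,
    compute_type3: bool = False,
) -> FitResult:
    """Ordinary least squares fit of the design to the phenotype."""
    if y is None:
        if design.dataset.phenotype is None:
            raise ValueError("dataset has no phenotype and no y was supplied")
        y = design.dataset.phenotype
    y = np.asarray(y, dtype=float)
    X = design.X
    n, p = X.shape
    beta, sse, rank = _ols(X, y)
    if rank < p:
        if not allow_rank_deficient:
            raise np.linalg.LinAlgError(
                f"design matrix is rank deficient (rank {rank} < {p} columns); "
                "an empty genotype cell in a saturated model is the usual cause. "
                "Pass allow_rank_deficient=True to fit a pseudoinverse solution."
            )
        logger.warning("rank-deficient design (rank %d < %d); using pseudoinverse", rank, p)
    fitted = X @ beta
    resid = y - fitted
    tss = float(np.sum((y - y.mean()) ** 2))
    ssr = tss - sse
    df_resid = n - rank
    mse = sse / df_resid if df_resid > 0 else np.nan
    cov_beta = None
    if df_resid > 0 and rank == p:
        cov_beta = mse * np.linalg.inv(X.T @ X)
    fit = FitResult(
        design=design, beta=beta, fitted=fitted, residuals=resid,
        sse=sse, ssr=ssr, mse=mse, df_resid=df_resid, cov_beta=cov_beta,
    )
    if compute_type3:
        for b in design.spec.blocks:
            fit.type3[b] = type3_ss(fit, b)
    return fit


def type3_ss(fit: FitResult, block: str) -> float:
    """Partial SS of a block: SSR(full) - SSR(all other terms), by refit."""
    if block not in fit.design.block_cols:
        raise KeyError(f"block {block!r} is not in the fitted model")
    keep = np.setdiff1d(np.arange(fit.design.X.shape[1]), fit.design.block_cols[block])
    y = fit.fitted + fit.residuals
    _, sse_red, _ = _ols(fit.design.X[:, keep], y)
    return float(sse_red - fit.sse)


def group_f_test(fit: FitResult, block: str) -> tuple[float, tuple[int, int], float]:
    """F-test of a whole component block via its Type III SS.

    Testing the average allelic effects of a block tests the existence of the
    corresponding variance component under the GMA coding.
    """
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    scale = fit.sse + fit.ssr  # total SS about the mean
    if not np.isfinite(fit.mse) or fit.mse <= 1e-12 * (scale / max(len(fit.fitted), 1)):
        raise ValueError("saturated or noiseless fit: MSE is zero")
    ss3 = fit.type3.get(block)
    if ss3 is None:
        ss3 = type3_ss(fit, block)
    df1 = len(fit.design.block_cols[block])
    F = (ss3 / df1) / fit.mse
    pval = float(stats.f.sf(F, df1, fit.df_resid))
    return float(F), (df1, fit.df_resid), pval


def anova_table(fit: FitResult):
    """ANOVA-style block table (df, Type III SS, F, p) as a DataFrame."""
    import pandas as pd

    rows = []
    for b in fit.design.spec.blocks:
        F, (df1, df2), pval = group_f_test(fit, b)
        rows.append({"block": b, "df": df1, "type3_ss": fit.type3.get(b) or type3_ss(fit, b),
                     "F": F, "p": pval})
    return pd.DataFrame(rows).set_index("block")


# ---------------------------------------------------------------------------
# closed-form LSE from group means (saturated, no covariates)
# ---------------------------------------------------------------------------


def _check_complete(means: GroupMeans) -> None:
    empty = means.empty_cells()
    if empty:
        raise ValueError(f"empty genotype cells: {empty}; closed-form LSE needs all cells")


def closed_form_lse_one_locus(
    means: GroupMeans, freqs: np.ndarray | None = None
) -> tuple[GMAParams, GLMParams]:
    """Closed-form LSE of the saturated one-locus GMA and GLM models.

    ``mu^* = ybar..*``, ``alpha*_j = ybar_j.* - ybar_m.*``,
    ``delta*_jk = d_jk = ybar_jk - ybar_jm - ybar_km + ybar_mm``; the GLM side
    is ``mu_0 = ybar_mm``, ``a_j = ybar_jm - ybar_mm`` with the same ``d``.
    Identical to the matrix OLS coefficients on the same data.
    """
    if means.n_loci != 1:
        raise ValueError("one-locus means required")
    _check_complete(means)
    p = means.freqs[0] if freqs is None else np.asarray(freqs, dtype=float)
    table = GenotypicValueTable(values=means.means, freqs=[p])
    gma = genotypic_values_to_params(table, "gma")
    glm = genotypic_values_to_params(table, "glm")
    return gma, glm


def closed_form_lse_two_locus(
    means: GroupMeans, freqs: Sequence[np.ndarray] | None = None
) -> tuple[GMAParams, GLMParams]:
    """Closed-form LSE of the saturated two-locus models from weighted means."""
    if means.n_loci != 2:
        raise ValueError("two-locus means required")
    _check_complete(means)
    fr = list(means.freqs) if freqs is None else [np.asarray(p, float) for p in freqs]
    table = GenotypicValueTable(values=means.means, freqs=fr)
    gma = genotypic_values_to_params(table, "gma")
    glm = genotypic_values_to_params(table, "glm")
    return gma, glm
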