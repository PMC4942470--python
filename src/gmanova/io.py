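"""Readers, writers and exact fixtures for genotype/phenotype data.

The native table format is delimited text (TSV/CSV) with one row per
individual: an optional ``sample_id`` column, one column per locus holding
the unordered genotype as ``a/b`` allele labels, a numeric ``phenotype``
column, and optional covariate columns.  Unphased VCF input is supported via
cyvcf2 for up to two sites; phase separators are ignored because the method
is defined on unordered allele pairs.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from math import lcm
from typing import Sequence

import numpy as np
import pandas as pd

from .data import GenotypeDataset, Locus

logger = logging.getLogger(__name__)

_MISSING = {"", "na", "nan", ".", "./.", ".|."}


def _is_missing(value) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return True
    return str(value).strip().lower() in _MISSING


def read_genotype_table(
    path,
    schema: dict | None = None,
    loci: Sequence[Locus] | None = None,
    sep: str | None = None,
) -> GenotypeDataset:
    """Read a delimited genotype/phenotype table.

    ``schema`` maps column roles: ``genotype_cols`` (list of 1-2 column
    names), ``phenotype_col`` (default ``"phenotype"``), ``covariate_cols``,
    ``sample_col`` (default ``"sample_id"``, ignored for modeling).  Without
    an explicit ``genotype_cols`` every non-role column is treated as a
    locus.  Rows with missing genotype or phenotype are dropped with a
    logged count; a non-numeric, non-missing phenotype is a hard error.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, skipinitialspace=True)
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    phen_col = schema.get("phenotype_col", "phenotype")
    sample_col = schema.get("sample_col", "sample_id")
    cov_cols = list(schema.get("covariate_cols", []))
    gt_cols = schema.get("genotype_cols")
    if gt_cols is None:
        reserved = {phen_col, sample_col, *cov_cols}
        gt_cols = [c for c in df.columns if c not in reserved]
    if not 1 <= len(gt_cols) <= 2:
        raise ValueError(f"expected 1-2 genotype columns, got {gt_cols}")
    if phen_col not in df.columns:
        raise ValueError(f"phenotype column {phen_col!r} not found")

    has_phen = df[phen_col].map(lambda v: not _is_missing(v))
    pairs: dict[str, list] = {c: [] for c in gt_cols}
    keep = []
    for i, row in df.iterrows():
        ok = bool(has_phen.loc[i])
        parsed = {}
        for c in gt_cols:
            raw = row[c]
            if _is_missing(raw):
                ok = False
                break
            alleles = str(raw).split("/")
            if len(alleles) != 2:
                raise ValueError(f"row {i}: genotype {raw!r} in column {c!r} is not 'a/b'")
            parsed[c] = tuple(a.strip() for a in alleles)
        if ok:
            keep.append(i)
            for c in gt_cols:
                pairs[c].append(parsed[c])
    dropped = len(df) - len(keep)
    if dropped:
        logger.warning("dropped %d row(s) with missing genotype or phenotype", dropped)
    if not keep:
        raise ValueError(f"no complete data rows in {path}")

    phen = []
    for i in keep:
        raw = df.loc[i, phen_col]
        try:
            phen.append(float(raw))
        except (TypeError, ValueError):
            raise ValueError(f"row {i}: non-numeric phenotype {raw!r}") from None

    built_loci: list[Locus] = []
    genotypes: list[np.ndarray] = []
    for idx, c in enumerate(gt_cols):
        observed = sorted({a for pair in pairs[c] for a in pair})
        if loci is not None:
            locus = loci[idx]
            unknown = set(observed) - set(locus.alleles)
            if unknown:
                raise ValueError(
                    f"column {c!r}: allele(s) {sorted(unknown)} not declared for locus "
                    f"{locus.name!r}"
                )
        else:
            # reference defaults to the most frequent observed allele
            tally = {a: 0 for a in observed}
            for a, b in pairs[c]:
                tally[a] += 1
                tally[b] += 1
            ref = max(observed, key=lambda a: (tally[a], a))
            locus = Locus(name=c, alleles=observed, ref_allele=ref)
        built_loci.append(locus)
        genotypes.append(np.array([[locus.index(a), locus.index(b)] for a, b in pairs[c]]))

    covariates = None
    if cov_cols:
        covariates = df.loc[keep, cov_cols].astype(float).reset_index(drop=True)
    return GenotypeDataset(
        loci=built_loci, genotypes=genotypes,
        phenotype=np.array(phen), covariates=covariates,
    )


def write_genotype_table(dataset: GenotypeDataset, path) -> None:
    """Write a dataset back to TSV; round-trips counts, means and phenotypes."""
    cols: dict[str, list] = {"sample_id": [f"s{i}" for i in range(dataset.N)]}
    for i, locus in enumerate(dataset.loci):
        cols[locus.name] = dataset.genotype_labels(i)
    if dataset.phenotype is not None:
        cols["phenotype"] = [repr(float(v)) for v in dataset.phenotype]
    if dataset.covariates is not None:
        for c in dataset.covariates.columns:
            cols[c] = [repr(float(v)) for v in dataset.covariates[c]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_vcf_unphased(
    path,
    sample_ids: Sequence[str] | None = None,
    site_ids: Sequence[str] | None = None,
) -> GenotypeDataset:
    """Read unphased genotypes for up to two VCF sites.

    Both ``/`` and ``|`` separated GT fields are treated as unordered allele
    pairs — phase information is always discarded.  Individuals with a
    missing GT at any selected site are dropped with a warning.  Alleles are
    labeled by the REF/ALT strings; multi-allelic sites are supported.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=list(sample_ids) if sample_ids else None)
    records = []
    for var in vcf:
        key = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        if site_ids is not None and key not in site_ids and (var.ID or "") not in site_ids:
            continue
        records.append((key, var.REF, list(var.ALT), np.array(var.genotypes)[:, :2]))
    if site_ids is not None and len(records) != len(site_ids):
        found = {k for k, *_ in records}
        raise ValueError(f"sites not found in VCF: {sorted(set(site_ids) - found)}")
    if len(records) > 2:
        raise ValueError(f"{len(records)} sites selected; at most 2 are supported")
    if not records:
        raise ValueError("no sites selected from VCF")

    n = records[0][3].shape[0]
    missing = np.zeros(n, dtype=bool)
    for _, _, _, gts in records:
        missing |= (gts < 0).any(axis=1)
    if missing.any():
        logger.warning("dropped %d individual(s) with missing GT", int(missing.sum()))
    if missing.all():
        raise ValueError("all individuals have missing genotypes at the selected sites")

    loci, genotypes = [], []
    for key, ref, alts, gts in records:
        labels = [ref] + alts
        gts = gts[~missing]
        tallies = np.bincount(gts.ravel(), minlength=len(labels))
        ref_allele = labels[int(np.argmax(tallies))]
        locus = Locus(name=key, alleles=labels, ref_allele=ref_allele)
        remap = np.array([locus.index(a) for a in labels])
        loci.append(locus)
        genotypes.append(remap[gts])
    return GenotypeDataset(loci=loci, genotypes=genotypes)


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg fixtures
# ---------------------------------------------------------------------------


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        return Fraction(str(x))
    return Fraction(x)


def exact_hwe_fixture(
    freqs: Sequence, scale: int, name: str = "L1"
) -> GenotypeDataset:
    """A genotype sample whose counts sit exactly at HWE proportions.

    With rational allele frequencies ``p_j`` and total size ``scale``, the
    expected counts ``N p_j^2`` and ``2 N p_j p_k`` must all be integers;
    the resulting sample has every estimated disequilibrium coefficient
    exactly zero, removing the sampling deviation a random draw would carry.
    """
    p = [_as_fraction(x) for x in freqs]
    if sum(p) != 1:
        raise ValueError("allele frequencies must sum to exactly 1")
    m = len(p)
    N = int(scale)
    expected = {}
    denoms = []
    for j in range(m):
        for k in range(j, m):
            e = N * (p[j] * p[k] if j == k else 2 * p[j] * p[k])
            expected[(j, k)] = e
            denoms.append((p[j] * p[k] * (1 if j == k else 2)).denominator)
    bad = {cell: e for cell, e in expected.items() if e.denominator != 1}
    if bad:
        minimal = lcm(*denoms)
        raise ValueError(
            f"expected counts are not integers at scale N={N} "
            f"(e.g. cell {next(iter(bad))} -> {float(next(iter(bad.values())))}); "
            f"the minimal valid scale is N={minimal}"
        )
    rows = []
    for (j, k), e in expected.items():
        rows.extend([[j, k]] * int(e))
    locus = Locus(
        name=name, alleles=[str(i) for i in range(m)],
        freqs=np.array([float(x) for x in p]), ref_allele=str(m - 1),
    )
    return GenotypeDataset(loci=[locus], genotypes=[np.array(rows)])


def independent_product_fixture(
    ds1: GenotypeDataset, ds2: GenotypeDataset
) -> GenotypeDataset:
    """Cross-join two one-locus fixtures into an exactly independent two-locus one.

    Every pairing of a row of ``ds1`` with a row of ``ds2`` appears once
    (N = N1 * N2), so all joint disequilibrium coefficients are exactly zero.
    """
    if ds1.n_loci != 1 or ds2.n_loci != 1:
        raise ValueError("inputs must be one-locus datasets")
    g1 = np.repeat(ds1.genotypes[0], ds2.N, axis=0)
    g2 = np.tile(ds2.genotypes[0], (ds1.N, 1))
    locus2 = ds2.loci[0]
    if locus2.name == ds1.loci[0].name:
        locus2 = Locus(
            name=locus2.name + "_2", alleles=locus2.alleles,
            freqs=locus2.freqs, ref_allele=locus2.ref_allele,
        )
    return GenotypeDataset(loci=[ds1.loci[0], locus2], genotypes=[g1, g2])
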