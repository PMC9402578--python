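"""Expression filtering, CDS-group integration, isoform-ratio phenotypes,
and the normalization cascade (quantile -> inverse-normal -> latent-factor
removal).

Matrices are pandas DataFrames with feature rows and sample columns.
Pipeline order is fixed: filter -> (integrate) -> ratio -> quantile
normalization -> inverse normal transform -> factor removal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_model import CdsGroupSet

logger = logging.getLogger(__name__)

BLOM_OFFSET = 3.0 / 8.0


@dataclass
class RatioMatrix:
    """Per-feature expression fraction of the gene total; NaN = missing."""

    values: pd.DataFrame
    gene_of: dict[str, str] = field(default_factory=dict)


def filter_genes(gene_expr: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Keep genes with FPKM strictly above ``threshold`` in every sample."""
    keep = (gene_expr > threshold).all(axis=1)
    out = gene_expr.loc[keep]
    if out.empty:
        logger.warning("filter_genes: no genes pass FPKM > %g in all samples",
                       threshold)
    return out


def filter_isoforms(
    iso_expr: pd.DataFrame,
    retained_genes,
    gene_of: dict[str, str],
    threshold: float = 1.0,
    frac: float = 0.05,
) -> pd.DataFrame:
    """Keep isoforms of retained genes with FPKM strictly above ``threshold``
    in at least ceil(frac * n_samples) samples."""
    retained = set(retained_genes)
    n_min = math.ceil(frac * iso_expr.shape[1])
    of_gene = iso_expr.index.map(lambda i: gene_of.get(i) in retained)
    enough = (iso_expr > threshold).sum(axis=1) >= n_min
    return iso_expr.loc[np.asarray(of_gene) & enough.to_numpy()]


def integrate_isoforms(
    iso_expr: pd.DataFrame, groups: CdsGroupSet
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Sum member-isoform FPKM within each CDS group.

    Returns (group x sample matrix, group -> members-present map). Groups with
    no member in the matrix are dropped; members missing from the matrix
    contribute zero and are logged.
    """
    rows = {}
    members_used: dict[str, list[str]] = {}
    present = set(iso_expr.index)
    for gid, members in groups.groups.items():
        here = [m for m in members if m in present]
        if not here:
            continue
        if len(here) < len(members):
            logger.info("group %s: %d member(s) absent from matrix, treated as 0",
                        gid, len(members) - len(here))
        rows[gid] = iso_expr.loc[here].sum(axis=0)
        members_used[gid] = here
    return pd.DataFrame(rows).T, members_used


def compute_ratios(expr: pd.DataFrame, gene_of: dict[str, str]) -> RatioMatrix:
    """Feature FPKM over the per-gene total; missing where the total is 0."""
    genes = expr.index.map(gene_of.get)
    if genes.isna().any():
        missing = expr.index[genes.isna()]
        raise KeyError(f"features with no gene mapping: {list(missing)[:5]}")
    totals = expr.groupby(genes.to_numpy()).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = expr / totals
    vals = vals.where(totals > 0)
    return RatioMatrix(values=vals, gene_of={f: gene_of[f] for f in expr.index})


def impute_missing_ratios(
    ratio: RatioMatrix, max_missing_frac: float = 0.05
) -> pd.DataFrame:
    """Drop features with more than ``max_missing_frac`` missing entries,
    then fill remaining NaNs with the feature's non-missing mean."""
    vals = ratio.values
    miss = vals.isna().mean(axis=1)
    kept = vals.loc[miss <= max_missing_frac]
    n_drop = len(vals) - len(kept)
    if n_drop:
        logger.info("dropped %d features with >%g%% missing ratios",
                    n_drop, 100 * max_missing_frac)
    return kept.apply(lambda row: row.fillna(row.mean()), axis=1)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the mean order-statistic distribution.

    Ties within a column receive the mean of the target values they span
    (average-rank convention).
    """
    X = m.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("quantile_normalize requires a complete matrix")
    n = X.shape[0]
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), target)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def inverse_normal_transform(
    m: pd.DataFrame, offset: float = BLOM_OFFSET
) -> pd.DataFrame:
    """Blom rank-based inverse normal transform applied per feature row.

    value = Phi^-1((r - offset) / (n + 1 - 2*offset)) with average ranks.
    Zero-variance features are dropped with a warning.
    """
    const = m.std(axis=1, ddof=0) == 0
    if const.any():
        logger.warning("inverse_normal_transform: dropping %d zero-variance "
                       "features", int(const.sum()))
        m = m.loc[~const]
    n = m.shape[1]
    ranks = m.rank(axis=1, method="average")
    return pd.DataFrame(
        stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset)),
        index=m.index, columns=m.columns,
    )


def remove_latent_factors(m: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Residualize each feature on the top-k principal components of the
    feature-standardized matrix (deterministic PCA stand-in for a Bayesian
    latent-factor model).
    """
    if k >= m.shape[1]:
        raise ValueError(f"k={k} must be smaller than n_samples={m.shape[1]}")
    if k == 0:
        return m.copy()
    X = m.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    # right singular vectors span sample space; k of them define the factors
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    V = vt[:k].T  # (n_samples, k), orthonormal
    Xc = X - X.mean(axis=1, keepdims=True)
    resid = Xc - (Xc @ V) @ V.T
    return pd.DataFrame(resid, index=m.index, columns=m.columns)


def build_phenotypes(
    gene_expr: pd.DataFrame,
    iso_expr: pd.DataFrame | None,
    gene_of: dict[str, str] | None,
    mode: str,
    groups: CdsGroupSet | None = None,
    gene_fpkm_min: float = 0.1,
    iso_fpkm_min: float = 1.0,
    iso_frac: float = 0.05,
    n_factors: int = 15,
    max_missing_frac: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """End-to-end phenotype construction for one QTL mode.

    Modes: ``gene_eqtl`` (filtered gene FPKM), ``i_eqtl`` / ``i2_eqtl``
    (isoform or integrated-isoform FPKM levels), ``i_rqtl`` / ``i2_rqtl``
    (isoform or integrated-isoform ratios). Returns the normalized phenotype
    matrix and a feature -> gene map.
    """
    genes_kept = filter_genes(gene_expr, gene_fpkm_min)
    if mode == "gene_eqtl":
        mat = genes_kept
        feature_gene = {g: g for g in mat.index}
    else:
        if iso_expr is None or gene_of is None:
            raise ValueError("isoform matrix and gene map required for " + mode)
        iso_kept = filter_isoforms(
            iso_expr, genes_kept.index, gene_of, iso_fpkm_min, iso_frac
        )
        if mode.startswith("i2"):
            if groups is None:
                raise ValueError("CDS groups required for " + mode)
            iso_kept, members_used = integrate_isoforms(iso_kept, groups)
            feature_gene = {
                gid: gene_of[members[0]] for gid, members in members_used.items()
            }
        else:
            feature_gene = {i: gene_of[i] for i in iso_kept.index}
        if mode.endswith("rqtl"):
            ratio = compute_ratios(iso_kept, feature_gene)
            mat = impute_missing_ratios(ratio, max_missing_frac)
        elif mode.endswith("eqtl"):
            mat = iso_kept
        else:
            raise ValueError(f"unknown mode {mode!r}")

    if mat.empty:
        return mat, {}
    n_factors = min(n_factors, max(mat.shape[1] - 1, 0))
    mat = quantile_normalize(mat)
    mat = inverse_normal_transform(mat)
    mat = remove_latent_factors(mat, n_factors)
    feature_gene = {f: feature_gene[f] for f in mat.index}
    return mat, feature_gene
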