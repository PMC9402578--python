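"""Trans-eQTL scanning, QQ enrichment comparison between variant classes,
and GSEA with a continuous phenotype label and Pearson-correlation weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cis_qtl import _corr_pvalues

logger = logging.getLogger(__name__)


@dataclass
class TransScanResult:
    variant_id: str
    gene_id: str
    r: float | None
    p: float | None
    excluded_reason: str = "none"  # none | cis_window | cis_eqtl_gene


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float = np.nan
    p: float = np.nan
    leading_edge: list[str] = field(default_factory=list)
    weight_exponent: float = 1.0


def trans_scan(
    dosage: np.ndarray,
    expr: pd.DataFrame,
    gene_coords: dict[str, tuple[str, int, int]],
    variant_locus: tuple[str, int],
    cis_eqtl_genes: set | None = None,
    cis_margin: int = 1_000_000,
    variant_id: str = "variant",
) -> list[TransScanResult]:
    """Pearson association of one variant's dosage with every distal gene.

    Genes on the variant's chromosome within ``cis_margin`` of it, and genes
    carrying a cis-eQTL (FDR-significant, supplied as a set), are excluded
    with a reason instead of a statistic.
    """
    cis_eqtl_genes = cis_eqtl_genes or set()
    g = np.asarray(dosage, dtype=float)
    v_chrom, v_pos = variant_locus
    n = g.size
    gc = g - g.mean()
    gsd = g.std()
    out: list[TransScanResult] = []
    for gid in expr.index:
        if gid in cis_eqtl_genes:
            out.append(TransScanResult(variant_id, gid, None, None,
                                       "cis_eqtl_gene"))
            continue
        coords = gene_coords.get(gid)
        if coords is not None:
            chrom, tss, tes = coords
            lo, hi = min(tss, tes) - cis_margin, max(tss, tes) + cis_margin
            if chrom == v_chrom and lo <= v_pos <= hi:
                out.append(TransScanResult(variant_id, gid, None, None,
                                           "cis_window"))
                continue
        y = expr.loc[gid].to_numpy(dtype=float)
        if y.std() == 0 or gsd == 0:
            out.append(TransScanResult(variant_id, gid, 0.0, 1.0))
            continue
        r = float((y - y.mean()) @ gc / (n * y.std() * gsd))
        p = float(_corr_pvalues(np.array([r]), n)[0])
        out.append(TransScanResult(variant_id, gid, r, p))
    return out


def qq_compare(
    p_class_a, p_class_b, background=None, n_quantiles: int = 100
) -> dict:
    """QQ table of observed vs expected -log10 p per class, plus a
    lambda-style summary: the ratio of class medians of -log10 p."""
    def table(p):
        p = np.sort(np.asarray(p, dtype=float))
        m = p.size
        expected = (np.arange(1, m + 1) - 0.5) / m
        qs = np.linspace(0, 1, n_quantiles, endpoint=False)
        idx = (qs * m).astype(int)
        return pd.DataFrame({
            "expected_nlp": -np.log10(expected[idx]),
            "observed_nlp": -np.log10(np.maximum(p[idx], 1e-300)),
        })

    med_a = float(np.median(-np.log10(np.maximum(p_class_a, 1e-300))))
    med_b = float(np.median(-np.log10(np.maximum(p_class_b, 1e-300))))
    out = {
        "qq_a": table(p_class_a),
        "qq_b": table(p_class_b),
        "median_nlp_a": med_a,
        "median_nlp_b": med_b,
        "median_ratio": med_a / med_b if med_b > 0 else np.inf,
    }
    if background is not None:
        out["qq_background"] = table(background)
    return out


def rank_genes_by_metric(
    expr: pd.DataFrame, label: np.ndarray
) -> pd.DataFrame:
    """Genes sorted by Pearson r with the continuous label, descending;
    ties broken by gene id. Zero-variance genes get metric 0."""
    y = np.asarray(label, dtype=float)
    if y.std() == 0:
        raise ValueError("label has zero variance")
    yc = (y - y.mean()) / (y.std() * np.sqrt(y.size))
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    zero = sd == 0
    if zero.any():
        logger.info("%d zero-variance genes get metric 0", int(zero.sum()))
    sd[zero] = 1.0
    Xc = (X - X.mean(axis=1, keepdims=True)) / (sd[:, None] * np.sqrt(y.size))
    r = Xc @ yc
    r[zero] = 0.0
    df = pd.DataFrame({"gene": expr.index, "r": r})
    return df.sort_values(["r", "gene"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)


def gsea_es(
    ranked: pd.DataFrame, gene_set, weight_p: float = 1.0
) -> GseaResult:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    Hits add |r|^weight_p normalized by the hit total; misses subtract
    1/(N - N_hits); es is the signed maximum deviation, and the leading edge
    contains the set members at or before (after, for negative es) the
    extremum.
    """
    genes = ranked["gene"].to_numpy()
    metric = ranked["r"].to_numpy(dtype=float)
    in_set = np.isin(genes, list(gene_set))
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    N = genes.size
    w = np.abs(metric) ** weight_p
    w_hit = np.where(in_set, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:  # all hit metrics are exactly 0
        w_hit = in_set.astype(float)
        denom = float(n_hits)
    step = w_hit / denom - (~in_set) / max(N - n_hits, 1)
    running = np.cumsum(step)
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    if es >= 0:
        leading = [g for g, hit in zip(genes[: i_max + 1], in_set[: i_max + 1]) if hit]
    else:
        leading = [g for g, hit in zip(genes[i_max:], in_set[i_max:]) if hit]
    return GseaResult(set_name="", es=es, leading_edge=leading,
                      weight_exponent=weight_p)


def gsea_permutation_p(
    expr: pd.DataFrame,
    label: np.ndarray,
    gene_set,
    set_name: str = "set",
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Sample-label permutation p-value and NES for one gene set.

    The label is permuted across samples (preserving inter-gene correlation)
    and the metric ranking and es are recomputed per permutation;
    p = (1 + #{|es_perm| >= |es_obs|}) / (1 + n_perm), and the NES divides
    es_obs by the mean |es_perm| of permutations matching its sign.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    y = np.asarray(label, dtype=float)
    obs = gsea_es(rank_genes_by_metric(expr, y), gene_set, weight_p)
    es_perm = np.empty(n_perm)
    for b in range(n_perm):
        yp = y[rng.permutation(y.size)]
        es_perm[b] = gsea_es(rank_genes_by_metric(expr, yp), gene_set,
                             weight_p).es
    if np.allclose(es_perm, es_perm[0]):
        logger.warning("all permutation enrichment scores identical")
    p = (1.0 + np.sum(np.abs(es_perm) >= abs(obs.es))) / (1.0 + n_perm)
    same_sign = es_perm[np.sign(es_perm) == np.sign(obs.es)]
    nes = obs.es / np.abs(same_sign).mean() if same_sign.size else np.nan
    return GseaResult(set_name=set_name, es=obs.es, nes=float(nes), p=float(p),
                      leading_edge=obs.leading_edge, weight_exponent=weight_p)


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets
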