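"""Cis-window QTL mapping: nominal linear association, permutation-based
phenotype-level adjusted p-values with a Beta-approximation smoother, and
Storey-Tibshirani q-values.

The association model is a simple linear regression of the normalized
phenotype on allele dosage; significance comes from the Pearson correlation
through t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, two-sided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).tiny


@dataclass
class VariantRecord:
    variant_id: str
    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "G"
    maf: float = np.nan


@dataclass
class GenotypeMatrix:
    """Variant records plus a samples x variants dosage matrix in {0,1,2}."""

    variants: list[VariantRecord]
    dosages: np.ndarray  # (n_samples, n_variants) float
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage matrix shape inconsistent with ids")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants])

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def empirical_maf(self) -> np.ndarray:
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def index_of(self, variant_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.variant_id == variant_id:
                return i
        raise KeyError(variant_id)

    def subset(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            variants=[self.variants[i] for i in idx],
            dosages=self.dosages[:, idx],
            sample_ids=self.sample_ids,
        )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (plain-text) VCF with GT fields into dosages.

    Missing genotypes are mean-imputed per variant and logged. Only the GT
    subfield is consulted; multi-allelic records are rejected.
    """
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    n_missing = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.rstrip("\n").split("\t")[9:]
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, vid, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            if "," in alt:
                raise ValueError(f"multi-allelic record {vid} not supported")
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT")
            dos = np.empty(len(sample_ids))
            for j, cell in enumerate(fields[9:]):
                gt = cell.split(":")[gt_i].replace("|", "/")
                if "." in gt:
                    dos[j] = np.nan
                else:
                    a, b = gt.split("/")
                    dos[j] = int(a) + int(b)
            if np.isnan(dos).any():
                n_missing += int(np.isnan(dos).sum())
                dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
            freq = dos.mean() / 2.0
            variants.append(
                VariantRecord(vid, chrom, pos, ref, alt, min(freq, 1 - freq))
            )
            rows.append(dos)
    if n_missing:
        logger.info("mean-imputed %d missing genotype calls", n_missing)
    return GenotypeMatrix(
        variants=variants,
        dosages=np.array(rows).T if rows else np.zeros((len(sample_ids), 0)),
        sample_ids=sample_ids,
    )


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal GT-only VCF writer (uncompressed)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i, v in enumerate(geno.variants):
            calls = [gt_map[int(round(d))] for d in geno.dosages[:, i]]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


@dataclass
class CisQtlResult:
    phenotype_id: str
    lead_variant_id: str
    nominal_p: float
    slope: float
    r: float
    perm_p: float
    beta_shape1: float | None = None
    beta_shape2: float | None = None
    adjusted_p: float = np.nan
    qvalue: float = np.nan
    n_variants: int = 0


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, _EPS))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def window_mask(
    geno: GenotypeMatrix,
    gene_anchor: tuple[str, int, int],
    window: int = 1_000_000,
    maf_min: float = 0.05,
) -> np.ndarray:
    """Boolean mask of variants within ``window`` of the gene body and with
    empirical MAF >= ``maf_min`` and nonzero variance."""
    chrom, tss, tes = gene_anchor
    lo, hi = min(tss, tes) - window, max(tss, tes) + window
    pos = geno.positions
    on_chrom = np.array([v.chrom == chrom for v in geno.variants])
    in_win = (pos >= lo) & (pos <= hi) & on_chrom
    maf_ok = geno.empirical_maf() >= maf_min
    var_ok = geno.dosages.std(axis=0) > 0
    if (in_win & maf_ok & ~var_ok).any():
        logger.debug("skipping zero-variance variants in window")
    return in_win & maf_ok & var_ok


def nominal_scan(
    pheno: np.ndarray,
    geno: GenotypeMatrix,
    gene_anchor: tuple[str, int, int],
    window: int = 1_000_000,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Per-variant Pearson r, regression slope and two-sided p within the
    cis window. Returns a frame indexed like the retained variants."""
    y = np.asarray(pheno, dtype=float)
    if y.std() == 0:
        raise ValueError("phenotype has zero variance")
    mask = window_mask(geno, gene_anchor, window, maf_min)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("no variants in cis window after filtering")
    G = geno.dosages[:, idx]
    n = y.size
    yc = y - y.mean()
    Gc = G - G.mean(axis=0)
    g_sd = Gc.std(axis=0)
    r = (yc @ Gc) / (n * y.std() * g_sd)
    slope = r * y.std() / g_sd
    p = _corr_pvalues(r, n)
    return pd.DataFrame(
        {
            "variant_id": [geno.variants[i].variant_id for i in idx],
            "pos": [geno.variants[i].pos for i in idx],
            "r": r,
            "slope": slope,
            "p": p,
        }
    )


def _lead_index(scan: pd.DataFrame) -> int:
    """Lead = min nominal p; ties broken by genomic position then id."""
    best = scan["p"].min()
    tied = scan[scan["p"] == best]
    tied = tied.sort_values(["pos", "variant_id"], kind="mergesort")
    return int(tied.index[0])


def fit_beta_approx(perm_minima: np.ndarray):
    """Maximum-likelihood Beta fit to permutation minimum p-values.

    Returns ``(shape1, shape2, adjusted_p)`` where ``adjusted_p`` maps an
    observed minimum p to the Beta CDF, or ``None`` on degenerate input.
    """
    x = np.asarray(perm_minima, dtype=float)
    if x.size < 100:
        raise ValueError("need >= 100 permutation minima for a stable fit")
    if np.allclose(x, x[0]):
        logger.warning("degenerate permutation minima; beta fit skipped")
        return None
    x = np.clip(x, 1e-300, 1 - 1e-16)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a, b, _, _ = stats.beta.fit(x, floc=0, fscale=1)

    def adjusted_p(obs: float) -> float:
        return float(stats.beta.cdf(obs, a, b))

    return a, b, adjusted_p


def permutation_pass(
    pheno: np.ndarray,
    geno: GenotypeMatrix,
    gene_anchor: tuple[str, int, int],
    window: int = 1_000_000,
    maf_min: float = 0.05,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    phenotype_id: str = "phenotype",
    fit_beta: bool = True,
) -> CisQtlResult:
    """Phenotype-level cis scan with an empirical permutation p-value.

    The observed statistic is the minimum nominal p over the window. Each
    permutation shuffles the phenotype across samples once and rescans all
    variants (preserving LD), recording its minimum p. The empirical
    permutation p is ``(1 + #{perm <= obs}) / (B + 1)``; when a Beta
    approximation is fitted to the permutation minima, ``adjusted_p`` is the
    Beta CDF at the observed minimum, else it falls back to the empirical
    value.
    """
    if n_permutations < 100:
        logger.warning("B=%d permutations gives coarse p-value granularity",
                       n_permutations)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    scan = nominal_scan(pheno, geno, gene_anchor, window, maf_min)
    lead = scan.loc[_lead_index(scan)]
    obs_min_p = float(lead["p"])

    mask = window_mask(geno, gene_anchor, window, maf_min)
    G = geno.dosages[:, mask]
    n = len(pheno)
    y = np.asarray(pheno, dtype=float)
    Gz = (G - G.mean(axis=0)) / (G.std(axis=0) * np.sqrt(n))

    # (B, n) matrix of permuted standardized phenotypes -> |r| via one matmul
    perm = np.empty((n_permutations, n))
    for b in range(n_permutations):
        perm[b] = y[rng.permutation(n)]
    perm = (perm - perm.mean(axis=1, keepdims=True))
    perm /= (perm.std(axis=1, keepdims=True) * np.sqrt(n))
    abs_r_max = np.abs(perm @ Gz).max(axis=1)
    perm_min_p = _corr_pvalues(abs_r_max, n)

    perm_p = (1.0 + np.sum(perm_min_p <= obs_min_p)) / (n_permutations + 1.0)

    shape1 = shape2 = None
    adj = perm_p
    if fit_beta and n_permutations >= 100:
        fitted = fit_beta_approx(perm_min_p)
        if fitted is not None:
            shape1, shape2, adj_fn = fitted
            adj = max(adj_fn(obs_min_p), _EPS)

    return CisQtlResult(
        phenotype_id=phenotype_id,
        lead_variant_id=str(lead["variant_id"]),
        nominal_p=obs_min_p,
        slope=float(lead["slope"]),
        r=float(lead["r"]),
        perm_p=float(perm_p),
        beta_shape1=shape1,
        beta_shape2=shape2,
        adjusted_p=float(adj),
        n_variants=len(scan),
    )


def storey_qvalues(pvalues, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey-Tibshirani q-values.

    pi0 is estimated on the lambda grid 0.05..0.95 (step 0.05) with a cubic
    smoother evaluated at the largest lambda, clipped to (0, 1]. With fewer
    than 20 p-values pi0 is fixed at 1 (the procedure then equals BH).
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if m < 20:
        logger.warning("m=%d < 20: pi0 fixed at 1 (BH-equivalent)", m)
        pi0 = 1.0
    else:
        pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
        coefs = np.polyfit(lambdas, pi0_l, deg=3)
        pi0 = float(np.polyval(coefs, lambdas.max()))
        pi0 = min(max(pi0, 1.0 / m), 1.0)

    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def map_cis(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    anchors: dict[str, tuple[str, int, int]],
    window: int = 1_000_000,
    maf_min: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    fit_beta: bool = True,
) -> pd.DataFrame:
    """Run the permutation pass for every phenotype row and attach q-values.

    ``pheno`` is features x samples with sample columns matching
    ``geno.sample_ids``; ``anchors`` maps phenotype id -> (chrom, tss, tes).
    """
    if list(pheno.columns) != list(geno.sample_ids):
        pheno = pheno[geno.sample_ids]
    rng = np.random.default_rng(seed)
    results: list[CisQtlResult] = []
    for pid, row in pheno.iterrows():
        try:
            res = permutation_pass(
                row.to_numpy(), geno, anchors[pid], window, maf_min,
                n_permutations, rng, phenotype_id=str(pid), fit_beta=fit_beta,
            )
        except ValueError as exc:
            logger.warning("phenotype %s skipped: %s", pid, exc)
            continue
        results.append(res)
    if not results:
        return pd.DataFrame()
    df = pd.DataFrame([vars(r) for r in results])
    df["qvalue"] = storey_qvalues(df["adjusted_p"].to_numpy())
    return df
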