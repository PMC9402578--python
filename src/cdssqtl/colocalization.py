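"""GWAS-QTL colocalization: LD r2, regulatory-trait-concordance (RTC)
scoring within recombination intervals, and dual-evidence signal curation
against a junction-QTL table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cis_qtl import GenotypeMatrix, _corr_pvalues

logger = logging.getLogger(__name__)


@dataclass
class RtcRecord:
    interval_id: str
    gwas_variant_id: str
    qtl_variant_id: str
    phenotype_id: str
    n_variants: int
    rank: int
    rtc: float
    r2: float
    trait: str = ""
    passed: bool | None = None
    flagged: bool = False


@dataclass
class CurationCriteria:
    qtl_fdr_max: float = 0.05
    junction_fdr_max: float = 0.05
    require_direction_concordance: bool = True


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of dosage vectors (composite r2)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.std() == 0 or g2.std() == 0:
        raise ValueError("LD r2 undefined for a monomorphic variant")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def rtc_score(
    pheno: np.ndarray,
    interval_geno: GenotypeMatrix,
    gwas_variant_id: str,
    qtl_variant_id: str,
    interval_id: str = "",
    phenotype_id: str = "",
) -> RtcRecord:
    """RTC of a GWAS variant against a QTL signal inside one interval.

    For every variant k in the interval the phenotype is residualized on k's
    dosage and the QTL variant is re-associated against the residuals. The
    variants are ranked by that residual p descending (largest p = the
    residualization that best removed the QTL signal gets rank 0, ties broken
    by genomic position); RTC = (N - rank(gwas)) / N, so RTC = 1 means the
    GWAS variant fully accounts for the QTL association.
    """
    y = np.asarray(pheno, dtype=float)
    N = interval_geno.n_variants
    if N < 2:
        raise ValueError("interval must contain at least 2 variants")
    gi = interval_geno.index_of(gwas_variant_id)
    qi = interval_geno.index_of(qtl_variant_id)
    gq = interval_geno.dosages[:, qi]
    n = y.size
    flagged = False

    p_k = np.empty(N)
    for k in range(N):
        gk = interval_geno.dosages[:, k]
        gkc = gk - gk.mean()
        denom = gkc @ gkc
        resid = y - y.mean() - (gkc * ((y @ gkc) / denom) if denom > 0 else 0.0)
        gqc = gq - gq.mean()
        sr, sq = resid.std(), gqc.std()
        if sr == 0 or sq == 0:
            p_k[k] = 1.0
            flagged = True
            continue
        r = (resid @ gqc) / (n * sr * sq)
        p_k[k] = _corr_pvalues(np.array([r]), n)[0]

    pos = interval_geno.positions
    order = np.lexsort((pos, -p_k))  # p descending, position ascending on ties
    rank = int(np.flatnonzero(order == gi)[0])
    return RtcRecord(
        interval_id=interval_id,
        gwas_variant_id=gwas_variant_id,
        qtl_variant_id=qtl_variant_id,
        phenotype_id=phenotype_id,
        n_variants=N,
        rank=rank,
        rtc=(N - rank) / N,
        r2=ld_r2(interval_geno.dosages[:, gi], gq),
        flagged=flagged,
    )


def read_intervals_bed(path) -> pd.DataFrame:
    """0-based half-open BED -> 1-based inclusive interval frame."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"],
                     usecols=[0, 1, 2, 3])
    df["start"] = df["start"] + 1  # to 1-based inclusive
    return df


def _interval_of(intervals: pd.DataFrame, chrom: str, pos: int) -> str | None:
    hit = intervals[(intervals["chrom"] == chrom)
                    & (intervals["start"] <= pos)
                    & (intervals["end"] >= pos)]
    if hit.empty:
        return None
    return str(hit.iloc[0]["name"])


def colocalize_catalog(
    qtl_results: pd.DataFrame,
    pheno: pd.DataFrame,
    gwas_catalog: pd.DataFrame,
    intervals: pd.DataFrame,
    geno: GenotypeMatrix,
    rtc_min: float = 0.8,
    r2_min: float = 0.8,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Score every (significant QTL, GWAS variant) pair sharing an interval.

    Emits one long-format row per pair with ``passed`` flag; ``rtc_best`` per
    (trait, phenotype) is the max over that trait's variants in the interval.
    """
    var_pos = {v.variant_id: (v.chrom, v.pos) for v in geno.variants}
    records: list[RtcRecord] = []
    sig = qtl_results[qtl_results["qvalue"] <= q_max]
    for _, row in sig.iterrows():
        lead = row["lead_variant_id"]
        if lead not in var_pos:
            logger.warning("lead variant %s absent from genotypes", lead)
            continue
        chrom, pos = var_pos[lead]
        iv = _interval_of(intervals, chrom, pos)
        if iv is None:
            logger.info("lead variant %s in no interval; skipped", lead)
            continue
        ivrow = intervals[intervals["name"] == iv].iloc[0]
        in_iv = [
            i for i, v in enumerate(geno.variants)
            if v.chrom == chrom and ivrow["start"] <= v.pos <= ivrow["end"]
        ]
        sub = geno.subset(np.array(in_iv))
        y = pheno.loc[row["phenotype_id"]].to_numpy()
        for _, grow in gwas_catalog.iterrows():
            gv = grow["variant_id"]
            try:
                sub.index_of(gv)
            except KeyError:
                continue
            rec = rtc_score(y, sub, gv, lead, interval_id=iv,
                            phenotype_id=str(row["phenotype_id"]))
            rec.trait = str(grow["trait"])
            rec.passed = rec.rtc >= rtc_min and rec.r2 >= r2_min
            records.append(rec)
    if not records:
        return pd.DataFrame()
    df = pd.DataFrame([vars(r) for r in records])
    df["rtc_best"] = df.groupby(["trait", "phenotype_id"])["rtc"].transform("max")
    return df


def curate_signals(
    irqtl: pd.DataFrame,
    junction_qtl: pd.DataFrame,
    criteria: CurationCriteria = CurationCriteria(),
) -> pd.DataFrame:
    """Keep ratio-QTL records backed by junction-level evidence.

    A record survives when (1) its own q <= qtl_fdr_max, (2) a junction row
    mapped to the same isoform has q <= junction_fdr_max, and (3) every such
    qualifying junction row agrees in effect direction (when required).
    Isoforms with no junction row are excluded and counted.
    """
    kept = []
    n_unmatched = 0
    sig_j = junction_qtl[junction_qtl["q"] <= criteria.junction_fdr_max]
    for _, row in irqtl.iterrows():
        if row["qvalue"] > criteria.qtl_fdr_max:
            continue
        matches = sig_j[sig_j["isoform_id"] == row["phenotype_id"]]
        if matches.empty:
            n_unmatched += 1
            continue
        if criteria.require_direction_concordance:
            if not all(np.sign(matches["slope"]) == np.sign(row["slope"])):
                continue
        kept.append(row)
    if n_unmatched:
        logger.info("curation: %d significant records had no junction match",
                    n_unmatched)
    return pd.DataFrame(kept).reset_index(drop=True) if kept else pd.DataFrame(
        columns=irqtl.columns)
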