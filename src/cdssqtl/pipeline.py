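"""End-to-end orchestration: run every QTL mode on one dataset with a single
config and fixed seed, and build the QTL-type overlap report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import annotation_model, cis_qtl, phenotype_builder, synthetic_data

logger = logging.getLogger(__name__)

ALL_MODES = ("gene_eqtl", "i_eqtl", "i_rqtl", "i2_eqtl", "i2_rqtl")


@dataclass
class RunConfig:
    gtf: str = ""
    proteins: str = ""
    vcf: str = ""
    gene_fpkm: str = ""
    iso_fpkm: str = ""
    out_dir: str = "run"
    modes: tuple = ALL_MODES
    window: int = 1_000_000
    maf_min: float = 0.05
    gene_fpkm_min: float = 0.1
    iso_fpkm_min: float = 1.0
    iso_frac: float = 0.05
    n_factors: int = 15
    n_permutations: int = 1000
    q_max: float = 0.05
    seed: int = 0


def _anchors_for(feature_gene: dict[str, str],
                 catalog: annotation_model.IsoformCatalog):
    anchors = {}
    for fid, gene in feature_gene.items():
        chrom, tss, tes, _strand = catalog.gene_span(gene)
        anchors[fid] = (chrom, tss, tes)
    return anchors


def run_pipeline(config: RunConfig) -> dict:
    """Execute annotation -> phenotypes per mode -> cis-QTL -> FDR, writing
    one result TSV per mode plus a manifest; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    catalog = annotation_model.read_annotation(
        config.gtf, config.proteins or None)
    groups = annotation_model.build_cds_groups(catalog)
    manifest["stages"]["annotation"] = {
        "n_isoforms": len(catalog),
        "n_genes": len(catalog.genes),
        "n_multi_member_groups": len(groups.multi_member_groups()),
        "n_cdsi": len(annotation_model.classify_cdsi(catalog)),
    }

    geno = cis_qtl.read_vcf(config.vcf)
    gene_fpkm = synthetic_data.read_matrix_tsv(config.gene_fpkm)
    iso_fpkm = synthetic_data.read_matrix_tsv(config.iso_fpkm)
    gene_of = {r.isoform_id: r.gene_id for r in catalog}

    results: dict[str, pd.DataFrame] = {}
    for mode in config.modes:
        try:
            pheno, feature_gene = phenotype_builder.build_phenotypes(
                gene_fpkm, iso_fpkm, gene_of, mode, groups=groups,
                gene_fpkm_min=config.gene_fpkm_min,
                iso_fpkm_min=config.iso_fpkm_min,
                iso_frac=config.iso_frac,
                n_factors=config.n_factors,
            )
        except ValueError as exc:
            raise RuntimeError(f"stage phenotypes[{mode}] failed: {exc}") from exc
        if pheno.empty:
            logger.warning("mode %s: no phenotypes after filtering", mode)
            results[mode] = pd.DataFrame()
            continue
        anchors = _anchors_for(feature_gene, catalog)
        df = cis_qtl.map_cis(
            pheno, geno, anchors,
            window=config.window, maf_min=config.maf_min,
            n_permutations=config.n_permutations, seed=config.seed,
        )
        df["gene_id"] = df["phenotype_id"].map(feature_gene)
        path = out / f"{mode}_results.tsv"
        df.to_csv(path, sep="\t", index=False)
        results[mode] = df
        manifest["stages"][mode] = {
            "n_phenotypes": int(pheno.shape[0]),
            "n_significant": int((df["qvalue"] <= config.q_max).sum()),
            "output": str(path),
        }

    report = overlap_report(results, q_max=config.q_max)
    manifest["overlap"] = report
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def overlap_report(results: dict[str, pd.DataFrame], q_max: float = 0.05) -> dict:
    """Per-gene membership in each significant QTL class and every
    intersection cell of the gene-eQTL / i-eQTL / i-rQTL taxonomy."""
    sig_genes: dict[str, set] = {}
    for mode, df in results.items():
        if df.empty:
            sig_genes[mode] = set()
        else:
            sig = df[df["qvalue"] <= q_max]
            sig_genes[mode] = set(sig["gene_id"])
    venn_modes = [m for m in ("gene_eqtl", "i_eqtl", "i_rqtl") if m in sig_genes]
    report = {"marginal": {m: len(s) for m, s in sig_genes.items()}}
    if len(venn_modes) == 3:
        a, b, c = (sig_genes[m] for m in venn_modes)
        universe = a | b | c
        cells = {}
        for g in universe:
            key = "".join("1" if g in s else "0" for s in (a, b, c))
            cells[key] = cells.get(key, 0) + 1
        report["venn_gene_eqtl_i_eqtl_i_rqtl"] = cells
        # consistency: marginals recoverable from cells
        for i, m in enumerate(venn_modes):
            total = sum(v for k, v in cells.items() if k[i] == "1")
            assert total == len(sig_genes[m])
    report["significant_genes"] = {m: sorted(s) for m, s in sig_genes.items()}
    return report
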