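"""Synthetic genotypes, annotation, expression and auxiliary reference files
with the statistical structure the pipeline assumes.

Everything is deterministic under ``SimulationConfig.seed``. All loci live on
one synthetic chromosome ("chrS") spaced far enough apart that 1 Mb cis
windows never overlap.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_model import CdsGroupSet, IsoformCatalog, IsoformRecord, write_gtf
from .cis_qtl import GenotypeMatrix, VariantRecord, write_vcf

CHROM = "chrS"
LOCUS_SPACING = 4_000_000  # > 2x the 1 Mb cis window on each side
AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    n_samples: int = 100
    n_genes: int = 20
    isoforms_per_gene: tuple[int, int] = (2, 4)
    frac_shared_cds: float = 0.5
    frac_cdsi: float = 0.3
    n_variants_per_locus: int = 50
    ld_block_size: int = 10
    ld_flip_prob: float = 0.02
    maf_range: tuple[float, float] = (0.1, 0.5)
    effect_gene_eqtl: float = 0.0
    effect_irqtl: float = 0.0
    effect_i2rqtl: float = 0.0
    noise_sd: float = 0.5
    n_trans_module_genes: int = 20
    effect_trans: float = 0.0
    baseline_log_fpkm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_shared_cds", "frac_cdsi", "ld_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError(f"maf_range {self.maf_range} invalid")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        # crc32 rather than hash(): stable across interpreter invocations
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


@dataclass
class PlantedEffect:
    phenotype_id: str
    causal_variant_id: str
    effect_type: str  # gene_eqtl | i_rqtl | i2_rqtl | trans
    effect_size: float


@dataclass
class PlantedTruth:
    effects: list[PlantedEffect] = field(default_factory=list)

    def of_type(self, effect_type: str) -> list[PlantedEffect]:
        return [e for e in self.effects if e.effect_type == effect_type]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.effects])


def locus_center(locus_index: int) -> int:
    return LOCUS_SPACING * (locus_index + 1)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """LD-blocked biallelic dosages for ``n_genes`` loci.

    Each block draws one latent haplotype pair per sample; block variants
    copy the latent alleles except at positions hit by the per-allele flip
    probability, where an independent allele at the same frequency is drawn.
    Variants whose empirical MAF falls below ``maf_range[0]`` are redrawn
    (rejection), so downstream MAF filters are exercised but not starved.
    """
    if config.n_samples < 10:
        raise ValueError("n_samples < 10: downstream statistics degenerate")
    rng = config.rng("genotypes")
    n, v_per = config.n_samples, config.n_variants_per_locus
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []

    for locus in range(config.n_genes):
        center = locus_center(locus)
        pos = np.sort(rng.choice(
            np.arange(center - 500_000, center + 500_000), size=v_per,
            replace=False,
        ))
        n_blocks = math.ceil(v_per / config.ld_block_size)
        for b in range(n_blocks):
            i0 = b * config.ld_block_size
            i1 = min(i0 + config.ld_block_size, v_per)
            p = rng.uniform(*config.maf_range)
            # block-level rejection: the latent haplotype pair itself must
            # satisfy the MAF floor, or no per-variant retry can
            while True:
                hap = rng.random((n, 2)) < p
                f_hap = hap.mean()
                if config.maf_range[0] <= min(f_hap, 1 - f_hap):
                    break
            for i in range(i0, i1):
                for _ in range(100):  # per-variant rejection on flip noise
                    flip = rng.random((n, 2)) < config.ld_flip_prob
                    indep = rng.random((n, 2)) < p
                    alleles = np.where(flip, indep, hap)
                    dos = alleles.sum(axis=1).astype(float)
                    freq = dos.mean() / 2
                    if config.maf_range[0] <= min(freq, 1 - freq):
                        break
                vid = f"rsS_{locus}_{i}"
                variants.append(VariantRecord(
                    vid, CHROM, int(pos[i]), "A", "G",
                    maf=float(min(freq, 1 - freq)),
                ))
                cols.append(dos)

    return GenotypeMatrix(
        variants=variants,
        dosages=np.column_stack(cols),
        sample_ids=[f"S{j:04d}" for j in range(n)],
    )


def _random_protein(rng: np.random.Generator, length: int = 30) -> str:
    return "M" + "".join(rng.choice(AA, size=length))


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[IsoformCatalog, CdsGroupSet, set[str]]:
    """Genes with multiple isoforms, some sharing an identical protein key
    and some flagged CDS-incomplete with a junction unique to them.

    Returns the catalog, the ground-truth CDS grouping, and the ground-truth
    CDSI id set.
    """
    rng = config.rng("annotation")
    catalog = IsoformCatalog()
    lo, hi = config.isoforms_per_gene
    for g in range(config.n_genes):
        gene_id = f"GENE{g:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(rng.integers(lo, hi + 1))
        gene_start = locus_center(g) - 15_000
        # shared exon scaffold: n_iso + 3 exon slots of 500 bp, 1.5 kb apart
        n_slots = n_iso + 3
        slots = [
            (gene_start + k * 2000, gene_start + k * 2000 + 499)
            for k in range(n_slots)
        ]
        share = n_iso >= 2 and rng.random() < config.frac_shared_cds
        proteins = [_random_protein(rng) for _ in range(n_iso)]
        if share:
            proteins[1] = proteins[0]
        for i in range(n_iso):
            iso_id = f"{gene_id}.T{i}"
            # every isoform keeps first and last slots; middle slots vary
            middle = [k for k in range(1, n_slots - 1)]
            keep = sorted(rng.choice(
                middle, size=max(1, len(middle) - 1 - (i % 2)), replace=False,
            ))
            exons = [slots[0]] + [slots[k] for k in keep] + [slots[-1]]
            is_cdsi = rng.random() < config.frac_cdsi
            if is_cdsi:
                # a private exon between the last two slots creates a
                # junction that no sibling isoform carries
                priv = (slots[-2][1] + 400 + i * 20, slots[-2][1] + 460 + i * 20)
                exons = exons[:-1] + [priv, slots[-1]]
            catalog.add(IsoformRecord(
                isoform_id=iso_id,
                gene_id=gene_id,
                chrom=CHROM,
                strand=strand,
                exons=exons,
                biotype="protein_coding",
                cds_incomplete_start=bool(is_cdsi and rng.random() < 0.5),
                cds_incomplete_end=bool(is_cdsi),
                protein_key=proteins[i] if not is_cdsi else None,
            ))

    truth_groups = _truth_groups(catalog)
    truth_cdsi = {r.isoform_id for r in catalog if r.is_cds_incomplete}
    return catalog, truth_groups, truth_cdsi


def _truth_groups(catalog: IsoformCatalog) -> CdsGroupSet:
    from .annotation_model import build_cds_groups

    return build_cds_groups(catalog)


def simulate_expression(
    genotypes: GenotypeMatrix,
    catalog: IsoformCatalog,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Gene and isoform FPKM matrices with planted additive genotype effects.

    Gene totals: T = exp(mu + beta_e * g_c + eps). Isoform fractions:
    softmax of per-isoform Gaussian scores with the planted logit-scale
    slope added to the target isoform (or equally to all members of a CDS
    group for integrated-ratio effects). Isoform FPKM = fraction * T, so the
    per-gene isoform sum equals the gene total by construction.
    """
    rng = config.rng("expression")
    n = genotypes.n_samples
    sample_ids = genotypes.sample_ids
    truth = PlantedTruth()
    gene_rows: dict[str, np.ndarray] = {}
    iso_rows: dict[str, np.ndarray] = {}

    gene_ids = sorted(catalog.genes)
    v_per = config.n_variants_per_locus
    for g_idx, gene_id in enumerate(gene_ids):
        iso_ids = catalog.genes[gene_id]
        # causal variant: middle of the locus' variant set
        causal_col = g_idx * v_per + v_per // 2
        g = genotypes.dosages[:, causal_col]
        g_c = g - g.mean()
        causal_id = genotypes.variants[causal_col].variant_id

        mu = config.baseline_log_fpkm + rng.normal(0, 0.3)
        eps = rng.normal(0, config.noise_sd, size=n)
        beta_e = config.effect_gene_eqtl
        T = np.exp(mu + beta_e * g_c + eps)
        if beta_e != 0:
            truth.effects.append(
                PlantedEffect(gene_id, causal_id, "gene_eqtl", beta_e))

        k = len(iso_ids)
        alpha = rng.normal(0, 1, size=k)
        scores = alpha[:, None] + rng.normal(0, config.noise_sd, size=(k, n))
        if k >= 2 and config.effect_irqtl != 0:
            target = 0
            scores[target] += config.effect_irqtl * g_c
            truth.effects.append(PlantedEffect(
                iso_ids[target], causal_id, "i_rqtl", config.effect_irqtl))
        if config.effect_i2rqtl != 0:
            group = _shared_cds_members(catalog, gene_id)
            if group:
                for iid in group:
                    scores[iso_ids.index(iid)] += config.effect_i2rqtl * g_c
                truth.effects.append(PlantedEffect(
                    "+".join(sorted(group)), causal_id, "i2_rqtl",
                    config.effect_i2rqtl))
        ex = np.exp(scores - scores.max(axis=0))
        frac = ex / ex.sum(axis=0)
        gene_rows[gene_id] = T
        for i, iid in enumerate(iso_ids):
            iso_rows[iid] = frac[i] * T

    gene_fpkm = pd.DataFrame(gene_rows, index=sample_ids).T
    iso_fpkm = pd.DataFrame(iso_rows, index=sample_ids).T
    return gene_fpkm, iso_fpkm, truth


def _shared_cds_members(catalog: IsoformCatalog, gene_id: str) -> list[str]:
    by_key: dict[str, list[str]] = {}
    for iid in catalog.genes[gene_id]:
        key = catalog.isoforms[iid].protein_key
        if key is not None:
            by_key.setdefault(key, []).append(iid)
    for members in by_key.values():
        if len(members) >= 2:
            return members
    return []


def simulate_trans_expression(
    genotypes: GenotypeMatrix,
    label: np.ndarray,
    config: SimulationConfig,
    causal_variant_id: str | None = None,
) -> tuple[pd.DataFrame, PlantedTruth, list[str]]:
    """Distal gene module responding to a continuous isoform-ratio label.

    Emits ``n_trans_module_genes`` responder genes (slope ``effect_trans``
    on the standardized label) plus the same number of null genes, placed on
    a separate chromosome so they are trans to every simulated locus.
    Returns (expression matrix, truth, module gene ids).
    """
    rng = config.rng("trans")
    n = len(label)
    z = (label - label.mean()) / (label.std() if label.std() > 0 else 1.0)
    rows = {}
    truth = PlantedTruth()
    module = [f"TRANSGENE{j:04d}" for j in range(config.n_trans_module_genes)]
    for j, gid in enumerate(module):
        rows[gid] = config.effect_trans * z + rng.normal(0, 1, size=n)
        if config.effect_trans != 0 and causal_variant_id is not None:
            truth.effects.append(PlantedEffect(
                gid, causal_variant_id, "trans", config.effect_trans))
    for j in range(config.n_trans_module_genes):
        rows[f"NULLGENE{j:04d}"] = rng.normal(0, 1, size=n)
    expr = pd.DataFrame(rows, index=genotypes.sample_ids).T
    return expr, truth, module


def simulate_aux(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    catalog: IsoformCatalog,
    truth: PlantedTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write GWAS catalog, hotspot intervals, CAGE TSS / PolyASite TES BEDs,
    a GMT of gene sets, and a junction-QTL table. Returns the path map.

    GWAS positives sit on planted causal variants; negatives on independent
    loci. CAGE/TES entries cover the true isoform ends (plus decoys) so that
    completion filters pass for faithful candidates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng("aux")
    paths: dict[str, Path] = {}

    # recombination-interval stand-ins: one interval per locus, covering it
    v_per = config.n_variants_per_locus
    intervals = []
    for locus in range(config.n_genes):
        block = genotypes.positions[locus * v_per:(locus + 1) * v_per]
        intervals.append((CHROM, int(block.min()) - 1, int(block.max()) + 1,
                          f"interval{locus:04d}"))
    paths["intervals"] = out / "intervals.bed"
    with open(paths["intervals"], "w") as fh:
        for chrom, s, e, name in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")

    # GWAS catalog: positives = planted causal variants; negatives = random
    planted = {e.causal_variant_id for e in truth.effects}
    gwas_rows = []
    for vid in sorted(planted):
        i = genotypes.index_of(vid)
        gwas_rows.append(("trait_pos", vid, CHROM, genotypes.variants[i].pos))
    n_neg = max(len(planted), 3)
    neg_idx = rng.choice(genotypes.n_variants, size=n_neg, replace=False)
    for i in neg_idx:
        v = genotypes.variants[int(i)]
        gwas_rows.append(("trait_neg", v.variant_id, v.chrom, v.pos))
    paths["gwas"] = out / "gwas_catalog.tsv"
    pd.DataFrame(gwas_rows, columns=["trait", "variant_id", "chrom", "pos"]) \
        .to_csv(paths["gwas"], sep="\t", index=False)

    # CAGE TSS / PolyASite TES: single-base entries at true ends + distant
    # decoys (point intervals keep the 50 bp edge-distance rule sharp)
    tss_rows, tes_rows = [], []
    for rec in catalog:
        for target, rowlist in ((rec.tss, tss_rows), (rec.tes, tes_rows)):
            rowlist.append((rec.chrom, target - 1, target))
            rowlist.append((rec.chrom, target + 4999, target + 5000))  # decoy
    paths["cage_tss"] = out / "cage_tss.bed"
    paths["polya_tes"] = out / "polya_tes.bed"
    for key, rows in (("cage_tss", tss_rows), ("polya_tes", tes_rows)):
        with open(paths[key], "w") as fh:
            for chrom, s, e in sorted(set(rows)):
                fh.write(f"{chrom}\t{s}\t{e}\n")

    # gene sets: trans module + random sets
    paths["gene_sets"] = out / "gene_sets.gmt"
    module = [f"TRANSGENE{j:04d}" for j in range(config.n_trans_module_genes)]
    nulls = [f"NULLGENE{j:04d}" for j in range(config.n_trans_module_genes)]
    with open(paths["gene_sets"], "w") as fh:
        fh.write("trans_module\tsynthetic\t" + "\t".join(module) + "\n")
        fh.write("null_set\tsynthetic\t" + "\t".join(nulls) + "\n")

    # junction-QTL table: concordant entries for planted i-rQTL isoforms,
    # discordant/noise rows for a few others
    jq_rows = []
    for e in truth.of_type("i_rqtl"):
        jq_rows.append((f"junc_{e.phenotype_id}", e.phenotype_id,
                        e.causal_variant_id, 1e-6, 0.001,
                        math.copysign(1.0, e.effect_size)))
    all_iso = sorted(catalog.isoforms)
    for iid in all_iso[: max(3, len(jq_rows))]:
        if any(r[1] == iid for r in jq_rows):
            continue
        jq_rows.append((f"junc_{iid}", iid, "rs_none",
                        float(rng.uniform(0.2, 1.0)), float(rng.uniform(0.2, 1.0)),
                        float(rng.choice([-1.0, 1.0]))))
    paths["junction_qtl"] = out / "junction_qtl.tsv"
    pd.DataFrame(jq_rows, columns=[
        "junction_id", "isoform_id", "lead_variant", "p", "q", "slope",
    ]).to_csv(paths["junction_qtl"], sep="\t", index=False)
    return paths


def write_matrix_tsv(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def simulate_all(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run all four generators and write every artifact under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes = simulate_genotypes(config)
    catalog, _groups, _cdsi = simulate_annotation(config)
    gene_fpkm, iso_fpkm, truth = simulate_expression(genotypes, catalog, config)

    paths = {
        "vcf": out / "genotypes.vcf",
        "gtf": out / "annotation.gtf",
        "gene_fpkm": out / "gene_fpkm.tsv",
        "iso_fpkm": out / "isoform_fpkm.tsv",
        "truth": out / "planted_truth.tsv",
    }
    write_vcf(genotypes, paths["vcf"])
    write_gtf(catalog, paths["gtf"])
    write_matrix_tsv(gene_fpkm, paths["gene_fpkm"])
    write_matrix_tsv(iso_fpkm, paths["iso_fpkm"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    # protein FASTA for CDS grouping
    paths["proteins"] = out / "proteins.fa"
    with open(paths["proteins"], "w") as fh:
        for rec in catalog:
            if rec.protein_key:
                fh.write(f">{rec.isoform_id}|{rec.gene_id}\n{rec.protein_key}\n")
    paths.update(simulate_aux(config, genotypes, catalog, truth, out))
    return paths


# ---------------------------------------------------------------------------
# Special-case generators for the shared-CDS power comparison
# ---------------------------------------------------------------------------

def simulate_shared_cds_locus(
    config: SimulationConfig,
    kind: str,
    seed_offset: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame, dict[str, str], CdsGroupSet, str]:
    """One gene, three isoforms, isoforms A and B sharing a CDS.

    ``kind='split'``: the genotype shifts the *summed* fraction of (A, B)
    while expression splits between A and B with heavy genotype-independent
    noise — the integrated ratio is clean, member ratios are diluted.
    ``kind='opposing'``: the genotype swaps expression *between* A and B with
    their sum held fixed — member ratios respond in opposite directions and
    the integrated ratio is null.

    Returns (genotypes, isoform FPKM, gene_of, CDS groups, causal variant id).
    """
    if kind not in ("split", "opposing"):
        raise ValueError(kind)
    cfg = SimulationConfig(**{**asdict(config), "n_genes": 1,
                              "seed": config.seed + seed_offset})
    rng = cfg.rng("shared-cds-" + kind)
    geno = simulate_genotypes(cfg)
    n = cfg.n_samples
    causal_col = cfg.n_variants_per_locus // 2
    g = geno.dosages[:, causal_col]
    g_c = g - g.mean()
    causal_id = geno.variants[causal_col].variant_id

    T = np.exp(cfg.baseline_log_fpkm + rng.normal(0, cfg.noise_sd, size=n))
    beta = cfg.effect_irqtl if cfg.effect_irqtl != 0 else 1.0
    if kind == "split":
        # group fraction driven by genotype; within-group split is pure noise
        f = 1.0 / (1.0 + np.exp(-(beta * g_c + rng.normal(0, cfg.noise_sd, n))))
        u = rng.uniform(0.15, 0.85, size=n)
    else:
        # group fraction constant-ish; genotype flips the within-group split
        f = 1.0 / (1.0 + np.exp(-rng.normal(0, cfg.noise_sd, n)))
        u = 1.0 / (1.0 + np.exp(-(beta * g_c + rng.normal(0, 0.5, n))))
    iso = pd.DataFrame(
        {
            "GENE0000.TA": f * u * T,
            "GENE0000.TB": f * (1 - u) * T,
            "GENE0000.TC": (1 - f) * T,
        },
        index=geno.sample_ids,
    ).T
    gene_of = {i: "GENE0000" for i in iso.index}
    groups = CdsGroupSet()
    gid = "GENE0000|GENE0000.TA+GENE0000.TB"
    groups.groups = {gid: ["GENE0000.TA", "GENE0000.TB"],
                     "GENE0000|GENE0000.TC": ["GENE0000.TC"]}
    groups.membership = {"GENE0000.TA": gid, "GENE0000.TB": gid,
                         "GENE0000.TC": "GENE0000|GENE0000.TC"}
    return geno, iso, gene_of, groups, causal_id
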