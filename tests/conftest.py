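import numpy as np
import pytest

from cdssqtl import annotation_model as am
from cdssqtl import cis_qtl as cq
from cdssqtl.synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def base_config():
    return SimulationConfig(
        n_samples=100,
        n_genes=8,
        effect_gene_eqtl=0.6,
        effect_irqtl=1.0,
        noise_sd=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def sim_genotypes(base_config):
    return simulate_genotypes(base_config)


@pytest.fixture(scope="session")
def sim_annotation(base_config):
    return simulate_annotation(base_config)


@pytest.fixture(scope="session")
def sim_expression(base_config, sim_genotypes, sim_annotation):
    catalog, _, _ = sim_annotation
    return simulate_expression(sim_genotypes, catalog, base_config)


@pytest.fixture()
def toy_catalog():
    """Two genes; gene A has two isoforms sharing a protein plus one odd
    one out; gene B has one isoform with the same protein as A's pair."""
    cat = am.IsoformCatalog()
    cat.add(am.IsoformRecord("A.T1", "A", "chr1", "+",
                             [(100, 200), (300, 400)], protein_key="MKT"))
    cat.add(am.IsoformRecord("A.T2", "A", "chr1", "+",
                             [(100, 200), (350, 400)], protein_key="MKT"))
    cat.add(am.IsoformRecord("A.T3", "A", "chr1", "+",
                             [(100, 400)], protein_key="MKV"))
    cat.add(am.IsoformRecord("B.T1", "B", "chr1", "-",
                             [(1000, 1200)], protein_key="MKT"))
    return cat


def make_genotypes(dosage_columns, positions=None, chrom="chr1",
                   prefix="v"):
    """Small helper for hand-built genotype matrices in tests."""
    G = np.asarray(dosage_columns, dtype=float).T
    n, m = G.shape
    positions = positions or [1000 * (i + 1) for i in range(m)]
    variants = [
        cq.VariantRecord(f"{prefix}{i}", chrom, positions[i])
        for i in range(m)
    ]
    return cq.GenotypeMatrix(variants, G, [f"S{j}" for j in range(n)])
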