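import numpy as np
import pandas as pd
import pytest

from tadreg.io_formats import (
    ExpressionStudy, GeneAnnotation, PhenotypeTable, TadSegmentation,
)
from tadreg.synthetic_data import SimulationConfig, make_genome, make_study


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale genome: 2 chromosomes x 20 TADs, ~8 genes per TAD."""
    return SimulationConfig(
        seed=11, n_chromosomes=2, n_tads_per_chromosome=20,
        genes_per_tad_mean=8.0, n_regulated_tads=4, responsive_per_tad=6,
        n_scattered_responsive=40,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return make_genome(small_config)


@pytest.fixture(scope="session")
def small_study(small_config, small_genome):
    return make_study(small_genome, config=small_config)


@pytest.fixture()
def tiny_study():
    """3 genes x 4 samples, two diets in one region, hand-set values."""
    meta = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "region": ["HT"] * 4,
        "diet": ["SC", "SC", "CM", "CM"],
        "mouse": ["m1", "m2", "m3", "m4"],
    }).set_index("sample_id")
    values = np.array([
        [5.0, 5.2, 6.0, 6.2],
        [7.0, 7.0, 7.0, 7.0],
        [8.0, 7.8, 7.1, 6.9],
    ])
    return ExpressionStudy(["g1", "g2", "g3"], list(meta.index), values, meta)


@pytest.fixture()
def toy_tads():
    return TadSegmentation(pd.DataFrame({
        "tad_id": ["A", "B", "C"],
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [100, 500, 0],
        "end": [300, 900, 400],
    }))


@pytest.fixture()
def toy_genes():
    return GeneAnnotation(pd.DataFrame({
        "gene_id": ["ga", "gb", "gc", "gd", "ge"],
        "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
        "start": [150, 295, 400, 10, 395],
        "end": [250, 305, 450, 60, 460],
        "strand": ["+", "+", "+", "+", "+"],
    }))


@pytest.fixture()
def toy_phenotypes():
    rng = np.random.default_rng(5)
    n = 8
    diet = ["SC"] * 4 + ["CM"] * 4
    lat = np.where(np.array(diet) == "CM", 2.0, 0.0) + rng.normal(0, 1, n)
    t = pd.DataFrame({
        "diet": diet,
        "final_weight": 24 + 1.5 * lat + rng.normal(0, 0.5, n),
        "pct_gain": 18 + 6 * lat + rng.normal(0, 2, n),
        "grooming": 80 + 25 * lat + rng.normal(0, 8, n),
        "nesting": 2 + 0.5 * lat + rng.normal(0, 0.2, n),
        "intake_d1": 40 + 8 * lat + rng.normal(0, 3, n),
        "intake_d2": 45 + 8 * lat + rng.normal(0, 3, n),
        "intake_d3": 48 + 8 * lat + rng.normal(0, 3, n),
        "quinine": 35 + 9 * lat + rng.normal(0, 3, n),
        "total_intake": 250 + 40 * lat + rng.normal(0, 10, n),
        "eating_rate": 2 + 0.5 * lat + rng.normal(0, 0.1, n),
    }, index=pd.Index([f"m{i+1}" for i in range(n)], name="mouse"))
    return PhenotypeTable(t)
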