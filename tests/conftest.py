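import numpy as np
import pandas as pd
import pytest

from locus_echo import datasets, genome_map
from locus_echo.synthetic import SimulationConfig, simulate_expression, simulate_genome


@pytest.fixture(scope="session")
def yeast_map():
    """The packaged freeze-thaw locus gene-order map."""
    return datasets.freeze_thaw_annotation()


@pytest.fixture(scope="session")
def small_sim():
    """One simulated chromosome with its expression compendium (3 blocks)."""
    cfg = SimulationConfig(
        n_chromosomes=1,
        genes_per_chromosome=12,
        decay_amplitude=0.7,
        decay_length=8000,
        baseline_corr=0.05,
        n_blocks=3,
        samples_per_block=40,
        seed=42,
    )
    annotation = simulate_genome(cfg)
    expr = simulate_expression(annotation, cfg)
    return cfg, annotation, expr


@pytest.fixture()
def two_gene_annotation():
    """Two genes 1 kb apart (midpoint to midpoint) on one chromosome."""
    genes = pd.DataFrame(
        {
            "gene_id": ["gA", "gB"],
            "chromosome": ["c1", "c1"],
            "start": [0, 1000],
            "end": [200, 1200],
            "strand": ["+", "-"],
            "is_essential": [False, False],
        }
    )
    return genome_map.AnnotationTable(genes)
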