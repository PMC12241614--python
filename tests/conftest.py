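import numpy as np
import pandas as pd
import pytest

from netage import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Session-wide small synthetic cohort (no network inference run here)."""
    return generate_cohort(
        CohortSpec(n_tfs=10, n_genes=60, n_samples=30, n_chry_genes=4,
                   n_pathways=3, seed=42)
    )


@pytest.fixture()
def toy_annotations():
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC", "gY1", "gY2"],
            "chromosome": ["chr1", "chr1", "chr2", "chrY", "chrY"],
            "strand": ["+", "-", "+", "+", "-"],
            "tss": [10_000, 20_000, 10_000, 5_000, 9_000],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
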