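import numpy as np
import pandas as pd
import pytest

import poolfit as pf


def make_key(truth: pd.DataFrame) -> pd.DataFrame:
    """Strain key corresponding to a simulated truth table."""
    return pd.DataFrame(
        {
            "strain_id": truth["strain_id"],
            "gene": truth["gene"],
            "zygosity": truth["zygosity"],
            "in_pool": truth["in_pool"],
            "annotation_class": truth["annotation_class"],
            "has_up_tag": True,
            "has_dn_tag": True,
        }
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A compact planted-effect experiment shared by read-only tests:
    400 strains (30 depleted at s=-0.4, 15 enriched at +0.4), 60 false
    barcodes, 3 replicate spots, moderate noise."""
    return pf.simulate_experiment(
        n_strains=400,
        frac_depleted=0.075,
        frac_enriched=0.0375,
        n_false_barcodes=60,
        dead_tag_rate=0.05,
        n_replicate_spots=3,
        noise_sd_log2=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_key(small_experiment):
    return make_key(small_experiment.truth)


@pytest.fixture(scope="session")
def small_matrix(small_experiment, small_key):
    normalized = pf.normalize.normalize_all(small_experiment.scans, key=small_key)
    matrix, tag_matrix = pf.tagstats.build_fitness_matrix(normalized, small_key)
    return matrix, tag_matrix


def rand_matrix(rng: np.random.Generator, n_rows: int, n_cols: int = 6) -> pd.DataFrame:
    """Random fitness-profile matrix with distinct, tie-free values."""
    vals = rng.normal(size=(n_rows, n_cols)) * 2.0
    return pd.DataFrame(vals, index=[f"R{i}" for i in range(n_rows)])
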