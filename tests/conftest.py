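import numpy as np
import pandas as pd
import pytest

from hervscreen.barcode_enrichment import CountsTable
from hervscreen.synthetic_data import SimulationConfig, nb_counts


@pytest.fixture
def small_cfg():
    """A scaled-down cohort: quick to generate, still exercises every stage."""
    return SimulationConfig(
        seed=11,
        n_loci=10,
        n_healthy=6,
        n_pre=8,
        n_post=8,
        response_prob_by_class={"healthy": 0.01, "pre": 0.05, "post": 0.06},
    )


def make_null_table(rng, n_barcodes=200, depth=100.0, dispersion=0.1, planted=None):
    """One experiment: triplicate baselines plus a sorted sample from the
    same null, optionally with planted enriched barcodes {index: mean}."""
    mean = np.full(n_barcodes, depth)
    if planted:
        for idx, m in planted.items():
            mean[idx] = m
    cols = {f"S_baseline_{k}": nb_counts(rng, depth, dispersion, n_barcodes) for k in (1, 2, 3)}
    cols["S"] = nb_counts(rng, mean, dispersion)
    df = pd.DataFrame(cols, index=[f"B{i}" for i in range(n_barcodes)])
    return CountsTable(df, {"S": ["S_baseline_1", "S_baseline_2", "S_baseline_3"]})
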