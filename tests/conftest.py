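import numpy as np
import pandas as pd
import pytest

from fracloc.beta_model import BetaModelConfig
from fracloc.io_quant import FractionQuantSet, quant_frame
from fracloc.preprocess import filter_by_cpm
from fracloc.simulate import SimConfig, generate_dataset


def make_fraction_set(counts, efflens, ids=None, sample_id="s", replicate_id="1"):
    """Build a FractionQuantSet from raw (whole, nuclear, cytosolic) count
    vectors, with CPM/FPKM computed per fraction."""
    from fracloc.io_quant import assemble_fraction_set, compute_cpm, compute_fpkm

    whole, nuclear, cytosolic = counts
    n = len(whole)
    ids = ids if ids is not None else [f"T{i}" for i in range(n)]
    frames = []
    for vec in (whole, nuclear, cytosolic):
        qf = quant_frame(ids, np.asarray(vec, float), np.asarray(efflens, float))
        frames.append(compute_fpkm(compute_cpm(qf)))
    return assemble_fraction_set(*frames, sample_id=sample_id, replicate_id=replicate_id)


@pytest.fixture(scope="session")
def quick_model_config():
    """Reduced sampler settings for fast, still well-mixed unit tests."""
    return BetaModelConfig(chains=2, draws_per_chain=900, warmup=300, seed=7)


@pytest.fixture(scope="session")
def sim_beta06():
    """Desk-scale simulated dataset at target beta 0.6, CPM-filtered."""
    cfg = SimConfig(
        n_transcripts=2000, total_molecules=100_000,
        target_beta=0.6, depth=1_000_000, seed=11,
    )
    fqs, tx = generate_dataset(cfg)
    return filter_by_cpm(fqs), tx, cfg


@pytest.fixture(scope="session")
def sim_beta08():
    cfg = SimConfig(
        n_transcripts=2000, total_molecules=100_000,
        target_beta=0.8, depth=1_000_000, seed=13,
    )
    fqs, tx = generate_dataset(cfg)
    return filter_by_cpm(fqs), tx, cfg


@pytest.fixture(scope="session")
def fig1_worked_example():
    """Two-gene worked example: molecule counts, expected depth-1000 reads.

    Cell type 1: gene A 40 nuclear / 60 cytosolic, gene B 110/90.
    Cell type 2: gene A 40/60, gene B 20/180. Equal lengths.
    """
    depth = 1000.0

    def expected(counts):
        counts = np.asarray(counts, float)
        return counts / counts.sum() * depth

    return {
        "cell1": {
            "m_n": np.array([40.0, 110.0]),
            "m_c": np.array([60.0, 90.0]),
            "reads_n": expected([40, 110]),
            "reads_c": expected([60, 90]),
        },
        "cell2": {
            "m_n": np.array([40.0, 20.0]),
            "m_c": np.array([60.0, 180.0]),
            "reads_n": expected([40, 20]),
            "reads_c": expected([60, 180]),
        },
        "depth": depth,
        "length": 1000.0,
    }
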