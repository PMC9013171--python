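import numpy as np
import pytest

from medkgqa import (BootstrapConfig, LedgerOracle, SeedStore, generate_kb,
                     render_qa_pairs, render_records)
from medkgqa.pipeline import initial_seeds, run_pipeline

NOISE_LEVELS = (0.0, 0.15, 0.3)


@pytest.fixture(scope="session")
def small_kb():
    return generate_kb(12, 6, rng_seed=3)


@pytest.fixture(scope="session")
def small_corpus(small_kb):
    records, ledger = render_records(small_kb, 250, 3.3, 0.0, rng_seed=1)
    return records, ledger


@pytest.fixture(scope="session")
def ledger_oracle(small_kb, small_corpus):
    return LedgerOracle(small_kb, small_corpus[1])


@pytest.fixture(scope="session")
def qa_pairs(small_kb):
    pairs, _ = render_qa_pairs(small_kb, 200, rng_seed=5)
    return pairs


@pytest.fixture(scope="session")
def seed_store(small_kb):
    return initial_seeds(small_kb)


@pytest.fixture(scope="session")
def pipeline_results():
    """The full study at three injected noise levels (shared; expensive)."""
    return {noise: run_pipeline(seed=1, n_records=250, n_qa=200,
                                noise_rate=noise)
            for noise in NOISE_LEVELS}


@pytest.fixture(scope="session")
def clean_run(pipeline_results):
    return pipeline_results[0.0]
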