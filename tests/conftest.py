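import numpy as np
import pytest

from calseg import GeneratorConfig, build_sequences, generate, pairwise_matrix


@pytest.fixture(scope="session")
def small_run():
    """A small synthetic dataset with its dissimilarity matrix (n=200)."""
    cfg = GeneratorConfig(
        n_strata=2, psus_per_stratum=5, women_per_psu=20, seed=7
    )
    records, truth = generate(cfg)
    seqs, excluded = build_sequences(records)
    assert not excluded
    weights = np.array([r.weight for r in records])
    dissim = pairwise_matrix(seqs, weights)
    return {
        "config": cfg,
        "records": records,
        "truth": truth,
        "seqs": seqs,
        "weights": weights,
        "dissim": dissim,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
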