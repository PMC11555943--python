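import numpy as np
import pytest

from adrfuse import autodiff
from adrfuse.corpus import build_frequency_matrix, positive_samples, sample_negatives
from adrfuse.synthetic import SyntheticSpec, generate_corpus
from adrfuse.text import HashedBagOfWordsEncoder
from adrfuse.training import TrainingConfig, prepare_features


@pytest.fixture
def float64_mode():
    """Run autodiff in double precision (finite-difference gradient checks
    and exact-permutation assertions need it)."""
    autodiff.set_dtype(np.float64)
    yield
    autodiff.set_dtype(np.float32)


@pytest.fixture(scope="session")
def tiny_synthetic():
    """A small but complete synthetic corpus shared across tests."""
    spec = SyntheticSpec(n_drugs=12, n_side_effects=15, latent_rank=3, sparsity=0.15,
                         noise_sd=0.2, seed=7)
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def tiny_features(tiny_synthetic):
    syn = tiny_synthetic
    matrix = build_frequency_matrix(syn.corpus)
    samples = positive_samples(matrix) + sample_negatives(matrix, 7)
    feats = prepare_features(
        syn.corpus, syn.drug_chem, syn.drug_disease, HashedBagOfWordsEncoder(),
        train_matrix=matrix,
    )
    return feats, samples, matrix


@pytest.fixture
def smoke_config():
    return TrainingConfig(dim=8, max_epochs=2, batch_size=16, seed=3,
                          fusion_out=8, head_hidden=8, dropout=0.4)
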