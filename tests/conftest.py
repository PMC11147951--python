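import numpy as np
import pytest

from nfscore.classifier import labeled_set_from_features, train
from nfscore.spectral import featurize_sequences
from nfscore.synthetic import (SyntheticSpec, gen_toy_genome,
                               gen_toy_pentamer_table, gen_training_set)


@pytest.fixture(scope="session")
def at_table():
    """Complete toy table with values monotone in A/T content (rc-symmetric)."""
    return gen_toy_pentamer_table("at_content")


@pytest.fixture(scope="session")
def rc_table():
    """Complete random table with reverse-complement symmetry enforced."""
    return gen_toy_pentamer_table("rc_symmetric_random", seed=7)


@pytest.fixture(scope="session")
def training_small(at_table):
    """A 500+500 high-margin synthetic set with its feature matrix.

    The size keeps the binomial SD of a pooled chance-level accuracy near
    0.016, so a +/-0.05 band on the permutation null is a ~3-sigma bound.
    """
    spec = SyntheticSpec(n_pos=500, n_neg=500, seed=11)
    ts = gen_training_set(spec)
    feats = featurize_sequences(ts.sequences, at_table, ids=ts.ids)
    return ts, labeled_set_from_features(feats, ts.labels)


@pytest.fixture(scope="session")
def model_small(training_small):
    """A forest trained on the small synthetic set."""
    _, data = training_small
    return train(data, n_trees=200, seed=11)


@pytest.fixture(scope="session")
def toy_genome():
    return gen_toy_genome(60_000, 40, seed=5)


def random_seq(rng, n=147):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
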