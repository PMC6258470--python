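import numpy as np
import pytest

from rnaqa import (
    DecoyGenConfig,
    FeaturizeConfig,
    ModelSpec,
    TrainingSchedule,
    apply_normalization,
    build_model,
    fit_normalization,
    make_toy_rna,
    make_training_set,
    train,
)


@pytest.fixture(scope="session")
def toy_structure():
    """14-nucleotide toy helix with properties assigned (read-only)."""
    return make_toy_rna(DecoyGenConfig(n_nucleotides=14))


@pytest.fixture()
def config():
    return FeaturizeConfig()


@pytest.fixture(scope="session")
def tiny_spec():
    """A seconds-scale network used by optimizer-level unit tests."""
    return ModelSpec(conv_filters=(2, 2), conv_kernels=(3, 3),
                     pool_after_layer=2, dense_units=4, input_channels=2,
                     grid_edge=8, dropout_layers=frozenset())


@pytest.fixture(scope="session")
def desk_run():
    """The desk-scale end-to-end run: synthetic set, stats, trained model.

    Expensive (minutes); shared by the learning/ranking acceptance checks.
    """
    gen = DecoyGenConfig(n_nucleotides=14, n_decoys=5, seed=0)
    samples = list(make_training_set(gen, sigmas=(0.1, 0.5, 1.0)))
    stats = fit_normalization((g for g, _, _ in samples),
                              (l for _, l, _ in samples))
    pairs = [(apply_normalization(g, stats), apply_normalization(l, stats))
             for g, l, _ in samples]
    model = build_model(ModelSpec.desk_scale(), seed=0)
    model.normalization = stats
    train(model, pairs, pairs, TrainingSchedule.desk_scale(seed=0))
    return {"generator": gen, "samples": samples, "stats": stats,
            "pairs": pairs, "model": model}
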