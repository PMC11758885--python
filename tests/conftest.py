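"""Shared fixtures: small synthetic datasets and trained-model caches."""

from __future__ import annotations

import numpy as np
import pytest

from lwheatnet import (GeneratorConfig, ModelConfig, ScheduleConfig, SplitSpec,
                       TrainConfig, build_model, evaluate_model, fit,
                       generate_dataset, load_split_arrays, split_dataset)

ACCEPTANCE_SEED = 0

# study conditions of the synthetic training experiment: 5 classes,
# 50 images per class at 64 pixels, 10 epochs at the published
# hyperparameters (batch 16, lr 3e-3, momentum 0.9, weight decay 4e-5)
ACCEPT_GEN = dict(classes=5, images_per_class=50, canvas_size=64,
                  seed=ACCEPTANCE_SEED)
ACCEPT_TRAIN = dict(epochs=10, seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def synthetic_tree(tmp_path_factory):
    """A generated 5-class dataset tree at the default study conditions."""
    root = tmp_path_factory.mktemp("synthetic") / "data"
    cfg = GeneratorConfig(**ACCEPT_GEN)
    records = generate_dataset(cfg, root)
    return root, records, cfg


@pytest.fixture(scope="session")
def synthetic_arrays(synthetic_tree):
    """Split and materialised arrays for the synthetic dataset."""
    _, records, _ = synthetic_tree
    records = split_dataset(records, SplitSpec(seed=ACCEPTANCE_SEED))
    return load_split_arrays(records, input_size=64, seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def trained_variants(synthetic_arrays):
    """All three build variants trained for 10 epochs on the synthetic data;
    returns {variant: (model, train_state, test_evaluation)}."""
    out = {}
    for variant in ("backbone", "backbone+tpsa", "backbone+tpsa+eca"):
        model = build_model(ModelConfig(input_size=64, variant=variant,
                                        seed=ACCEPTANCE_SEED))
        state = fit(model, synthetic_arrays.train, TrainConfig(**ACCEPT_TRAIN),
                    val_data=synthetic_arrays.val)
        result = evaluate_model(model, synthetic_arrays.test[0],
                                synthetic_arrays.test[1])
        out[variant] = (model, state, result)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
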