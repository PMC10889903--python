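"""Shared fixtures: the stimulus grid, scored strengths and a small
trained classifier reused across the analysis tests."""

import pytest

from illusionprobe import (
    HyperParams,
    ResponseModelParams,
    aggregate_strengths,
    build_independent_test,
    build_training_pool,
    enumerate_stimulus_grid,
    make_model,
    manifest_to_arrays,
    simulate_responses,
    split_train_val,
    train,
)


@pytest.fixture(scope="session")
def grid():
    return enumerate_stimulus_grid()


@pytest.fixture(scope="session")
def strengths(grid):
    records = simulate_responses(grid, ResponseModelParams(seed=0))
    return aggregate_strengths(records)


@pytest.fixture(scope="session")
def small_hp():
    return HyperParams(epochs=2, seed=11)


@pytest.fixture(scope="session")
def small_manifests():
    pool = build_training_pool(per_level=8, seed=11)
    train_m, val_m = split_train_val(pool, seed=11)
    test_m = build_independent_test(n=16, seed=12)
    return train_m, val_m, test_m


@pytest.fixture(scope="session")
def small_model(small_manifests, small_hp):
    """A briefly trained desknet; enough structure for saliency and
    representation tests, not meant to be accurate."""
    train_m, val_m, _ = small_manifests
    Xtr, ytr = manifest_to_arrays(train_m, downscale=small_hp.downscale)
    Xva, yva = manifest_to_arrays(val_m, downscale=small_hp.downscale)
    model = make_model("desknet", seed=small_hp.seed, input_hw=Xtr.shape[1:3])
    train(model, train_m, val_m, small_hp, data=((Xtr, ytr), (Xva, yva)))
    return model
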