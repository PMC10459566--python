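import numpy as np
import pytest

from pcsem.resnet import ModelSpec, build_model
from pcsem.synthetic import SceneSpec, generate_dataset
from pcsem.training import TrainConfig, evaluate, train

# Desk-scale ("fast mode") study conditions shared by the end-to-end tests:
# 64x64 frames from the default synthetic scene distribution, the full
# ResNet50 backbone, and the unmodified 10-epoch training recipe.
FAST = {
    "image_size": (64, 64),
    "n_train": 200,
    "n_test": 100,
    "seeds": (13, 17),
}


def _run_one(seed: int, attention: str | None):
    train_ds = generate_dataset(SceneSpec(image_size=FAST["image_size"], seed=seed),
                                FAST["n_train"])
    test_ds = generate_dataset(SceneSpec(image_size=FAST["image_size"],
                                         seed=seed + 1000), FAST["n_test"])
    placement = "place2" if attention else "none"
    model = build_model(ModelSpec(attention=attention, placement=placement,
                                  head_classes=7), seed=seed)
    model, log = train(model, train_ds.training_arrays(), TrainConfig(seed=seed))
    result = evaluate(model, test_ds.training_arrays())
    return {"model": model, "log": log, "map": result.map, "result": result,
            "test_ds": test_ds}


@pytest.fixture(scope="session")
def trained_fast_models():
    """Train P-CSEM (place 2, R=16) and the attention-free base model from
    random init on the default synthetic task, for both study seeds."""
    runs = {}
    for seed in FAST["seeds"]:
        runs[(seed, "pcsem")] = _run_one(seed, "pcsem")
        runs[(seed, "base")] = _run_one(seed, None)
    return runs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
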