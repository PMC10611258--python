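"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from somaxon.classifier import TrainConfig, build_training_set, train
from somaxon.phenotypes import (PhenotypeParams, default_label_map,
                                default_profiles)
from somaxon.simulate import generate_soma_image

#: Severity-1 soma damage without puncta: shrunken, deformed, dimmed cells.
#: Dropping the puncta keeps the two classes separable by mean intensity,
#: which the logistic-regression oracle below relies on.
DAMAGED_PARAMS = PhenotypeParams(
    soma_severity=1.0, soma_shrinkage=0.45, contour_irregularity=0.35,
    puncta_rate=0.0, luminance_loss=0.35)
HEALTHY_PARAMS = PhenotypeParams.from_severity(0.0, 0.0)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def label_map(profiles):
    return default_label_map(profiles)


def make_soma_images(params: PhenotypeParams, n: int, seed0: int, *,
                     width: int = 576, n_somata: int = 400,
                     split: str = "train", compound: str = "DMSO"):
    """Dense soma images (nearly every tile contains cell material)."""
    images = []
    for i in range(n):
        img = generate_soma_image(params, width, width, seed0 + i,
                                  n_somata=n_somata, spontaneous=False)
        img.compound = compound
        img.split = split
        img.replicate = i
        img.image_id = f"{compound}_{seed0}_{i}"
        images.append(img)
    return images


@pytest.fixture(scope="session")
def separable_dataset(label_map):
    """Weak-labelled tiles from strongly separable healthy/damaged images.

    Two cell-free fields are included on the negative side so the model
    also learns that bare background is not damage.
    """
    images = (make_soma_images(HEALTHY_PARAMS, 6, 100, compound="DMSO") +
              make_soma_images(HEALTHY_PARAMS, 2, 300, n_somata=0,
                               compound="DMSO") +
              make_soma_images(DAMAGED_PARAMS, 6, 200, compound="oxaliplatin"))
    return build_training_set(images, "soma", label_map)


@pytest.fixture(scope="session")
def separable_soma_model(separable_dataset):
    """CNN trained on the strongly separable tile set."""
    return train(separable_dataset, seed=7, config=TrainConfig(epochs=10))
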