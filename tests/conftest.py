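"""Shared fixtures: phantoms and a trained district classifier.

Everything is generated programmatically; training phantoms use seeds
disjoint from any evaluation phantom so the classifier is never applied to
a case it saw.
"""

import numpy as np
import pytest

from dopaquant import (PipelineConfig, compute_district_features,
                       generate_phantom, label_districts_from_mask,
                       parcellate, run_case, train_classifier)
from dopaquant.phantom import PhantomSpec

TRAIN_SPECS = (
    PhantomSpec(seed=101),
    PhantomSpec(seed=102, lesion_side="left"),
    PhantomSpec(seed=103),
    PhantomSpec(seed=104, background_noise_sigma=0.0),
    PhantomSpec(seed=105, background_noise_sigma=0.0, lesion_side="left"),
)


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def trained_model(cfg):
    """Classifier fitted on districts of noisy and noiseless training
    phantoms (both lesion sides), labelled from the ground-truth lesion
    masks."""
    pool = []
    for spec in TRAIN_SPECS:
        bundle = generate_phantom(spec)
        hemis = (bundle.atlas.hemisphere_mask("left")
                 | bundle.atlas.hemisphere_mask("right"))
        districts = parcellate(bundle.flair, hemis, cfg)
        compute_district_features(districts, bundle.flair)
        label_districts_from_mask(districts, bundle.truth["lesion_mask"])
        pool.extend(districts)
    return train_classifier(pool, seed=0)


@pytest.fixture(scope="session")
def noiseless_bundle():
    return generate_phantom(PhantomSpec(background_noise_sigma=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_bundle():
    return generate_phantom(PhantomSpec(seed=12))


@pytest.fixture(scope="session")
def noiseless_result(noiseless_bundle, trained_model, cfg):
    b = noiseless_bundle
    return run_case(b.pet, b.flair, b.atlas, trained_model, cfg)


@pytest.fixture(scope="session")
def noisy_result(noisy_bundle, trained_model, cfg):
    b = noisy_bundle
    return run_case(b.pet, b.flair, b.atlas, trained_model, cfg)
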