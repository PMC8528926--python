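import numpy as np
import pandas as pd
import pytest

from mitoscreen.image_core import LabelMaps, SegmentationConfig
from mitoscreen.morphology import extract_features
from mitoscreen.ratiometric import RatioConfig
from mitoscreen.synthetic_data import (SceneConfig, generate_field,
                                       generate_morphology_set)


@pytest.fixture(scope="session")
def seg_cfg():
    # backgrounds in the generator are flat, so constant subtraction is exact
    return SegmentationConfig(background_method="constant")


@pytest.fixture(scope="session")
def ratio_cfg():
    return RatioConfig()


@pytest.fixture(scope="session")
def clean_scene():
    """Low-noise, low-blur scene config used where geometry matters."""
    return SceneConfig(rng_seed=33, psf_sigma=0.8, mitolysosomes_per_cell=4.0)


@pytest.fixture(scope="session")
def clean_field(clean_scene):
    return generate_field(clean_scene)


def truth_labelmaps(truth):
    return LabelMaps(nuclei=truth.nuclei_mask, cells=truth.cell_mask,
                     mito=truth.mito_mask)


def morphology_feature_table(n_per_class, classes, seed):
    """Per-cell features extracted from ground-truth masks of generated
    morphology fields, with the class label attached."""
    rows = []
    for field, truth in generate_morphology_set(n_per_class, classes, seed):
        df = extract_features(truth_labelmaps(truth))
        df["label"] = field.metadata["morphology"]
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


@pytest.fixture(scope="session")
def small_morphology_features():
    return morphology_feature_table(8, ["tubular", "fragmented"], seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
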