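import numpy as np
import pytest

from algaespec.features import build_feature_table
from algaespec.simulate import (
    AnchorTable,
    GeneratorConfig,
    TEMPLATE_ANCHORS,
    build_reference_curve,
    generate_dataset,
)

GRID = np.arange(400.0, 901.0)


@pytest.fixture(scope="session")
def grid():
    return GRID.copy()


@pytest.fixture(scope="session")
def ulva_ref():
    return build_reference_curve(AnchorTable("Ulva", TEMPLATE_ANCHORS["Ulva"]), GRID)


@pytest.fixture(scope="session")
def sargassum_ref():
    return build_reference_curve(AnchorTable("Sargassum", TEMPLATE_ANCHORS["Sargassum"]), GRID)


@pytest.fixture(scope="session")
def rhodophyta_ref():
    return build_reference_curve(AnchorTable("Rhodophyta", TEMPLATE_ANCHORS["Rhodophyta"]), GRID)


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded draw of the default 382-sample synthetic dataset."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_features(default_dataset):
    return build_feature_table(default_dataset)
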