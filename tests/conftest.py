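"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from spacetrace import synthetic_tissue as st
from spacetrace.msi_data import PixelMatrix


@pytest.fixture(scope="session")
def small_config():
    """Three well-separated cell types on a 40x40 grid, two metabolites."""
    return st.SimConfig(
        shape=(40, 40),
        n_types=3,
        n_lipids=20,
        noise_cv=0.1,
        metabolites=(("hexose", 6, 179.0561), ("glutamate", 5, 146.0459)),
        tracers={"glc13": (15.0, 30.0, 60.0, 120.0)},
        sites_per_type=6,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    control, labeled, truth = st.generate(small_config, seed=2)
    return control, labeled, truth


@pytest.fixture(scope="session")
def lipid_ids(small_config):
    feats = st.feature_table(small_config)
    return list(feats.loc[feats["kind"] == "lipid", "feature_id"])


@pytest.fixture
def tiny_pm():
    """Hand-built 6-pixel, 3-feature matrix on a 3x2 grid."""
    coords = np.array([[0, 0], [1, 0], [2, 0], [0, 1], [1, 1], [2, 1]])
    intens = np.array(
        [
            [2.0, 3.0, 5.0],
            [1.0, 1.0, 2.0],
            [4.0, 4.0, 2.0],
            [10.0, 0.0, 0.0],
            [0.5, 0.5, 1.0],
            [3.0, 3.0, 4.0],
        ]
    )
    return PixelMatrix(
        section_id="tiny",
        coords=coords,
        intensities=intens,
        feature_ids=["lipA", "lipB", "met"],
    )
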