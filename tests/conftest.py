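import numpy as np
import pytest

import poipcm as pp


@pytest.fixture(scope="session")
def design():
    return pp.default_design()


@pytest.fixture(scope="session")
def library(design):
    return pp.standard_library(design)


@pytest.fixture(scope="session")
def lat_library(design):
    return pp.standard_library(design, lateralized=True)


@pytest.fixture(scope="session")
def two_poi_dataset(library):
    """N=60 similarity vectors: 0.05 + 0.12*nST + 0.06*ET + N(0, 0.02)."""
    cfg = pp.GeneratorConfig(n_participants=60, weights={"nST": 0.12, "ET": 0.06},
                             intercept=0.05, noise_sd=0.02, seed=1)
    return pp.gen_similarity(cfg, library)


@pytest.fixture(scope="session")
def cohort_dataset(library):
    """Full 67-participant cohort for cross-validation tests."""
    cfg = pp.GeneratorConfig(n_participants=67, weights={"nST": 0.12, "ET": 0.06},
                             intercept=0.05, noise_sd=0.02, seed=2)
    return pp.gen_similarity(cfg, library)
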