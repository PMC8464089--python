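import numpy as np
import pandas as pd
import pytest

from eegfractal import (
    SyntheticCorpusSpec,
    build_feature_table,
    generate_bonn_mimic,
)
from eegfractal.features import feature_names


@pytest.fixture(scope="session")
def mimic_corpus():
    """The full five-class synthetic corpus (500 segments, fixed seed)."""
    return generate_bonn_mimic(SyntheticCorpusSpec(seed=7))


@pytest.fixture(scope="session")
def mimic_features(mimic_corpus):
    """Feature table of the full synthetic corpus (computed once per session)."""
    return build_feature_table(mimic_corpus)


@pytest.fixture(scope="session")
def small_corpus():
    """A small corpus (5 classes x 8 segments) for structural tests."""
    return generate_bonn_mimic(SyntheticCorpusSpec(seed=3, segments_per_class=8))


@pytest.fixture(scope="session")
def feature_cols():
    return feature_names()
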