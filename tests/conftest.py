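import numpy as np
import pandas as pd
import pytest

from projcensus.regions import RegionNode, RegionOntology
from projcensus.synth import SyntheticConfig, make_synthetic_ontology


@pytest.fixture
def toy_ontology() -> RegionOntology:
    """root -> {striatum -> CP, thalamus -> dorsal -> VAL}; CP and VAL are targets."""
    return RegionOntology(
        [
            RegionNode("root", "root", None),
            RegionNode("STR", "STR", "root", major_division="striatum"),
            RegionNode("CP", "CP", "STR", is_summary_target=True),
            RegionNode("TH", "TH", "root", major_division="thalamus"),
            RegionNode("DORpm", "DORpm", "TH"),
            RegionNode("VAL", "VAL", "DORpm", is_summary_target=True),
        ]
    )


@pytest.fixture
def synth_ontology():
    return make_synthetic_ontology()


@pytest.fixture
def config() -> SyntheticConfig:
    return SyntheticConfig(seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def small_fraction_frame() -> pd.DataFrame:
    """4 rows forming two orthogonal pattern pairs over 6 targets."""
    rows = {
        "a1": [0.5, 0.5, 0.0, 0.0, 0.0, 0.0],
        "a2": [0.45, 0.55, 0.0, 0.0, 0.0, 0.0],
        "b1": [0.0, 0.0, 0.0, 0.0, 0.5, 0.5],
        "b2": [0.0, 0.0, 0.0, 0.0, 0.55, 0.45],
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = [f"R{i}:ipsi" for i in range(6)]
    # break rank ties deterministically with tiny jitter
    jitter = np.random.default_rng(0).normal(0, 1e-6, frame.shape)
    return frame + np.abs(jitter)
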