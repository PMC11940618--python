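import pytest

from nephroscreen import datasets
from nephroscreen.doseresponse import normalize_to_vehicle
from nephroscreen.simulate import TruthParams, generate_plate_dataset


@pytest.fixture(scope="session")
def annotations():
    return datasets.compound_annotations()


@pytest.fixture(scope="session")
def call_matrix():
    return datasets.call_matrix()


@pytest.fixture(scope="session")
def in_vivo_labels():
    return datasets.in_vivo_labels()


@pytest.fixture()
def noiseless_points():
    """Vehicle-normalized points from an exact logistic truth (EC50=10, hill=1)."""
    params = TruthParams(noise_cv=0.0, bottom=0.0, ec50_true=10.0, hill=1.0, seed=0)
    return normalize_to_vehicle(generate_plate_dataset(params))
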