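import numpy as np
import pytest
from hypothesis import settings

from trapsense import classify, features, simulate

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_lab_recordings():
    """~560 recordings, 10% invalid, across all class x temperature cells."""
    return simulate.simulate_lab_dataset(40, invalid_fraction=0.1, rng_seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_lab_recordings):
    """Balanced LabeledDataset of valid recordings from the small lab batch."""
    valid = [
        r
        for r in small_lab_recordings
        if features.clean_recording(r).valid and r.validity.value == "VALID"
    ]
    table = features.extract_feature_table(valid)
    data = classify.LabeledDataset(
        features.feature_matrix(table),
        table["label"].to_numpy(),
        table["temperature"].to_numpy(float),
    )
    return classify.balance_by_undersampling(data, rng_seed=0)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return classify.split_test_set(small_dataset, 80, rng_seed=1)


@pytest.fixture(scope="session")
def small_model(small_split):
    train, _ = small_split
    return classify.train_classifier(
        train, grid=[{"max_depth": 3, "learning_rate": 0.3}], rng_seed=0
    )
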