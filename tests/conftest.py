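import pytest
from hypothesis import HealthCheck, settings

import toxcascade as tc

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def small_toxin_dataset() -> tc.LabeledDataset:
    """Four-class motif dataset small enough for fast training tests."""
    return tc.generate(tc.default_toxin_spec(seed=11, n_per_class=80))


@pytest.fixture(scope="session")
def small_split(small_toxin_dataset):
    return tc.capped_fraction_split(small_toxin_dataset, tc.SplitSpec(seed=11))


@pytest.fixture(scope="session")
def trained_toxin_model(small_toxin_dataset, small_split):
    """One trained 4-class model shared across tests (64-residue inputs)."""
    clf = tc.TrainedClassifier(
        tc.EncoderSpec(fixed_length=64),
        small_toxin_dataset.class_labels,
        tc.TrainingSpec(seed=11, epochs=24),
    )
    clf.fit(
        small_split.train_subset(small_toxin_dataset),
        small_split.val_subset(small_toxin_dataset),
    )
    return clf


@pytest.fixture(scope="session")
def trained_housekeeping_model():
    ds = tc.generate(tc.default_housekeeping_spec(seed=12, n_toxin=400, n_other=400))
    res = tc.capped_fraction_split(ds, tc.SplitSpec(seed=12, train_cap=300))
    clf = tc.TrainedClassifier(
        tc.EncoderSpec(fixed_length=64), ds.class_labels,
        tc.TrainingSpec(seed=12, epochs=24),
    )
    return clf.fit(res.train_subset(ds), res.val_subset(ds))


@pytest.fixture(scope="session")
def trained_functional_ensemble():
    ds = tc.generate(tc.default_functional_spec(seed=13))
    ensemble = []
    for seed in (21, 22, 23):
        res = tc.fixed_train_split(ds, tc.SplitSpec(mode="fixed_train", seed=seed))
        clf = tc.TrainedClassifier(
            tc.EncoderSpec(fixed_length=64), ds.class_labels,
            tc.TrainingSpec(epochs=8, batch_size=8, seed=seed),
        )
        ensemble.append(clf.fit(res.train_subset(ds), res.val_subset(ds)))
    return ensemble
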