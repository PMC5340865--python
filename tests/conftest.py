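import numpy as np
import pytest

from bloomcull import (
    FeatureTable,
    SampleMetadata,
    SimulationConfig,
    simulate_cohort_studies,
    simulate_storage_study,
)


@pytest.fixture
def tiny_table() -> FeatureTable:
    """2 samples x 3 sequence-keyed features with easy totals."""
    return FeatureTable(
        ["s1", "s2"],
        ["ACGT", "CCGT", "GGGT"],
        np.array([[6, 0, 2], [2, 2, 0]]),
    )


@pytest.fixture
def storage_metadata() -> SampleMetadata:
    """One subject, frozen day 0 plus two room-temperature time points."""
    return SampleMetadata.from_records(
        [
            {"sample_id": "d0", "study_id": "stor", "condition": "frozen",
             "subject_id": "a", "day": 0},
            {"sample_id": "d1", "study_id": "stor", "condition": "room_temperature",
             "subject_id": "a", "day": 1},
            {"sample_id": "d4", "study_id": "stor", "condition": "room_temperature",
             "subject_id": "a", "day": 4},
        ]
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One full default scenario (storage study + cohorts), seed 0."""
    cfg = SimulationConfig(seed=0)
    storage_table, storage_md, _ = simulate_storage_study(cfg)
    cohort_tables, cohort_md, truth = simulate_cohort_studies(cfg)
    return {
        "config": cfg,
        "storage_table": storage_table,
        "storage_metadata": storage_md,
        "cohort_tables": cohort_tables,
        "cohort_metadata": cohort_md,
        "truth": truth,
    }


def random_table(rng: np.random.Generator, n_samples=None, n_features=None) -> FeatureTable:
    """A random valid sequence-keyed table for property tests."""
    n_samples = n_samples or int(rng.integers(1, 6))
    n_features = n_features or int(rng.integers(1, 12))
    seqs = set()
    while len(seqs) < n_features:
        seqs.add("".join(rng.choice(list("ACGT"), size=8)))
    counts = rng.integers(0, 50, size=(n_samples, n_features))
    return FeatureTable(
        [f"s{i}" for i in range(n_samples)], sorted(seqs), counts.astype(np.int64)
    )
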