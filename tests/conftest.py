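"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from adomics import (
    ExperimentConfig,
    LabelVector,
    OmicsTable,
    SyntheticConfig,
    align_modalities,
    generate_cohort,
)
from adomics.select import SelectionConfig


@pytest.fixture(scope="session")
def small_synthetic():
    """A compact planted-signal cohort: 60+40 samples, 120 probes, 60 taxa."""
    cfg = SyntheticConfig(
        n_cases=55,
        n_controls=45,
        n_probes=120,
        n_taxa=60,
        n_signal_probes=10,
        n_signal_taxa=8,
        probe_effect=1.5,
        taxa_effect=4.0,
        zero_inflation=0.5,
        missing_transcriptome=1,
        missing_microbiota=1,
        seed=42,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_synthetic):
    _cfg, (t, m, y, _truth) = small_synthetic
    return align_modalities(t, m, y)


@pytest.fixture(scope="session")
def paper_shaped_synthetic():
    """The study cohort's shape (161 samples, 1 missing per modality) at a
    desk-scale probe count."""
    cfg = SyntheticConfig(
        n_probes=400,
        n_taxa=120,
        n_signal_probes=20,
        n_signal_taxa=15,
        seed=7,
    )
    return cfg, generate_cohort(cfg)


def make_experiment_config(synthetic, **overrides):
    defaults = dict(
        synthetic=synthetic,
        test_size=30,
        seed=3,
        strategy="transcriptome_only",
        transcriptome_selection=SelectionConfig(ranker="chi2", n_features=20, seed=5),
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


@pytest.fixture
def toy_table():
    return OmicsTable(
        ["s1", "s2", "s3"],
        ["f1", "f2"],
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        "transcriptome",
    )


@pytest.fixture
def toy_labels():
    return LabelVector(["s1", "s2", "s3"], np.array([1, 0, 1]))
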