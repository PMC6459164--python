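import numpy as np
import pytest

from hdcn import simulate
from hdcn.localization import (
    features_from_expression,
    predict_profiles,
    train_localization_classifier,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Small contaminated two-group cohort with planted DEGs."""
    return simulate.simulate_expression_cohort(
        n_genes=200, n_mixed=20, n_reference=20, n_deg=40, seed=42
    )


@pytest.fixture(scope="session")
def repertoire_sim():
    return simulate.simulate_repertoire(
        n_samples_per_group=10,
        n_v=6,
        n_j=4,
        concentration_low=5.0,
        concentration_high=50.0,
        reads_per_sample=800,
        seed=7,
    )


@pytest.fixture(scope="session")
def localization_sim():
    return simulate.simulate_network_with_localization(
        n_proteins=100, n_relocated=5, n_samples=60, seed=5
    )


@pytest.fixture(scope="session")
def localization_profile(localization_sim):
    graph, annotations, m_mixed, m_ref, truth = localization_sim
    feats_mixed = features_from_expression(m_mixed, graph, annotations)
    feats_ref = features_from_expression(m_ref, graph, annotations)
    classifier, accuracy = train_localization_classifier(
        feats_ref, annotations, seed=5
    )
    profile = predict_profiles(classifier, feats_mixed, feats_ref)
    return classifier, accuracy, profile


@pytest.fixture
def rng():
    return np.random.default_rng(0)
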