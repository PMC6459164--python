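import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hdcn.containers import COMPARTMENTS, LocalizationAnnotation
from hdcn.localization import (
    build_features,
    detect_changes,
    feature_matrix,
    features_from_expression,
    predict_profiles,
    summarize_compartment_changes,
    train_localization_classifier,
)


def _toy_network():
    g = nx.Graph()
    g.add_edges_from([("p", "a"), ("p", "b"), ("p", "c"), ("q", "a")])
    ann = LocalizationAnnotation(
        {"a": "mitochondria", "b": "mitochondria", "c": "nucleus"}
    )
    return g, ann


class TestFeatures:
    def test_single_compartment_support(self):
        g = nx.Graph()
        g.add_edges_from([("p", "a"), ("p", "b")])
        ann = LocalizationAnnotation({"a": "mitochondria", "b": "mitochondria"})
        mics = {("a", "p"): 0.8, ("b", "p"): 0.4}
        feat = build_features("p", g, ann, mics)
        idx = COMPARTMENTS.index("mitochondria")
        assert feat[idx] == pytest.approx(1.0)
        assert feat.sum() == pytest.approx(1.0)

    def test_no_annotated_partners_gives_zero_vector(self):
        g = nx.Graph()
        g.add_edge("p", "x")
        ann = LocalizationAnnotation({})
        assert build_features("p", g, ann, {}).sum() == 0.0

    def test_weights_partition_across_compartments(self):
        g, ann = _toy_network()
        mics = {("a", "p"): 0.6, ("b", "p"): 0.2, ("c", "p"): 0.2}
        feat = build_features("p", g, ann, mics)
        assert feat[COMPARTMENTS.index("mitochondria")] == pytest.approx(0.8)
        assert feat[COMPARTMENTS.index("nucleus")] == pytest.approx(0.2)

    def test_scale_invariance_of_normalized_features(self):
        g, ann = _toy_network()
        mics = {("a", "p"): 0.6, ("b", "p"): 0.2, ("c", "p"): 0.2}
        scaled = {k: 3.7 * v for k, v in mics.items()}
        assert np.allclose(
            build_features("p", g, ann, mics),
            build_features("p", g, ann, scaled),
        )

    def test_unknown_protein_rejected(self):
        g, ann = _toy_network()
        with pytest.raises(ValueError):
            build_features("ghost", g, ann, {})

    def test_block_simulation_features_argmax_own_compartment(self):
        from hdcn.simulate import simulate_network_with_localization

        g, ann, mm, mr, _ = simulate_network_with_localization(
            n_proteins=60, n_relocated=0, coexpr_within=0.9,
            coexpr_between=0.0, n_samples=40, seed=6,
        )
        feats = features_from_expression(mr, g, ann)
        hits = sum(
            feats.columns[np.argmax(feats.loc[p])] == ann[p]
            for p in feats.index
        )
        assert hits / len(feats) >= 0.95


class TestClassifier:
    def test_separable_training_reaches_full_cv_accuracy(self, localization_profile):
        _, accuracy, _ = localization_profile
        assert accuracy >= 0.95

    def test_probability_vectors_sum_to_one(self, localization_profile):
        _, _, profile = localization_profile
        assert np.allclose(profile.probs_mixed.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(profile.probs_reference.sum(axis=1), 1.0, atol=1e-9)

    def test_shuffled_labels_give_chance_accuracy(self, localization_sim):
        graph, annotations, _, m_ref, _ = localization_sim
        feats = features_from_expression(m_ref, graph, annotations)
        rng = np.random.default_rng(0)
        proteins = list(feats.index)
        shuffled = LocalizationAnnotation(
            {
                p: annotations[q]
                for p, q in zip(proteins, rng.permutation(proteins))
            }
        )
        _, accuracy = train_localization_classifier(feats, shuffled, seed=0)
        assert accuracy < 0.35  # chance is ~0.1 over 10 compartments

    def test_small_compartments_need_two_classes(self):
        feats = pd.DataFrame(
            np.eye(10)[:4], index=list("abcd"), columns=COMPARTMENTS
        )
        ann = LocalizationAnnotation({p: COMPARTMENTS[0] for p in "abcd"})
        with pytest.raises(ValueError):
            train_localization_classifier(feats, ann)


class TestChangeDetection:
    def test_identical_features_give_zero_change(self, localization_profile):
        classifier, _, _ = localization_profile
        feats = pd.DataFrame(
            np.eye(10)[:3], index=list("xyz"), columns=COMPARTMENTS
        )
        profile = predict_profiles(classifier, feats, feats.copy())
        assert (profile.change_score == 0).all()

    def test_change_scores_bounded(self, localization_profile):
        _, _, profile = localization_profile
        assert ((profile.change_score >= 0) & (profile.change_score <= 1)).all()

    def test_relocated_proteins_score_higher(self, localization_sim,
                                             localization_profile):
        *_, truth = localization_sim
        _, _, profile = localization_profile
        rel = [p for p in truth.relocated if p in profile.change_score.index]
        other = [p for p in profile.change_score.index if p not in truth.relocated]
        assert profile.change_score[rel].mean() > 5 * profile.change_score[other].mean()

    def test_top_compartment_moves_for_most_relocated(self, localization_sim,
                                                      localization_profile):
        *_, truth = localization_sim
        _, _, profile = localization_profile
        rel = [p for p in truth.relocated if p in profile.top_mixed.index]
        flips = sum(profile.top_mixed[p] != profile.top_reference[p] for p in rel)
        assert flips >= len(rel) / 2

    def test_degenerate_quantile_gives_empty_set(self, localization_sim,
                                                 localization_profile):
        graph, annotations, m_mixed, m_ref, _ = localization_sim
        classifier, _, profile = localization_profile
        changed, threshold, _ = detect_changes(
            profile, classifier, graph, annotations, m_mixed, m_ref,
            threshold_quantile=1.0, n_null=20, n_null_proteins=4, seed=0,
        )
        assert changed == set()
        assert threshold == float("inf")

    def test_unstable_null_size_rejected(self, localization_sim,
                                         localization_profile):
        graph, annotations, m_mixed, m_ref, _ = localization_sim
        classifier, _, profile = localization_profile
        with pytest.raises(ValueError):
            detect_changes(
                profile, classifier, graph, annotations, m_mixed, m_ref,
                n_null=5, seed=0,
            )


class TestCompartmentSummary:
    def test_counts_follow_top_compartments(self, localization_profile):
        _, _, profile = localization_profile
        changed = set(profile.change_score.nlargest(5).index)
        summary = summarize_compartment_changes(changed, profile)
        assert summary["count"].max() <= 5
        assert (summary["percent"] <= 100.0).all()

    def test_single_change_is_hundred_percent(self, localization_profile):
        _, _, profile = localization_profile
        p = profile.change_score.index[0]
        summary = summarize_compartment_changes({p}, profile)
        assert (summary["percent"] == 100.0).all() or len(summary) == 2

    def test_empty_changed_set_gives_empty_summary(self, localization_profile):
        _, _, profile = localization_profile
        assert summarize_compartment_changes(set(), profile).empty
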