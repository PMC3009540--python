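"""Positional naive Bayes window model: smoothing, posteriors, CV scoring."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchormotif.alphabet import encode
from anchormotif.bayes import (
    WindowSample,
    cross_validated_score,
    fit_window_model,
    train_window_model,
    window_posterior,
)


def toy_model(alpha=1.0):
    samples = [WindowSample("AA", f"m{i}", "motif") for i in range(3)] + [
        WindowSample("CC", f"b{i}", "background") for i in range(3)
    ]
    return train_window_model(samples, alpha=alpha)


def product_posterior_oracle(motif, background, query, alpha=1.0):
    """Explicit probability products, no logarithms.

    Laplace-smoothed per-position categorical likelihoods times class
    priors, normalised over the two classes; 'X' contributes 1/20.
    """
    n_m, n_b = len(motif), len(background)
    joint = {}
    for cls, samples, prior in (("m", motif, n_m), ("b", background, n_b)):
        p = prior / (n_m + n_b)
        for j, q in enumerate(query):
            if q == "X":
                p *= 1 / 20
                continue
            count = sum(1 for s in samples if s[j] == q)
            observed = sum(1 for s in samples if s[j] != "X")  # X never counted
            p *= (count + alpha) / (observed + 20 * alpha)
        joint[cls] = p
    return joint["m"] / (joint["m"] + joint["b"])


class TestTraining:
    def test_laplace_smoothing_rule(self):
        model = toy_model(alpha=1.0)
        # three 'A' observations at position 0 of the motif class
        assert np.exp(model.log_likelihood[1, 0, encode("A")[0]]) == pytest.approx(4 / 23)

    def test_large_alpha_washes_out_to_prior(self):
        model = toy_model(alpha=1e9)
        assert window_posterior(model, "AA") == pytest.approx(0.5, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_window_model([WindowSample("AA", "m", "motif")])

    def test_per_position_probabilities_sum_to_one(self):
        model = toy_model()
        probs = np.exp(model.log_likelihood[:, :, :20])
        assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-9)


class TestPosterior:
    def test_separable_training_sample_scores_high(self):
        # hand computation: P(AA|motif) = (4/23)^2, P(AA|bg) = (1/23)^2,
        # equal priors -> posterior = 16/17
        model = toy_model()
        assert window_posterior(model, "AA") == pytest.approx(16 / 17)

    def test_identical_classes_give_half(self):
        samples = [WindowSample("AC", "m", "motif"), WindowSample("AC", "b", "background")]
        model = train_window_model(samples)
        assert window_posterior(model, "CA") == pytest.approx(0.5)

    def test_all_x_window_returns_class_prior(self):
        motif = np.array([encode("AA")] * 3)
        background = np.array([encode("CC")] * 1)
        model = fit_window_model(motif, background)
        assert window_posterior(model, "XX") == pytest.approx(3 / 4)

    def test_posterior_and_complement_sum_to_one(self):
        model = toy_model()
        for query in ("AA", "AC", "CC", "WW"):
            p1 = window_posterior(model, query)
            swapped = fit_window_model(
                np.array([encode("CC")] * 3), np.array([encode("AA")] * 3), 1.0
            )
            assert p1 + window_posterior(swapped, query) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        motif=st.lists(st.text(alphabet="ACDX", min_size=3, max_size=3), min_size=1, max_size=5),
        background=st.lists(st.text(alphabet="ACDX", min_size=3, max_size=3), min_size=1, max_size=5),
        query=st.text(alphabet="ACDWX", min_size=3, max_size=3),
    )
    def test_agrees_with_product_oracle(self, motif, background, query):
        model = fit_window_model(
            np.array([encode(s) for s in motif]),
            np.array([encode(s) for s in background]),
        )
        expected = product_posterior_oracle(motif, background, query)
        assert window_posterior(model, query) == pytest.approx(expected, abs=1e-9)

    def test_agrees_with_sklearn_categorical_nb(self):
        # independent cross-check of the likelihood/prior arithmetic on
        # X-free windows
        from sklearn.naive_bayes import CategoricalNB

        rng = np.random.default_rng(3)
        pos = rng.integers(0, 20, size=(12, 4))
        neg = rng.integers(0, 20, size=(9, 4))
        model = fit_window_model(pos, neg, alpha=1.0)
        clf = CategoricalNB(alpha=1.0, min_categories=20)
        X = np.vstack([pos, neg])
        y = np.array([1] * 12 + [0] * 9)
        clf.fit(X, y)
        ours = model.posteriors(X)
        theirs = clf.predict_proba(X)[:, 1]
        assert np.allclose(ours, theirs, atol=1e-9)


class TestCrossValidation:
    def test_perfectly_separable_classes_score_one(self):
        pos = np.array([encode("AAA")] * 10)
        neg = np.array([encode("CCC")] * 10)
        score = cross_validated_score(pos, neg, folds=5, seed=0)
        assert score.min_pr == pytest.approx(1.0)
        assert score.min_pr == min(score.precision, score.recall)

    def test_iid_classes_score_near_half(self):
        mins = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pos = rng.integers(0, 20, size=(200, 6))
            neg = rng.integers(0, 20, size=(200, 6))
            mins.append(cross_validated_score(pos, neg, folds=5, seed=seed).min_pr)
        assert np.mean(mins) == pytest.approx(0.5, abs=0.07)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 20, size=(30, 4))
        neg = rng.integers(0, 20, size=(30, 4))
        a = cross_validated_score(pos, neg, folds=3, seed=42)
        b = cross_validated_score(pos, neg, folds=3, seed=42)
        assert a == b

    def test_class_smaller_than_folds_rejected(self):
        pos = np.zeros((3, 2), dtype=int)
        neg = np.zeros((10, 2), dtype=int)
        with pytest.raises(ValueError):
            cross_validated_score(pos, neg, folds=5)
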