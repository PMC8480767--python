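"""Change modulation, decoding, weight-CMI correlation, Jaccard agreement."""

import numpy as np
import pandas as pd
import pytest

from stpnet.neural_metrics import (
    CMITable,
    DecodingResult,
    PresentationResponses,
    change_modulation_index,
    decode,
    jaccard_agreement,
    subsample_accuracy_curve,
    weight_cmi_correlation,
)
from stpnet.synthetic_data import generate_session, generate_synthetic_population


def _labels(n, image_ids=None, change=None, pre=None, sham=None, omitted=None):
    return pd.DataFrame(
        {
            "step": np.arange(n) * 3,
            "image_id": image_ids if image_ids is not None else np.zeros(n, int),
            "is_omitted": omitted if omitted is not None else np.zeros(n, bool),
            "is_change": change if change is not None else np.zeros(n, bool),
            "is_sham_change": sham if sham is not None else np.zeros(n, bool),
            "is_pre_change": pre if pre is not None else np.zeros(n, bool),
            "repeat_index": np.ones(n, int),
            "trial_id": np.arange(n),
        }
    )


def _responses(values, **label_kw):
    values = np.atleast_2d(np.asarray(values, float))
    return PresentationResponses(values, _labels(values.shape[1], **label_kw))


class TestChangeModulationIndex:
    def _simple(self, change_val, pre_val):
        change = np.array([True, False, True, False])
        pre = np.array([False, True, False, True])
        vals = np.where(change, change_val, pre_val)[None, :]
        return _responses(vals, change=change, pre=pre)

    def test_equal_means_give_zero(self):
        cmi = change_modulation_index(self._simple(0.4, 0.4))
        assert cmi.values[0] == pytest.approx(0.0)

    def test_zero_prechange_gives_full_adaptation(self):
        cmi = change_modulation_index(self._simple(0.8, 0.0))
        assert cmi.values[0] == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        cmi = change_modulation_index(self._simple(0.3, 0.1))
        assert cmi.values[0] == pytest.approx(0.5)

    def test_negative_mean_excluded_with_reason(self):
        cmi = change_modulation_index(self._simple(-0.2, 0.1))
        row = cmi.table.iloc[0]
        assert row["excluded"] and row["reason"] == "negative_mean"
        assert len(cmi.values) == 0

    def test_zero_denominator_excluded(self):
        cmi = change_modulation_index(self._simple(0.0, 0.0))
        assert cmi.table.iloc[0]["reason"] == "zero_denominator"

    def test_requires_labeled_presentations(self):
        with pytest.raises(ValueError):
            change_modulation_index(_responses(np.ones((1, 4))))

    def test_recovery_on_synthetic_population(self):
        """Estimator bias < 0.05 on a 200-neuron adapting population at noise 0.2."""
        seq = generate_session(n_trials=400, seed=21)
        pop = generate_synthetic_population(
            n_neurons=200, noise_sd=0.2, sequence=seq, seed=22
        )
        resp = PresentationResponses.from_synthetic_population(pop)
        cmi = change_modulation_index(resp)
        retained = ~cmi.table["excluded"].to_numpy()
        est = cmi.table["cmi"].to_numpy()[retained]
        gt = pop.ground_truth_cmi[retained]
        mae = np.abs(est - gt).mean()
        assert mae < 0.05
        # sign agreement: adapting neurons are detected as adapting
        assert (np.sign(est[gt > 0.05]) > 0).mean() > 0.95


class TestDecode:
    def test_perfect_separation(self, rng):
        n = 60
        change = np.arange(n) % 2 == 0
        pre = ~change
        vals = np.vstack([np.where(change, 5.0, 0.0) + rng.normal(0, 0.1, n),
                          np.where(change, 0.0, 5.0) + rng.normal(0, 0.1, n)])
        resp = _responses(vals, change=change, pre=pre)
        assert decode(resp, "change", seed=0).mean_accuracy == 1.0

    def test_shuffled_labels_at_chance(self, rng):
        n = 300
        change = np.arange(n) % 2 == 0
        vals = rng.normal(size=(10, n))  # responses carry no label information
        resp = _responses(vals, change=change, pre=~change)
        acc = decode(resp, "change", seed=1).mean_accuracy
        assert abs(acc - 0.5) < 0.12

    def test_identity_chance_level(self, rng):
        n = 400
        ids = rng.integers(0, 8, n)
        vals = rng.normal(size=(10, n))
        resp = _responses(vals, image_ids=ids)
        acc = decode(resp, "identity", seed=2).mean_accuracy
        assert abs(acc - 0.125) < 0.08

    def test_deterministic_given_seed(self, rng):
        n = 100
        change = np.arange(n) % 2 == 0
        vals = rng.normal(size=(5, n)) + np.where(change, 1.0, 0.0)
        resp = _responses(vals, change=change, pre=~change)
        a = decode(resp, "change", seed=3)
        b = decode(resp, "change", seed=3)
        assert np.array_equal(a.fold_accuracies, b.fold_accuracies)
        assert np.array_equal(a.weights, b.weights)

    def test_insufficient_class_counts_rejected(self):
        vals = np.ones((2, 4))
        change = np.array([True, False, False, False])
        resp = _responses(vals, change=change, pre=~change)
        with pytest.raises(ValueError):
            decode(resp, "change", n_folds=3)


class TestSubsampleCurve:
    def test_full_population_equals_direct_decode(self, rng):
        n = 120
        change = np.arange(n) % 2 == 0
        vals = rng.normal(size=(8, n)) + np.where(change, 1.0, 0.0)
        resp = _responses(vals, change=change, pre=~change)
        curve = subsample_accuracy_curve(resp, "change", unit_counts=[8], seed=4)
        direct = decode(resp, "change", seed=4).mean_accuracy
        assert curve["mean_accuracy"].iloc[0] == pytest.approx(direct)

    def test_informative_subset_beats_chance(self, rng):
        n = 200
        change = np.arange(n) % 2 == 0
        vals = rng.normal(size=(6, n)) * 0.1
        vals[0] += np.where(change, 3.0, 0.0)  # one highly informative unit
        resp = _responses(vals, change=change, pre=~change)
        curve = subsample_accuracy_curve(resp, "change", unit_counts=[6], seed=5)
        assert curve["mean_accuracy"].iloc[0] > 0.9


class TestWeightCmiCorrelation:
    def _result(self, weights):
        return DecodingResult(task="change", fold_accuracies=np.ones(3),
                              mean_accuracy=1.0, weights=np.asarray(weights, float))

    def _cmi(self, values):
        values = np.asarray(values, float)
        return CMITable(pd.DataFrame({
            "unit": np.arange(len(values)), "cmi": values,
            "excluded": np.zeros(len(values), bool), "reason": "",
        }))

    def test_proportional_weights_give_one(self):
        c = np.array([0.1, 0.3, -0.2, 0.5])
        assert weight_cmi_correlation(self._result(2.5 * c), self._cmi(c)) == pytest.approx(1.0)

    def test_antiproportional_weights_give_minus_one(self):
        c = np.array([0.1, 0.3, -0.2, 0.5])
        assert weight_cmi_correlation(self._result(-c), self._cmi(c)) == pytest.approx(-1.0)

    def test_adapting_units_carry_change_information(self):
        """When only adapting units are informative, decoder weights track CMI."""
        rng = np.random.default_rng(6)
        n = 600
        change = np.arange(n) % 2 == 0
        pre = ~change
        n_adapt, n_flat = 10, 10
        vals = np.zeros((n_adapt + n_flat, n))
        for u in range(n_adapt):
            base = rng.uniform(1, 2)
            vals[u] = np.where(change, base, base * 0.4) * (1 + rng.normal(0, 0.2, n))
        for u in range(n_adapt, n_adapt + n_flat):
            vals[u] = rng.uniform(1, 2) * (1 + rng.normal(0, 0.2, n))
        resp = _responses(np.maximum(vals, 0), change=change, pre=pre)
        result = decode(resp, "change", seed=7)
        cmi = change_modulation_index(resp)
        assert weight_cmi_correlation(result, cmi) > 0.8


class TestJaccard:
    def test_identical_vectors(self, rng):
        v = rng.random(200) < 0.3
        score, null_mean, _ = jaccard_agreement(v, v, n_shuffles=50, seed=0)
        assert score == 1.0
        assert null_mean < 1.0

    def test_disjoint_positives(self):
        a = np.array([1, 1, 0, 0], bool)
        b = np.array([0, 0, 1, 1], bool)
        score, _, _ = jaccard_agreement(a, b, n_shuffles=10, seed=0)
        assert score == 0.0

    def test_independent_bernoulli_matches_closed_form(self, rng):
        """For independent Bernoulli(p) vectors E[J] ~ p/(2-p)."""
        p = 0.3
        a = rng.random(1000) < p
        b = rng.random(1000) < p
        score, null_mean, (lo, hi) = jaccard_agreement(a, b, n_shuffles=300, seed=1)
        expected = p / (2 - p)
        assert abs(score - expected) < 0.05
        # the shuffle null preserves the marginals, so it matches the closed form too
        assert lo <= expected + 0.02 and hi >= expected - 0.02
        assert abs(null_mean - expected) < 0.03

    def test_all_zero_vectors_undefined(self):
        z = np.zeros(10, bool)
        with pytest.raises(ValueError):
            jaccard_agreement(z, z, n_shuffles=5)
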