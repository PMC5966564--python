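"""Feature flattening, C selection, SVM training, online prediction and metrics."""

import warnings

import numpy as np
import pytest

from nirsbci.classifier import (
    C_GRID,
    PredictionRecord,
    compute_metrics,
    make_cv_folds,
    predict,
    run_online_session,
    select_C,
    train,
    unvectorize,
    vectorize,
)
from nirsbci.hemodynamics import DeviceProfile, HemoStream
from nirsbci.protocol import TrialTensor


def tensors_from_clusters(rng, n_per_class=5, n_optodes=4, n_samples=20, sep=5.0, noise=0.5):
    """Labeled trial tensors drawn from two Gaussian clusters."""
    shape = (n_optodes, 2, n_samples)
    center = rng.normal(size=shape)
    out = []
    idx = 1
    for load, sign in (("low", -1.0), ("high", 1.0)):
        for _ in range(n_per_class):
            values = sign * sep * center + rng.normal(0, noise, size=shape)
            out.append(TrialTensor(values=values, load=load, index=idx, onset=0.0))
            idx += 1
    return out


class TestVectorize:
    @pytest.mark.parametrize(
        "profile,length",
        [(DeviceProfile.sim16(), 1920), (DeviceProfile.flight4(), 960)],
    )
    def test_feature_counts_for_device_profiles(self, profile, length):
        n_samples = round(30 * profile.sampling_rate)
        tensor = TrialTensor(
            values=np.zeros((profile.n_optodes, 2, n_samples)),
            load="low", index=1, onset=10.0,
        )
        assert vectorize(tensor, profile).shape == (length,)

    def test_round_trip(self, rng):
        values = rng.normal(size=(4, 2, 30))
        tensor = TrialTensor(values=values, load="low", index=1, onset=0.0)
        assert np.array_equal(unvectorize(vectorize(tensor), 4, 30), values)

    def test_flattening_order_is_optode_chromophore_time(self):
        values = np.arange(2 * 2 * 3).reshape(2, 2, 3).astype(float)
        tensor = TrialTensor(values=values, load="low", index=1, onset=0.0)
        assert np.array_equal(vectorize(tensor), np.arange(12.0))

    def test_dimension_mismatch_rejected(self, sim16):
        tensor = TrialTensor(values=np.zeros((4, 2, 60)), load="low", index=1, onset=0.0)
        with pytest.raises(ValueError):
            vectorize(tensor, sim16)


class TestCvFolds:
    def test_stratified_one_per_class_per_fold(self):
        labels = ["low", "high"] * 5
        folds = make_cv_folds(labels, seed=0)
        assert len(folds) == 5
        used = np.concatenate(folds)
        assert sorted(used) == list(range(10))
        for fold in folds:
            assert {labels[i] for i in fold} == {"low", "high"}

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            make_cv_folds(["low"] * 10)


class TestSelectC:
    def test_grid_has_eight_decades(self):
        assert len(C_GRID) == 8
        assert C_GRID[0] == 1e-3 and C_GRID[-1] == 1e4
        assert np.allclose(np.diff(np.log10(C_GRID)), 1.0)

    def test_wide_margin_ties_resolve_to_smallest_C(self, rng):
        tensors = tensors_from_clusters(rng, sep=50.0, noise=0.01)
        X = np.stack([vectorize(t) for t in tensors])
        best, cv = select_C(X, [t.load for t in tensors], seed=0)
        assert all(acc == 1.0 for acc in cv.values())
        assert best == 1e-3

    def test_permutation_null_centers_on_chance(self):
        # labels carry no information: CV accuracy of the best C hovers at 50 %
        rng = np.random.default_rng(2024)
        best_accs = []
        for _ in range(200):
            X = rng.normal(size=(10, 24))
            labels = list(rng.permutation(["low"] * 5 + ["high"] * 5))
            _, cv = select_C(X, labels, seed=rng)
            best_accs.append(max(cv.values()))
        mean_best = np.mean(best_accs)
        # maximum over the 8-point grid biases upward; stays well below
        # separable performance and above the floor
        assert 0.45 < mean_best < 0.85


class TestTrain:
    def test_separable_clusters_reach_perfect_training_accuracy(self, rng):
        model = train(tensors_from_clusters(rng), seed=0)
        assert model.training_accuracy == 100.0
        assert model.selected_C in C_GRID
        assert model.n_train == 10

    def test_contradictory_labels_cap_training_accuracy(self, rng):
        base = rng.normal(size=(2, 2, 10))
        tensors = []
        for i in range(5):
            tensors.append(TrialTensor(values=base, load="low", index=2 * i + 1, onset=0.0))
            tensors.append(TrialTensor(values=base, load="high", index=2 * i + 2, onset=0.0))
        model = train(tensors, seed=0)
        assert model.training_accuracy <= 50.0

    def test_too_few_trials_per_class_rejected(self, rng):
        tensors = tensors_from_clusters(rng, n_per_class=5)
        with pytest.raises(ValueError, match="at least 2"):
            train([t for t in tensors if t.load == "low"] + tensors[-1:], seed=0)

    def test_rotation_invariance_of_predictions(self, rng):
        tensors = tensors_from_clusters(rng, n_optodes=2, n_samples=10)
        X = np.stack([vectorize(t) for t in tensors])
        d = X.shape[1]
        q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        rotated = [
            TrialTensor(values=(x @ q.T).reshape(2, 2, 10), load=t.load, index=t.index, onset=0.0)
            for x, t in zip(X, tensors)
        ]
        model = train(tensors, seed=0)
        model_rot = train(rotated, seed=0)
        test_points = rng.normal(size=(20, d))
        for x in test_points:
            p1 = predict(model, x).predicted_load
            p2 = predict(model_rot, q @ x).predicted_load
            assert p1 == p2


class TestPredict:
    def test_high_centroid_classified_high(self, rng):
        tensors = tensors_from_clusters(rng)
        model = train(tensors, seed=0)
        X = np.stack([vectorize(t) for t in tensors])
        centroid = X[5:].mean(axis=0)  # high-load cluster mean
        assert predict(model, centroid).predicted_load == "high"

    def test_zero_decision_value_resolves_to_low(self, rng):
        model = train(tensors_from_clusters(rng), seed=0)
        # force an exactly-zero margin by zeroing the model
        model.weights = np.zeros_like(model.weights)
        model.bias = 0.0
        rec = predict(model, np.ones(model.n_features))
        assert rec.decision_margin == 0.0
        assert rec.predicted_load == "low"

    def test_margin_matches_dot_product_oracle(self, rng):
        model = train(tensors_from_clusters(rng), seed=0)
        for x in rng.normal(size=(100, model.n_features)):
            rec = predict(model, x)
            assert rec.decision_margin == pytest.approx(model.weights @ x + model.bias)
            assert rec.predicted_load == ("high" if model.weights @ x + model.bias > 0 else "low")

    def test_length_mismatch_rejected(self, rng):
        model = train(tensors_from_clusters(rng), seed=0)
        with pytest.raises(ValueError, match="length"):
            predict(model, np.ones(model.n_features + 1))


class TestComputeMetrics:
    @staticmethod
    def records_from_counts(tp, fp, fn, tn):
        recs = []
        k = 1
        for _ in range(tp):
            recs.append(PredictionRecord(k, "high", "high", 1.0)); k += 1
        for _ in range(fp):
            recs.append(PredictionRecord(k, "high", "low", 1.0)); k += 1
        for _ in range(fn):
            recs.append(PredictionRecord(k, "low", "high", -1.0)); k += 1
        for _ in range(tn):
            recs.append(PredictionRecord(k, "low", "low", -1.0)); k += 1
        return recs

    def test_published_subject_confusion_matrix(self):
        # TP=2, FP=1, FN=3, TN=4: the implied confusion matrix of a 60 %
        # accuracy / 66.67 precision / 40 recall / 50 f1 session
        m = compute_metrics(self.records_from_counts(2, 1, 3, 4))
        assert m.accuracy == pytest.approx(60.0)
        assert m.precision == pytest.approx(66.67, abs=0.005)
        assert m.recall == pytest.approx(40.0)
        assert m.f1 == pytest.approx(50.0, abs=0.005)

    def test_all_high_predictor(self):
        m = compute_metrics(self.records_from_counts(5, 5, 0, 0))
        assert (m.accuracy, m.precision, m.recall) == (50.0, 50.0, 100.0)

    def test_all_correct(self):
        m = compute_metrics(self.records_from_counts(5, 0, 0, 5))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (100.0,) * 4

    def test_no_predicted_positives_warns_nan_precision(self):
        with pytest.warns(UserWarning, match="precision"):
            m = compute_metrics(self.records_from_counts(0, 0, 5, 5))
        assert np.isnan(m.precision) and np.isnan(m.f1)
        assert m.accuracy == 50.0

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([])


def separable_session_stream(protocol, profile, rng, effect=3.0, noise=0.1):
    """Concentration stream whose trial windows carry a load-dependent offset."""
    n = round(protocol.duration * profile.sampling_rate)
    t = np.arange(n) / profile.sampling_rate
    hbo = rng.normal(0, noise, size=(n, profile.n_optodes))
    hhb = rng.normal(0, noise, size=(n, profile.n_optodes))
    for trial in protocol.trials:
        mask = (t >= trial.onset) & (t < trial.end)
        if trial.load == "high":
            hbo[mask] += effect
    return HemoStream(time=t, hbo=hbo, hhb=hhb)


class TestOnlineSession:
    def test_online_prediction_is_causal_bit_for_bit(self, sim16, protocol20, rng):
        stream = separable_session_stream(protocol20, sim16, rng)
        _, full_records, _ = run_online_session(stream, protocol20, sim16, seed=1)
        # truncate right after trial 15's window closes
        cut = protocol20.trials[14].end
        mask = stream.time < cut
        truncated = HemoStream(time=stream.time[mask], hbo=stream.hbo[mask], hhb=stream.hhb[mask])
        _, trunc_records, _ = run_online_session(truncated, protocol20, sim16, seed=1)
        assert len(trunc_records) == 5
        for a, b in zip(full_records[:5], trunc_records):
            assert a.trial_index == b.trial_index
            assert a.predicted_load == b.predicted_load
            assert a.decision_margin == b.decision_margin

    def test_separable_session_is_classified_perfectly(self, sim16, protocol20, rng):
        stream = separable_session_stream(protocol20, sim16, rng)
        model, records, metrics = run_online_session(stream, protocol20, sim16, seed=1)
        assert len(records) == 10
        assert all(r.trial_index > 10 for r in records)
        assert metrics.accuracy == 100.0

    def test_truncated_phase_c_trials_are_skipped_with_warning(self, sim16, protocol20, rng):
        stream = separable_session_stream(protocol20, sim16, rng)
        cut = protocol20.trials[17].end  # drop trials 19-20
        mask = stream.time < cut
        truncated = HemoStream(time=stream.time[mask], hbo=stream.hbo[mask], hhb=stream.hhb[mask])
        with pytest.warns(UserWarning, match="skipping trial"):
            _, records, metrics = run_online_session(truncated, protocol20, sim16, seed=1)
        assert len(records) == 8
        assert metrics.n == 8

    def test_incomplete_phase_a_is_fatal(self, sim16, protocol20, rng):
        stream = separable_session_stream(protocol20, sim16, rng)
        mask = stream.time < protocol20.trials[4].end
        truncated = HemoStream(time=stream.time[mask], hbo=stream.hbo[mask], hhb=stream.hhb[mask])
        with pytest.raises(ValueError, match="phase A"):
            run_online_session(truncated, protocol20, sim16, seed=1)
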