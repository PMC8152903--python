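"""Fold partitioning, the ECOC/SVM engine, and the decoding modes."""

import dataclasses

import numpy as np
import pytest

from erpdecode import _svm, core, decode, preprocess, synth
from erpdecode.core import DataError, DecodeConfig
from erpdecode.decode import (average_by_group, confusion_by_period,
                              decode_crossdim, decode_crosstime,
                              decode_timecourse, fit_predict_ecoc,
                              group_class_means, partition_balanced)

from conftest import balanced_labels, white_noise_epochs


class TestPartition:
    def test_160_per_class_three_folds(self):
        labels = np.repeat(np.arange(1, 5), 160)
        fa = partition_balanced(labels, 3, rng=0)
        for c in range(1, 5):
            assert fa.groups[c].shape == (3, 53)
            assert fa.dropped[c].shape == (1,)

    def test_divisible_no_drop(self):
        labels = np.repeat(np.arange(1, 5), 12)
        fa = partition_balanced(labels, 3, rng=1)
        for c in range(1, 5):
            assert fa.groups[c].shape == (3, 4)
            assert fa.dropped[c].size == 0

    def test_deterministic_given_seed(self):
        labels = np.repeat(np.arange(1, 5), 30)
        a = partition_balanced(labels, 3, rng=7)
        b = partition_balanced(labels, 3, rng=7)
        for c in range(1, 5):
            assert np.array_equal(a.groups[c], b.groups[c])

    def test_groups_disjoint_and_cover(self):
        labels = np.repeat(np.arange(1, 5), 17)
        fa = partition_balanced(labels, 3, rng=2)
        for c in range(1, 5):
            got = np.sort(np.concatenate([fa.groups[c].ravel(), fa.dropped[c]]))
            assert np.array_equal(got, np.flatnonzero(labels == c))

    def test_class_smaller_than_k_rejected(self):
        labels = np.array([1, 1, 1, 2, 2, 3, 3, 3, 4, 4, 4])
        with pytest.raises(DataError, match="2"):
            partition_balanced(labels, 3, rng=0)


class TestAveraging:
    def test_default_shape_3x4x59(self):
        ep = white_noise_epochs(n_trials=480, n_channels=59, n_times=5, seed=1)
        labels = np.repeat(np.arange(1, 5), 120)
        fa = partition_balanced(labels, 3, rng=0)
        mat = average_by_group(ep, fa, t=2)
        assert mat.shape == (3, 4, 59)

    def test_singleton_groups_identity(self):
        ep = white_noise_epochs(n_trials=12, n_channels=4, n_times=3, seed=2)
        labels = np.repeat(np.arange(1, 5), 3)
        fa = partition_balanced(labels, 3, rng=0)
        mat = average_by_group(ep, fa, t=1)
        for g in range(3):
            for ci, c in enumerate(range(1, 5)):
                trial = fa.groups[c][g][0]
                assert np.allclose(mat[g, ci], ep.data[trial, :, 1].astype(float))

    def test_duplicate_trials_mean_is_either(self):
        ep = white_noise_epochs(n_trials=8, n_channels=3, n_times=2, seed=3)
        ep.data[1] = ep.data[0]
        labels = np.array([1, 1, 2, 2, 3, 3, 4, 4])
        fa = decode.FoldAssignment(
            groups={1: np.array([[0, 1]]), 2: np.array([[2, 3]]),
                    3: np.array([[4, 5]]), 4: np.array([[6, 7]])},
            dropped={c: np.array([], dtype=int) for c in range(1, 5)}, n_folds=1)
        means = group_class_means(ep.data.astype(float), fa)
        assert np.allclose(means[0, 0], ep.data[0].astype(float))

    def test_exchangeable_under_trial_permutation(self):
        """Permuting trial storage order while carrying the assignment's
        trial indices along changes nothing."""
        ep = white_noise_epochs(n_trials=24, n_channels=5, n_times=4, seed=4)
        labels = np.repeat(np.arange(1, 5), 6)
        fa = partition_balanced(labels, 3, rng=0)
        perm = np.random.default_rng(0).permutation(24)
        inv = np.argsort(perm)
        data_p = ep.data[perm]
        fa_p = decode.FoldAssignment(
            groups={c: inv[g] for c, g in fa.groups.items()},
            dropped={c: inv[d] for c, d in fa.dropped.items()}, n_folds=3)
        a = group_class_means(ep.data.astype(float), fa)
        b = group_class_means(data_p.astype(float), fa_p)
        assert np.array_equal(a, b)


class TestEcoc:
    def test_separable_recall(self):
        rng = np.random.default_rng(0)
        cent = rng.standard_normal((4, 10)) * 4
        Xtr = np.repeat(cent, 2, axis=0) + rng.standard_normal((8, 10)) * 0.1
        ytr = np.repeat(np.arange(1, 5), 2)
        pred = fit_predict_ecoc(Xtr, ytr, Xtr)
        assert np.array_equal(pred, ytr)

    def test_symmetric_tie_returns_lowest_code(self):
        Xtr = np.eye(4)
        pred = fit_predict_ecoc(Xtr, [1, 2, 3, 4], np.zeros((1, 4)),
                                standardize=False)
        assert pred[0] == 1

    def test_monte_carlo_chance(self):
        """Random Gaussian train/test: accuracy converges to 1/4 (batched
        Monte Carlo, >= 1000 repetitions, 3 binomial SEs)."""
        rng = np.random.default_rng(123)
        B = 1500
        Xtr = rng.standard_normal((B, 8, 24))
        Xte = rng.standard_normal((B, 4, 24))
        ytr = np.tile(np.arange(1, 5), 2)
        Ztr, Zte = _svm.standardize_fold(Xtr, Xte)
        Y = np.where(ytr[None, :] == np.arange(1, 5)[:, None], 1.0, -1.0)
        W = _svm.train_ovr_batch(Ztr, Y)
        pred = _svm.ecoc_predict_from_decision(_svm.ecoc_decision(W, Zte))
        acc = (pred == np.arange(1, 5)[None, :]).mean()
        se = np.sqrt(0.25 * 0.75 / (B * 4))
        assert abs(acc - 0.25) <= 3 * se

    def test_agrees_with_independent_svm_implementation(self):
        """Cross-check against sklearn's libsvm binary SVMs combined with
        the same hinge-loss ECOC decoding rule."""
        sklearn_svm = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(1)
        agree, total = 0, 0
        for rep in range(25):
            cent = rng.standard_normal((4, 16)) * 2
            Xtr = np.repeat(cent, 2, axis=0) + rng.standard_normal((8, 16)) * 0.3
            ytr = np.repeat(np.arange(1, 5), 2)
            Xte = cent + rng.standard_normal((4, 16)) * 0.3
            pred = fit_predict_ecoc(Xtr, ytr, Xte, standardize=False)
            D = []
            for c in range(1, 5):
                clf = sklearn_svm.SVC(kernel="linear", C=1.0).fit(
                    Xtr, (ytr == c).astype(int))
                d = clf.decision_function(Xte)
                D.append(d)
            D = np.asarray(D)[:, None, :]
            pred_ref = _svm.ecoc_predict_from_decision(D)[0]
            agree += int((pred == pred_ref).sum())
            total += 4
        assert agree / total >= 0.97

    def test_brute_force_minimal_binary_loss_oracle(self):
        """ECOC decoding equals an explicit loop over classes and learners
        computing sum_l max(0, 1 - M[c,l] d_l)."""
        rng = np.random.default_rng(2)
        D = rng.standard_normal((4, 7, 5))
        pred = _svm.ecoc_predict_from_decision(D)
        M = 2 * np.eye(4) - 1
        for b in range(7):
            for m in range(5):
                losses = [sum(max(0.0, 1.0 - M[c, l] * D[l, b, m])
                              for l in range(4)) for c in range(4)]
                assert pred[b, m] == int(np.argmin(losses)) + 1

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            fit_predict_ecoc(np.zeros((4, 3)), [2, 2, 2, 2], np.zeros((1, 3)))


@pytest.fixture(scope="module")
def noise_run():
    ep = white_noise_epochs(n_trials=96, n_channels=10, n_times=25, seed=9)
    labels = core.collapse_dimension(ep.labels, "identity")
    cfg = DecodeConfig()
    series, store = decode_timecourse(ep, labels, cfg, seed=11)
    return ep, cfg, series, store


class TestTimecourse:

    def test_120_attempts_with_defaults(self, noise_run):
        _, cfg, series, store = noise_run
        assert store.n_attempts == 120 == cfg.n_attempts
        assert series.n_attempts == 120

    def test_series_is_smoothed_store_accuracy(self, noise_run):
        _, cfg, series, store = noise_run
        raw = store.accuracy()
        assert np.allclose(series.values,
                           preprocess.smooth_values(raw, cfg.smooth_points))

    def test_counts_consistent_with_accuracy(self, noise_run):
        *_, store = noise_run
        counts = store.counts()
        acc = counts[np.arange(4), np.arange(4), :].sum(axis=0) / store.n_attempts
        assert np.allclose(acc, store.accuracy())

    def test_deterministic_given_seed(self, noise_run):
        ep, cfg, series, store = noise_run
        labels = core.collapse_dimension(ep.labels, "identity")
        series2, store2 = decode_timecourse(ep, labels, cfg, seed=11)
        assert np.array_equal(store.predicted, store2.predicted)

    def test_label_shuffle_is_at_chance(self):
        ep = white_noise_epochs(n_trials=160, n_channels=12, n_times=50, seed=13)
        rng = np.random.default_rng(5)
        labels = rng.permutation(np.repeat(np.arange(1, 5), 40))
        _, store = decode_timecourse(ep, labels, DecodeConfig(), seed=17)
        grand = store.accuracy().mean()
        se = np.sqrt(0.25 * 0.75 / (120 * 50))
        assert abs(grand - 0.25) <= 3 * se

    def test_missing_class_rejected(self, tiny_epochs):
        labels = np.where(tiny_epochs.labels.identity == 4, 1,
                          tiny_epochs.labels.identity)
        with pytest.raises(DataError):
            decode_timecourse(tiny_epochs, labels, DecodeConfig(), seed=0)


@pytest.fixture(scope="module")
def windowed():
    cfg = dataclasses.replace(
        synth.SynthConfig(), n_trials=160, n_channels=16, rng_seed=21,
        noise=synth.NoiseParams(sd_uv=2.0, ar_phi=0.3, alpha_amp_uv=0.0))
    topo = synth.make_topographies(cfg, seed=21)
    ep = synth.simulate_participant(cfg, topo, seed=22)
    return preprocess.window_average(ep, 100.0), cfg


class TestCrosstime:

    def test_20_by_20_matrix(self, windowed):
        ep, _ = windowed
        labels = core.collapse_dimension(ep.labels, "identity")
        gm = decode_crosstime(ep, labels, DecodeConfig(n_iterations=2), seed=3)
        assert gm.accuracy.shape == (20, 20)
        assert (gm.accuracy >= 0).all() and (gm.accuracy <= 1).all()

    def test_diagonal_equals_windowed_timecourse(self, windowed):
        ep, _ = windowed
        labels = core.collapse_dimension(ep.labels, "identity")
        cfg = DecodeConfig(n_iterations=2)
        gm = decode_crosstime(ep, labels, cfg, seed=5)
        _, store = decode_timecourse(ep, labels, cfg, seed=5)
        assert np.array_equal(np.diag(gm.accuracy), store.accuracy())

    def test_dynamic_code_is_diagonal_dominant(self, windowed):
        """With three topography segments the code changes over time, so
        same-window decoding beats far-off-diagonal transfer."""
        ep, _ = windowed
        labels = core.collapse_dimension(ep.labels, "identity")
        gm = decode_crosstime(ep, labels, DecodeConfig(n_iterations=3), seed=7)
        post = ep.times >= 0
        diag = np.diag(gm.accuracy)[post]
        lag = np.abs(np.subtract.outer(np.arange(20), np.arange(20)))
        far = gm.accuracy[np.ix_(post, post)][lag[np.ix_(post, post)] >= 3]
        assert diag.mean() > far.mean() + 0.05

    def test_static_noiseless_code_generalizes_fully(self):
        cfg = dataclasses.replace(
            synth.SynthConfig(), n_trials=32, n_channels=8, fs=100.0,
            epoch_ms=(-100.0, 400.0), n_pattern_segments=1,
            segment_edges_ms=(0.0,), expression_gain=0.0,
            identity_envelope=synth.EnvelopeParams(0.0 - 1e-9, 50.0, 1e9, 1.0),
            noise=synth.NoiseParams(0.0, 0.0, 0.0))
        topo = synth.make_topographies(cfg, seed=1)
        ep = synth.simulate_participant(cfg, topo, seed=2)
        epw = preprocess.window_average(ep, 100.0)
        labels = core.collapse_dimension(ep.labels, "identity")
        gm = decode_crosstime(epw, labels, DecodeConfig(n_iterations=1), seed=3)
        on = epw.times >= 100.0  # windows fully inside the plateau
        assert (gm.accuracy[np.ix_(on, on)] == 1.0).all()


class TestCrossdim:
    def _epochs_with_fields(self, field_fn, n_trials=128, n_channels=10,
                            n_times=8, seed=0):
        """Voltage = field_fn(identity, expression) + tiny jitter."""
        labels = balanced_labels(n_trials, seed=seed)
        rng = np.random.default_rng(seed + 1)
        data = np.empty((n_trials, n_channels, n_times))
        for i in range(n_trials):
            pat = field_fn(labels.identity[i], labels.expression[i])
            data[i] = pat[:, None] + rng.standard_normal((n_channels, n_times)) * 1e-3
        return core.EpochSet(data=data.astype(np.float32), fs=250.0, t_start_ms=0.0,
                             channel_names=synth.default_channel_names(n_channels),
                             participant_id="x", labels=labels)

    def test_target_signal_generalizes(self):
        rng = np.random.default_rng(3)
        pats = rng.standard_normal((4, 10)) * 3
        ep = self._epochs_with_fields(lambda i, e: pats[i - 1])
        series, store = decode_crossdim(
            ep, ep.labels.identity, ep.labels.expression, DecodeConfig())
        assert (store.accuracy() == 1.0).all()
        assert store.n_attempts == 16

    def test_control_only_signal_is_chance(self):
        rng = np.random.default_rng(4)
        pats = rng.standard_normal((4, 10)) * 3
        ep = self._epochs_with_fields(lambda i, e: pats[e - 1], seed=5)
        series, store = decode_crossdim(
            ep, ep.labels.identity, ep.labels.expression, DecodeConfig())
        grand = store.accuracy().mean()
        assert abs(grand - 0.25) < 0.15

    def test_interaction_only_signal_fails_to_generalize(self):
        """Independent patterns per (target, control) cell: the held-out
        control level's patterns share nothing with the training levels, so
        cross-dimension decoding stays at chance while ordinary decoding
        (whose class means pool all cells) succeeds -- the analysis isolates
        information that generalizes across the control dimension."""
        rng = np.random.default_rng(6)
        pats = rng.standard_normal((4, 4, 12)) * 3
        ep = self._epochs_with_fields(lambda i, e: pats[i - 1, e - 1],
                                      n_channels=12, seed=7)
        _, store_cd = decode_crossdim(
            ep, ep.labels.identity, ep.labels.expression, DecodeConfig())
        assert abs(store_cd.accuracy().mean() - 0.25) < 0.15
        _, store_tc = decode_timecourse(
            ep, ep.labels.identity, DecodeConfig(n_iterations=2), seed=8)
        assert store_tc.accuracy().mean() > 0.6

    def test_empty_cell_rejected(self):
        ep = self._epochs_with_fields(lambda i, e: np.zeros(10), seed=8)
        control = ep.labels.expression.copy()
        control[(ep.labels.identity == 1) & (control == 2)] = 3
        with pytest.raises(DataError, match="cell"):
            decode_crossdim(ep, ep.labels.identity, control, DecodeConfig())


class TestConfusion:
    def _store(self, predicted, true, times):
        return core.PredictionStore(predicted=predicted, true=true, n_classes=4,
                                    times=times, n_iterations=1, n_folds=1)

    def test_perfect_decoder_identity_matrix(self):
        true = np.tile(np.arange(1, 5), 3)
        pred = np.tile(true[:, None], (1, 10))
        st = self._store(pred, true, np.arange(10.0))
        (cm,) = confusion_by_period(st, [(0.0, 10.0)])
        assert np.allclose(cm.matrix, np.eye(4))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        true = np.tile(np.arange(1, 5), 6)
        pred = rng.integers(1, 5, size=(24, 20))
        st = self._store(pred, true, np.arange(20.0))
        (cm,) = confusion_by_period(st, [(0.0, 20.0)])
        assert np.allclose(cm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_default_periods_give_two_matrices(self):
        true = np.tile(np.arange(1, 5), 2)
        times = np.arange(-500.0, 1500.0, 4.0)
        pred = np.tile(true[:, None], (1, times.size))
        st = self._store(pred, true, times)
        mats = confusion_by_period(st, [(0.0, 500.0), (500.0, 1500.0)])
        assert len(mats) == 2
        assert mats[0].period_ms == (0.0, 500.0)
        assert mats[1].period_ms == (500.0, 1500.0)

    def test_empty_period_rejected(self):
        true = np.tile(np.arange(1, 5), 2)
        st = self._store(np.tile(true[:, None], (1, 5)), true, np.arange(5.0))
        with pytest.raises(DataError):
            confusion_by_period(st, [(100.0, 200.0)])
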