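"""Parcellation model: forward-pass properties, training, prediction."""

import warnings

import numpy as np
import pytest

from tractofov.experiments import desk_model_params
from tractofov.model import (
    TractographyParcellator,
    group_parcellation,
    load_model,
    save_model,
)
from tractofov.nn import LocalGlobalPointNet, softmax
from tractofov.tractogram import LabeledTractogram

from conftest import random_polyline


@pytest.fixture
def net():
    return LocalGlobalPointNet(
        n_classes=4, repr_width=16, backbone_widths=(16, 32), head_widths=(24,),
        rng=np.random.default_rng(0),
    )


@pytest.fixture
def block(rng):
    return rng.normal(0, 20, size=(5, 9, 7, 6)).astype(np.float32)


class TestForwardProperties:
    def test_softmax_normalized_nonnegative(self, net, block):
        proba = net.predict_proba(block)
        assert np.all(proba >= 0)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_context_row_permutation_invariance(self, net, block, rng):
        base = net.forward(block)
        perm = np.concatenate([[0], 1 + rng.permutation(block.shape[1] - 1)])
        out = net.forward(block[:, perm])
        np.testing.assert_allclose(out, base, atol=1e-5)

    def test_consistent_point_permutation_is_pooled_away(self, net, block, rng):
        # shared per-point transforms + max-pool: reordering anchor and
        # context points together cannot change the output
        base = net.forward(block)
        perm = rng.permutation(block.shape[2])
        out = net.forward(block[:, :, perm])
        np.testing.assert_allclose(out, base, atol=1e-5)

    def test_breaking_point_correspondence_changes_output(self, net, block, rng):
        # geometry enters through the anchor-context pairing: permuting the
        # context triples against the anchor triples alters the pairs
        base = net.forward(block)
        perm = rng.permutation(block.shape[2])
        broken = block.copy()
        broken[:, :, :, 3:] = block[:, :, perm, 3:]
        out = net.forward(broken)
        assert not np.allclose(out, base, atol=1e-4)

    def test_shape_mismatch_raises(self, net, rng):
        with pytest.raises(ValueError):
            net.forward(rng.normal(size=(2, 3, 4, 5)))

    def test_gradients_match_finite_differences(self):
        """Spot-check the hand-written backprop on a tiny network."""
        net = LocalGlobalPointNet(
            n_classes=3, repr_width=4, backbone_widths=(5,), head_widths=(6,),
            dropout=0.0, rng=np.random.default_rng(1),
        )
        rng = np.random.default_rng(2)
        x = rng.normal(0, 30, size=(3, 4, 5, 6)).astype(np.float32)
        y = np.array([0, 2, 1])

        def loss_of(params):
            saved = {k: v.copy() for k, v in net.params.items()}
            net.params.update(params)
            logits = net.forward(x)
            p = softmax(logits)
            val = -np.log(p[np.arange(3), y]).mean()
            net.params.update(saved)
            return val

        logits = net.forward(x)
        p = softmax(logits)
        dlogits = p.copy()
        dlogits[np.arange(3), y] -= 1.0
        grads = net.backward((dlogits / 3).astype(np.float32))
        eps = 1e-3
        for key in ("repr.W", "bb0.W", "head0.W", "out.b"):
            W = net.params[key]
            flat_idx = [0, W.size // 2, W.size - 1]
            for fi in flat_idx:
                pert = {key: W.copy()}
                pert[key].flat[fi] += eps
                up = loss_of(pert)
                pert[key].flat[fi] -= 2 * eps
                dn = loss_of(pert)
                numeric = (up - dn) / (2 * eps)
                assert grads[key].flat[fi] == pytest.approx(numeric, abs=5e-3)


def _two_class_tractogram(rng, n=60):
    a = [random_polyline(rng, n_points=6) for _ in range(n // 2)]
    b = [random_polyline(rng, n_points=6) + [60, 0, 0] for _ in range(n - n // 2)]
    return LabeledTractogram(
        streamlines=a + b,
        labels=np.array([0] * (n // 2) + [1] * (n - n // 2)),
        class_names=["a", "b"],
    )


TINY = dict(
    n_points=8, n_local=3, n_global=5, repr_width=8, backbone_widths=(8, 16),
    head_widths=(12,), epochs=2, batch_size=16, random_state=0,
)


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_at_init(self, rng):
        t = _two_class_tractogram(rng)
        est = TractographyParcellator(lr=0.0, **TINY)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(t)
        ref = LocalGlobalPointNet(
            n_classes=2, repr_width=8, backbone_widths=(8, 16), head_widths=(12,),
            dropout=est.dropout, rng=np.random.default_rng(0),
        )
        for k in ref.params:
            np.testing.assert_array_equal(est.net_.params[k], ref.params[k])

    def test_single_class_raises(self, rng):
        t = _two_class_tractogram(rng)
        t.labels[:] = 0
        with pytest.raises(ValueError):
            TractographyParcellator(**TINY).fit(t)

    def test_unlabeled_raises(self, rng):
        t = _two_class_tractogram(rng)
        t.labels = None
        with pytest.raises(ValueError):
            TractographyParcellator(**TINY).fit(t)

    def test_history_length_and_loss_decreases(self, fitted_separable_model):
        hist = fitted_separable_model.history_
        assert len(hist["train_loss"]) == fitted_separable_model.epochs
        assert hist["train_loss"][-1] <= hist["train_loss"][0]

    def test_identical_seeds_reproduce_training(self, rng):
        t = _two_class_tractogram(rng)
        runs = []
        for _ in range(2):
            est = TractographyParcellator(**TINY)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(t)
            runs.append(est.history_["train_loss"][-1])
        assert runs[0] == runs[1]

    def test_batch_size_reduced_with_warning(self, rng):
        t = _two_class_tractogram(rng, n=20)
        est = TractographyParcellator(**{**TINY, "batch_size": 4096})
        with pytest.warns(UserWarning, match="reducing"):
            est.fit(t)


class TestPrediction:
    def test_separable_bundles_learned(self, fitted_separable_model, separable_tractogram):
        acc = fitted_separable_model.score(separable_tractogram)
        assert acc >= 0.95

    def test_output_length_matches_input(self, fitted_separable_model, separable_tractogram):
        pred = fitted_separable_model.predict(separable_tractogram)
        assert len(pred) == len(separable_tractogram)

    def test_duplicate_streamline_gets_identical_label(
        self, fitted_separable_model, separable_tractogram
    ):
        t = separable_tractogram
        dup = LabeledTractogram(
            streamlines=list(t.streamlines) + [t.streamlines[0].copy()]
        )
        pred = fitted_separable_model.predict(dup)
        assert pred[0] == pred[-1]
        proba = fitted_separable_model.predict_proba(dup)
        np.testing.assert_allclose(proba[0], proba[-1], atol=1e-6)

    def test_prediction_deterministic(self, fitted_separable_model, separable_tractogram):
        a = fitted_separable_model.predict_proba(separable_tractogram)
        b = fitted_separable_model.predict_proba(separable_tractogram)
        np.testing.assert_array_equal(a, b)

    def test_too_few_streamlines_raises(self, fitted_separable_model, rng):
        t = LabeledTractogram(streamlines=[random_polyline(rng) for _ in range(3)])
        with pytest.raises(ValueError):
            fitted_separable_model.predict(t)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(
        self, tmp_path, fitted_separable_model, separable_tractogram
    ):
        path = tmp_path / "model.ckpt"
        save_model(fitted_separable_model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(
            loaded.predict(separable_tractogram),
            fitted_separable_model.predict(separable_tractogram),
        )
        assert loaded.get_params() == fitted_separable_model.get_params()


class TestGroupParcellation:
    def test_single_class(self, rng):
        t = _two_class_tractogram(rng, n=6)
        groups = group_parcellation([0] * 6, t)
        assert len(groups["a"]) == 6
        assert groups["b"] == []

    def test_partition_property(self, rng):
        t = _two_class_tractogram(rng, n=8)
        labels = [0, 1, 0, 1, 1, 0, 0, 1]
        groups = group_parcellation(labels, t)
        flat = sorted(i for idx in groups.values() for i in idx)
        assert flat == list(range(8))

    def test_sizes(self, rng):
        t = LabeledTractogram(
            streamlines=[random_polyline(rng) for _ in range(4)],
            class_names=["t0", "t1", "t2"],
        )
        groups = group_parcellation([0, 1, 0, 2], t)
        assert {k: len(v) for k, v in groups.items()} == {"t0": 2, "t1": 1, "t2": 1}


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        est = TractographyParcellator(n_local=7)
        params = est.get_params()
        assert params["n_local"] == 7
        est.set_params(n_global=42)
        assert est.get_params()["n_global"] == 42

    def test_desk_params_are_valid_estimator_params(self):
        TractographyParcellator(**desk_model_params())
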