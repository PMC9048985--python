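"""Dual-pathway network: architecture, preprocessing, training, k-fold."""

import numpy as np
import pytest
from dataclasses import replace

from dcepk.cnn_surrogate import (NetworkSpec, TrainSpec, architecture_summary,
                                 build_network, make_fold_plan, predict,
                                 preprocess_for_net, run_kfold, save_model,
                                 load_model, train_fold, TrainedModel)

TINY = NetworkSpec(in_channels=8, stem_filters=8, fc_nodes=(16, 8, 1))


def smooth_mapping_data(rng, n=1, h=24, w=24, c=8):
    """Inputs whose channel-mean is the target: learnable by construction."""
    x = rng.standard_normal((n, h, w, c)).astype(np.float32)
    base = rng.standard_normal((n, h, w, 1)).astype(np.float32)
    x = x * 0.3 + base
    y = base[..., 0] * 2.0 + 1.0
    mask = np.ones((n, h, w), bool)
    return x, y, mask


class TestArchitecture:
    def test_full_scale_audit(self):
        """Walk of the composed graph: filters, kernels, dilations, head."""
        summary = architecture_summary(build_network(NetworkSpec(), seed=0))
        assert summary["stem_filters"] == 128
        assert summary["stem_kernel"] == 4
        assert summary["pathway_kernels"] == [4]
        assert summary["local_filters"] == [128, 128, 128]
        assert summary["local_dilations"] == [1, 1, 1]
        assert summary["global_dilations"] == [2, 4, 8]
        assert summary["concat_channels"] == 256
        assert summary["head_nodes"] == [1024, 512, 128, 1]
        assert summary["head_kernels"] == [1, 1, 1, 1]
        assert summary["preserves_size"]

    def test_output_is_single_channel_same_size(self):
        net = build_network(TINY, seed=1)
        out = net.forward(np.zeros((2, 20, 28, 8), np.float32), train=False)
        assert out.shape == (2, 20, 28, 1)

    def test_all_zero_input_gives_finite_bias_only_output(self):
        net = build_network(TINY, seed=2)
        out = net.forward(np.zeros((1, 16, 16, 8), np.float32), train=False)
        assert np.all(np.isfinite(out))
        assert np.ptp(out) == pytest.approx(0.0, abs=1e-6)

    def test_depthwise_and_standard_stems_both_compose(self):
        for mode in ("depthwise", "standard"):
            spec = replace(TINY, stem_mode=mode)
            net = build_network(spec, seed=0)
            out = net.forward(np.zeros((1, 12, 12, 8), np.float32), train=False)
            assert out.shape == (1, 12, 12, 1)


class TestPreprocess:
    def _dyn(self, rng, frames=40):
        sig = rng.uniform(10, 100, (16, 16, frames, 2))
        mask = np.zeros((16, 16, 2), bool)
        mask[4:12, 4:12, :] = True
        return sig, mask

    def test_planewise_standardization(self, rng):
        sig, mask = self._dyn(rng)
        out = preprocess_for_net(sig, mask)
        assert out.shape == (2, 16, 16, 40)
        for s in range(2):
            for t in (0, 17, 39):
                vals = out[s, :, :, t][mask[:, :, s]]
                assert abs(vals.mean()) < 1e-6
                assert vals.std() == pytest.approx(1.0, abs=1e-5)
        assert np.all(out[:, ~mask[:, :, 0], :] * 0 == 0)

    def test_masked_out_voxels_are_zero(self, rng):
        sig, mask = self._dyn(rng)
        out = preprocess_for_net(sig, mask)
        for s in range(2):
            assert np.all(out[s][~mask[:, :, s]] == 0.0)

    def test_long_series_truncated_to_40(self, rng):
        sig, mask = self._dyn(rng, frames=55)
        out = preprocess_for_net(sig, mask)
        assert out.shape[-1] == 40

    def test_too_few_dynamics_rejected(self, rng):
        sig, mask = self._dyn(rng, frames=30)
        with pytest.raises(ValueError):
            preprocess_for_net(sig, mask)

    def test_constant_plane_maps_to_zero(self):
        sig = np.ones((8, 8, 40, 1))
        mask = np.ones((8, 8, 1), bool)
        out = preprocess_for_net(sig, mask)
        assert np.all(out == 0.0)


class TestTraining:
    def test_single_sample_overfit_sanity(self, rng):
        """A correctly wired regression net fits one slice far below target SD."""
        x, y, mask = smooth_mapping_data(rng)
        tspec = TrainSpec(lr=3e-3, l2=0.0, max_epochs=300, minibatch=1,
                          val_every=1000, patience=1000, seed=3)
        model = train_fold(x, y, mask, None, None, None, tspec, TINY)
        pred = predict(model, x, mask)
        final_rmse = np.sqrt(np.mean((pred - y)[mask] ** 2))
        assert final_rmse < 0.1 * y[mask].std()
        losses = model.history.train_loss.to_numpy()
        assert losses[-10:].mean() < 0.05 * losses[:5].mean()

    def test_training_is_deterministic_given_seed(self, rng):
        x, y, mask = smooth_mapping_data(rng, n=2)
        tspec = TrainSpec(lr=1e-3, max_epochs=5, minibatch=2, seed=4)
        m1 = train_fold(x, y, mask, None, None, None, tspec, TINY)
        m2 = train_fold(x, y, mask, None, None, None, tspec, TINY)
        assert m1.history.train_loss.equals(m2.history.train_loss)
        for w1, w2 in zip(m1.net.get_weights(), m2.net.get_weights()):
            for a, b in zip(w1, w2):
                assert np.array_equal(a, b)

    def test_zero_learning_rate_leaves_weights_unchanged(self, rng):
        x, y, mask = smooth_mapping_data(rng)
        tspec = TrainSpec(lr=0.0, l2=0.0, max_epochs=3, minibatch=1, seed=5)
        model = train_fold(x, y, mask, None, None, None, tspec, TINY)
        ref = build_network(TINY, seed=0)
        init = np.random.default_rng(tspec.seed)
        ref_net = type(model.net)(TINY, init)
        for w1, w2 in zip(model.net.get_weights(), ref_net.get_weights()):
            for a, b in zip(w1, w2):
                assert np.array_equal(a, b)
        assert model.history.train_loss.nunique() == 1

    def test_l2_regularization_shrinks_final_weight_norm(self, rng):
        x, y, mask = smooth_mapping_data(rng)
        kw = dict(lr=1e-3, max_epochs=30, minibatch=1, seed=6)
        m_l2 = train_fold(x, y, mask, None, None, None,
                          TrainSpec(l2=1e-1, **kw), TINY)
        m_0 = train_fold(x, y, mask, None, None, None,
                         TrainSpec(l2=0.0, **kw), TINY)
        assert m_l2.net.weight_norm() < m_0.net.weight_norm()

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_fold(np.zeros((0, 8, 8, 8), np.float32), np.zeros((0, 8, 8)),
                       np.zeros((0, 8, 8), bool), None, None, None,
                       TrainSpec(), TINY)


class TestPredict:
    def _model(self, rng):
        x, y, mask = smooth_mapping_data(rng)
        tspec = TrainSpec(lr=1e-3, max_epochs=3, minibatch=1, seed=7)
        return train_fold(x, y, mask, None, None, None, tspec, TINY), x, mask

    def test_inference_is_deterministic(self, rng):
        model, x, mask = self._model(rng)
        p1 = predict(model, x, mask)
        p2 = predict(model, x, mask)
        assert np.array_equal(p1, p2)

    def test_output_respects_mask(self, rng):
        model, x, mask = self._model(rng)
        mask2 = mask.copy()
        mask2[:, :5, :] = False
        pred = predict(model, x, mask2)
        assert np.all(pred[:, :5, :] == 0.0)

    def test_channel_mismatch_rejected(self, rng):
        model, x, mask = self._model(rng)
        with pytest.raises(ValueError):
            predict(model, x[..., :4], mask)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model, x, mask = self._model(rng)
        save_model(model, tmp_path / "w.npz")
        loaded = load_model(tmp_path / "w.npz")
        assert np.array_equal(predict(model, x, mask), predict(loaded, x, mask))


class TestFoldPlan:
    def test_six_subjects_rotate_through_testing(self):
        plan = make_fold_plan(6, 5, seed=0)
        assert len(plan.folds) == 6
        assert sorted(f["test_subject"] for f in plan.folds) == list(range(6))
        for f in plan.folds:
            val_subjects = {s for s, _ in f["val"]}
            assert len(f["val"]) == 5  # one slice per remaining subject
            assert val_subjects == set(range(6)) - {f["test_subject"]}
            assert not set(f["train"]) & set(f["val"])

    def test_two_subjects_give_two_folds(self):
        plan = make_fold_plan(2, 3, seed=1)
        assert len(plan.folds) == 2

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(1, 5)

    def test_transfer_to_new_cohort_is_finite_and_masked(self, rng):
        """A net trained on one synthetic cohort yields finite, masked
        predictions on a differently specified cohort."""
        x, y, mask = smooth_mapping_data(rng, n=2)
        tspec = TrainSpec(lr=1e-3, max_epochs=3, minibatch=2, seed=8)
        model = train_fold(x, y, mask, None, None, None, tspec, TINY)
        x2 = rng.standard_normal((1, 24, 24, 8)).astype(np.float32) * 5.0
        mask2 = np.zeros((1, 24, 24), bool)
        mask2[0, 8:14, 3:9] = True
        pred = predict(model, x2, mask2)
        assert np.all(np.isfinite(pred))
        assert np.all(pred[~mask2] == 0.0)
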