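import numpy as np
import pytest

from crysvit import model as M
from crysvit.autograd import Tensor


class TestForward:
    def test_output_matches_input_shape(self):
        net = M.CompletionModel(M.toy_config(), seed=0)
        x = np.random.default_rng(0).normal(size=(16, 12, 8)).astype(np.float32)
        out = net.forward(x, x)
        assert out.shape == (16, 12, 8)
        assert np.isfinite(out.data).all()

    def test_non_divisible_axes_padded_and_cropped(self):
        net = M.CompletionModel(M.toy_config(), seed=0)
        x = np.random.default_rng(1).normal(size=(13, 10, 7)).astype(np.float32)
        out = net.forward(x, x)
        assert out.shape == (13, 10, 7)

    def test_batched_input(self):
        net = M.CompletionModel(M.toy_config(), seed=0)
        x = np.random.default_rng(2).normal(size=(2, 8, 8, 8)).astype(np.float32)
        assert net.forward(x, x).shape == (2, 8, 8, 8)

    def test_shape_mismatch_rejected(self):
        net = M.CompletionModel(M.toy_config(), seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((8, 8, 8)), np.zeros((8, 8, 4)))

    def test_scale_equivariant_stem_runs(self):
        net = M.CompletionModel(M.toy_config(scale_equivariant=True), seed=0)
        x = np.random.default_rng(3).normal(size=(8, 8, 8)).astype(np.float32)
        assert net.forward(x, x).shape == (8, 8, 8)


class TestNystromAttention:
    def _qkv(self, rng, n=256, d=16, heads=2, smooth=8.0):
        """Token fields with sequence-local correlation (token grids from
        volumetric maps vary smoothly), variance-normalised after smoothing.
        Segment-mean landmarks represent such sequences; they cannot
        represent i.i.d. tokens, whose attention matrix is full rank."""
        from scipy.ndimage import gaussian_filter1d

        def field():
            x = gaussian_filter1d(rng.normal(size=(1, heads, n, d)), smooth,
                                  axis=2, mode="wrap")
            return Tensor((x / x.std()).astype(np.float32))
        return field(), field(), field()

    def test_close_to_exact_attention(self):
        """Nyström approximation vs the exact softmax-attention oracle."""
        rng = np.random.default_rng(0)
        rel_errs = []
        for _ in range(100):
            q, k, v = self._qkv(rng)
            exact = M.exact_attention(q, k, v).data
            approx = M.nystrom_attention(q, k, v, landmarks=64).data
            rel_errs.append(np.linalg.norm(approx - exact) / np.linalg.norm(exact))
        assert max(rel_errs) < 0.15

    def test_converges_with_landmark_count(self):
        rng = np.random.default_rng(1)
        q, k, v = self._qkv(rng, n=128, smooth=4.0)
        exact = M.exact_attention(q, k, v).data
        errs = [np.linalg.norm(M.nystrom_attention(q, k, v, landmarks=m).data - exact)
                for m in (8, 32, 96)]
        assert errs[2] < errs[0]

    def test_exact_fallback_below_landmark_count(self):
        rng = np.random.default_rng(2)
        q, k, v = self._qkv(rng, n=32)
        exact = M.exact_attention(q, k, v).data
        approx = M.nystrom_attention(q, k, v, landmarks=64).data
        assert np.allclose(approx, exact)


class TestLoss:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=(6, 6, 6)).astype(np.float32)
        pred = Tensor(t.copy())
        assert float(M.loss(pred, t, pc_weight=1.0).data) == pytest.approx(-1.0, abs=1e-6)
        assert float(M.loss(pred, t, pc_weight=0.0).data) == 0.0

    def test_zero_weight_is_plain_mse(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=(5, 5, 5)).astype(np.float32)
        p = rng.normal(size=(5, 5, 5)).astype(np.float32)
        got = float(M.loss(Tensor(p), t, pc_weight=0.0).data)
        assert got == pytest.approx(((p - t) ** 2).mean(), rel=1e-6)

    def test_mse_gradient_vanishes_at_optimum(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=(4, 4, 4)).astype(np.float32)
        norms = []
        for eps in (0.1, 0.01):
            pred = Tensor(t + eps, requires_grad=True)
            M.loss(pred, t, pc_weight=0.0).backward()
            norms.append(np.linalg.norm(pred.grad))
        assert norms[1] < norms[0] / 5

    def test_zero_variance_truth_warns(self):
        pred = Tensor(np.random.default_rng(3).normal(size=(4, 4, 4)).astype(np.float32))
        with pytest.warns(UserWarning):
            l = M.loss(pred, np.ones((4, 4, 4)), pc_weight=1.0)
        assert np.isfinite(l.data)


class TestSchedule:
    def test_endpoints_match_config(self):
        cfg = M.TrainConfig()
        total = 100
        assert M.one_cycle_lr(0, total, cfg) == pytest.approx(cfg.lr_initial, abs=1e-12)
        warm = int(round(cfg.warmup_fraction * total))
        assert M.one_cycle_lr(warm, total, cfg) == pytest.approx(cfg.lr_max, abs=1e-9)
        assert M.one_cycle_lr(total - 1, total, cfg) == pytest.approx(cfg.lr_final, abs=1e-12)

    def test_one_cycle_shape(self):
        cfg = M.TrainConfig()
        lrs = [M.one_cycle_lr(s, 60, cfg) for s in range(60)]
        peak = int(np.argmax(lrs))
        assert all(a <= b + 1e-12 for a, b in zip(lrs[:peak], lrs[1:peak + 1]))
        assert all(a >= b - 1e-12 for a, b in zip(lrs[peak:], lrs[peak + 1:]))


class TestTraining:
    def _toy_batches(self, n=4, shape=(8, 8, 8), seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            tru = rng.normal(size=shape).astype(np.float32)
            pat = rng.normal(size=shape).astype(np.float32)
            tpl = (tru + 0.5 * rng.normal(size=shape)).astype(np.float32)
            out.append([(pat, tpl, tru)])
        return out

    def test_deterministic_under_seed(self):
        losses = []
        for _ in range(2):
            net = M.CompletionModel(M.toy_config(), seed=7)
            hist = M.train_toy(self._toy_batches(), net, M.TrainConfig(seed=7), max_steps=10)
            losses.append(hist.losses[9])
        assert abs(losses[0] - losses[1]) < 1e-5

    def test_loss_decreases(self):
        net = M.CompletionModel(M.toy_config(), seed=0)
        hist = M.train_toy(self._toy_batches(), net, M.TrainConfig(seed=0), max_steps=30)
        assert np.mean(hist.losses[-5:]) < np.mean(hist.losses[:5])

    def test_empty_dataset_rejected(self):
        net = M.CompletionModel(M.toy_config(), seed=0)
        with pytest.raises(ValueError):
            M.train_toy([], net, M.TrainConfig())


class TestConfig:
    def test_upsample_positions_validated(self):
        with pytest.raises(ValueError):
            M.ModelConfig(n_layers=4, downsample_after=(2,), upsample_after=(8,))

    def test_toy_preset_overrides(self):
        cfg = M.toy_config(pc_loss_weight=0.5)
        assert cfg.pc_loss_weight == 0.5 and cfg.patch == 2
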