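"""Analytic gradients of every autodiff operation are verified against
central finite differences on small random tensors."""
import numpy as np
import pytest

from densfx.nn import autograd as ag
from densfx.nn.autograd import Tensor
from densfx.nn.layers import BatchNorm3d
from densfx.nn.losses import (
    compute_class_weights,
    cross_entropy_loss,
    dice_ce_loss,
    soft_dice,
    softmax,
)


def numerical_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def backprop_sum_of_squares(out_nodes):
    """Seed d(sum out^2)/dout and walk the recorded nodes in reverse."""
    out_nodes[-1].grad = 2 * out_nodes[-1].data
    for node in reversed(out_nodes):
        if node.grad is not None and node._backward is not None:
            node._backward(node.grad)


class TestOpGradients:
    def test_conv3d(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(2, 2, 4, 4, 4)), requires_grad=True)
        w = Tensor(rng.normal(size=(3, 2, 3, 3, 3)), requires_grad=True)
        b = Tensor(rng.normal(size=3), requires_grad=True)
        out = ag.conv3d(x, w, b)
        backprop_sum_of_squares([out])

        def f():
            return float((ag.conv3d(Tensor(x.data), Tensor(w.data), Tensor(b.data)).data ** 2).sum())

        for t in (x, w, b):
            assert np.abs(t.grad - numerical_grad(f, t.data)).max() < 1e-5

    def test_conv3d_1x1(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.normal(size=(1, 3, 2, 2, 2)), requires_grad=True)
        w = Tensor(rng.normal(size=(2, 3, 1, 1, 1)), requires_grad=True)
        out = ag.conv3d(x, w)
        backprop_sum_of_squares([out])

        def f():
            return float((ag.conv3d(Tensor(x.data), Tensor(w.data)).data ** 2).sum())

        for t in (x, w):
            assert np.abs(t.grad - numerical_grad(f, t.data)).max() < 1e-6

    def test_maxpool_with_distinct_values(self):
        rng = np.random.default_rng(2)
        x = Tensor(rng.permutation(64).astype(float).reshape(1, 1, 4, 4, 4), requires_grad=True)
        out = ag.maxpool2(x)
        backprop_sum_of_squares([out])

        def f():
            return float((ag.maxpool2(Tensor(x.data)).data ** 2).sum())

        # gradient entries are O(100); finite differences carry ~1e-6 noise
        assert np.abs(x.grad - numerical_grad(f, x.data)).max() < 1e-4

    def test_upsample(self):
        rng = np.random.default_rng(3)
        x = Tensor(rng.normal(size=(1, 2, 2, 2, 2)), requires_grad=True)
        out = ag.upsample2(x)
        backprop_sum_of_squares([out])

        def f():
            return float((ag.upsample2(Tensor(x.data)).data ** 2).sum())

        assert np.abs(x.grad - numerical_grad(f, x.data)).max() < 1e-6

    def test_matmul_bias_relu_chain(self):
        rng = np.random.default_rng(4)
        x = Tensor(rng.normal(size=(3, 5)), requires_grad=True)
        w = Tensor(rng.normal(size=(5, 4)), requires_grad=True)
        b = Tensor(rng.normal(size=4), requires_grad=True)
        h = ag.matmul(x, w)
        a = ag.add_bias(h, b)
        r = ag.relu(a)
        backprop_sum_of_squares([h, a, r])

        def f():
            t = ag.relu(ag.add_bias(ag.matmul(Tensor(x.data), Tensor(w.data)), Tensor(b.data)))
            return float((t.data**2).sum())

        for t in (x, w, b):
            assert np.abs(t.grad - numerical_grad(f, t.data)).max() < 1e-6

    def test_batchnorm_training_mode(self):
        rng = np.random.default_rng(5)
        x = Tensor(rng.normal(size=(2, 2, 2, 2, 2)), requires_grad=True)
        bn = BatchNorm3d(2)

        def f():
            return float((bn(Tensor(x.data), True).data ** 3).sum())

        out = bn(x, True)
        out.grad = 3 * out.data**2
        out._backward(out.grad)
        assert np.abs(x.grad - numerical_grad(f, x.data)).max() < 1e-6
        assert np.abs(bn.gamma.grad - numerical_grad(f, bn.gamma.data)).max() < 1e-6

    def test_concat_channels_splits_gradient(self):
        rng = np.random.default_rng(6)
        a = Tensor(rng.normal(size=(1, 2, 2, 2, 2)), requires_grad=True)
        b = Tensor(rng.normal(size=(1, 3, 2, 2, 2)), requires_grad=True)
        out = ag.concat_channels(a, b)
        backprop_sum_of_squares([out])
        assert np.allclose(a.grad, 2 * a.data)
        assert np.allclose(b.grad, 2 * b.data)


class TestLosses:
    def test_cross_entropy_gradient(self):
        rng = np.random.default_rng(7)
        logits = Tensor(rng.normal(size=(5, 2)), requires_grad=True)
        y = np.array([0, 1, 1, 0, 1])
        loss = cross_entropy_loss(logits, y, (0.6, 2.3))
        loss.backward()

        def f():
            return float(cross_entropy_loss(Tensor(logits.data), y, (0.6, 2.3)).data)

        assert np.abs(logits.grad - numerical_grad(f, logits.data)).max() < 1e-6

    def test_dice_ce_gradient(self):
        rng = np.random.default_rng(8)
        logits = Tensor(rng.normal(size=(1, 2, 4, 4, 4)), requires_grad=True)
        target = (rng.random((1, 4, 4, 4)) > 0.5).astype(float)
        loss = dice_ce_loss(logits, target, 0.5, 0.5, (0.7, 2.3))
        loss.backward()

        def f():
            return float(dice_ce_loss(Tensor(logits.data), target, 0.5, 0.5, (0.7, 2.3)).data)

        assert np.abs(logits.grad - numerical_grad(f, logits.data)).max() < 1e-6

    def test_perfect_prediction_has_near_zero_loss(self):
        target = np.zeros((1, 2, 2, 2))
        target[0, 0, :, :] = 1.0
        logits = np.zeros((1, 2, 2, 2, 2))
        logits[:, 1] = 40.0 * target - 20.0
        logits[:, 0] = -logits[:, 1]
        loss = dice_ce_loss(Tensor(logits), target)
        assert float(loss.data) < 1e-4

    def test_complement_prediction_has_unit_dice_term(self):
        target = np.zeros((1, 2, 2, 2))
        target[0, 0] = 1.0
        logits = np.zeros((1, 2, 2, 2, 2))
        logits[:, 1] = -40.0 * target + 20.0
        logits[:, 0] = -logits[:, 1]
        loss = dice_ce_loss(Tensor(logits), target, dice_weight=1.0, ce_weight=0.0)
        assert float(loss.data) == pytest.approx(1.0, abs=1e-4)

    def test_uniform_prediction_soft_dice_closed_form(self):
        # 2x2x2 target with half the voxels on; p1 = 0.5 everywhere
        target = np.zeros((2, 2, 2))
        target[0] = 1.0
        p1 = np.full((2, 2, 2), 0.5)
        t_count = target.sum()
        expected = 2 * (0.5 * t_count) / (0.5 * 8 + t_count)
        assert soft_dice(p1, target) == pytest.approx(expected, abs=1e-6)

    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        p = softmax(rng.normal(size=(6, 2)))
        assert np.allclose(p.sum(axis=1), 1.0)


class TestClassWeights:
    def test_study_counts_give_documented_weights(self):
        w = compute_class_weights((287, 79))
        assert w[0] == pytest.approx(366 / 574, abs=1e-4)
        assert w[1] == pytest.approx(366 / 158, abs=1e-4)
        assert w[0] == pytest.approx(0.6376, abs=1e-4)
        assert w[1] == pytest.approx(2.3165, abs=1e-4)
        # prevalence-weighted mean of the weights is 1
        prev = np.array([287, 79]) / 366
        assert float((w * prev).sum()) == pytest.approx(1.0)

    @pytest.mark.parametrize("counts", [(50, 50), (1, 1)])
    def test_balanced_counts_give_unit_weights(self, counts):
        assert np.allclose(compute_class_weights(counts), 1.0)

    def test_zero_count_class_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights((10, 0))
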