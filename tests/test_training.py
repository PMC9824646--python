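"""Cross-entropy, the training loop, and the numpy engine's gradients."""

import numpy as np
import pytest

from csbnet.config import ModelConfig, TrainConfig
from csbnet.model import build_network
from csbnet.nn import Adam
from csbnet.training import (
    cross_entropy,
    evaluate,
    softmax,
    softmax_cross_entropy,
    train,
)


def test_cross_entropy_perfect_prediction_is_zero():
    p = np.array([0.0, 1.0, 0.0, 0.0])
    assert cross_entropy(p, p) == pytest.approx(0.0, abs=1e-9)


def test_cross_entropy_uniform_prediction_log4():
    p = np.array([1.0, 0.0, 0.0, 0.0])
    q = np.full(4, 0.25)
    assert cross_entropy(q, p) == pytest.approx(np.log(4), abs=1e-9)


def test_cross_entropy_epsilon_floor_keeps_loss_finite():
    p = np.array([1.0, 0.0])
    q = np.array([0.0, 1.0])
    loss = cross_entropy(q, p)
    assert np.isfinite(loss) and loss > 20  # -log(1e-12) ~ 27.6


def test_gibbs_inequality_on_random_distributions():
    rng = np.random.default_rng(17)
    for _ in range(200):
        p = rng.dirichlet(np.ones(4))
        q = rng.dirichlet(np.ones(4))
        assert cross_entropy(q, p) >= cross_entropy(p, p) - 1e-9


def test_cross_entropy_validates_inputs():
    with pytest.raises(ValueError):
        cross_entropy(np.array([0.5, 0.6]), np.array([0.5, 0.5]))
    with pytest.raises(ValueError):
        cross_entropy(np.array([0.5, 0.5]), np.array([-0.5, 1.5]))


def test_softmax_cross_entropy_gradient_is_q_minus_p():
    logits = np.array([[1.0, 2.0, 0.5, -1.0]], dtype=np.float32)
    labels = np.array([2])
    loss, grad = softmax_cross_entropy(logits, labels)
    q = softmax(logits)
    expected = q.copy()
    expected[0, 2] -= 1.0
    assert np.allclose(grad, expected, atol=1e-6)
    assert loss == pytest.approx(-np.log(q[0, 2]), rel=1e-5)


def test_zero_lr_adam_leaves_weights_unchanged():
    net = build_network(ModelConfig(sr=0.05, num_classes=2), seed=0)
    params = net.parameters()
    before = [p.value.copy() for p in params]
    opt = Adam(params, lr=0.0)
    x = np.random.default_rng(0).uniform(-1, 1, (2, 3, 224, 224)).astype(np.float32)
    logits = net.forward(x, training=True)
    _, g = softmax_cross_entropy(logits, np.array([0, 1]))
    net.backward(g)
    opt.step()
    for b, p in zip(before, params):
        assert np.array_equal(b, p.value)


def test_every_parameter_group_receives_gradient():
    net = build_network(ModelConfig(sr=0.1, num_classes=3), seed=2)
    x = np.random.default_rng(3).uniform(-1, 1, (3, 3, 224, 224)).astype(np.float32)
    logits = net.forward(x, training=True)
    _, g = softmax_cross_entropy(logits, np.array([0, 1, 2]))
    net.zero_grad()
    net.backward(g)
    for p in net.parameters():
        assert np.abs(p.grad).max() > 0, "dead parameter group"


def _tiny_batches(tiny_dataset):
    batch, _ = tiny_dataset
    idx = np.arange(len(batch))
    return batch.subset(idx[: len(idx) // 2]), batch.subset(idx[len(idx) // 2 :])


def test_same_seed_gives_identical_first_epoch(tiny_dataset):
    train_b, val_b = _tiny_batches(tiny_dataset)
    tc = TrainConfig(epochs=1, batch_size=8, seed=31)
    histories = []
    for _ in range(2):
        net = build_network(ModelConfig(sr=0.05, num_classes=4), seed=tc.seed)
        histories.append(train(net, train_b, val_b, tc))
    assert histories[0].epochs[0].train_loss == histories[1].epochs[0].train_loss
    assert histories[0].epochs[0].val_accuracy == histories[1].epochs[0].val_accuracy


def test_train_rejects_empty_and_mismatched_data(tiny_dataset):
    train_b, val_b = _tiny_batches(tiny_dataset)
    net = build_network(ModelConfig(sr=0.05, num_classes=7), seed=0)
    with pytest.raises(ValueError):
        train(net, train_b, val_b, TrainConfig(epochs=1))
    empty = train_b.subset(np.array([], dtype=int))
    net4 = build_network(ModelConfig(sr=0.05, num_classes=4), seed=0)
    with pytest.raises(ValueError):
        train(net4, empty, val_b, TrainConfig(epochs=1))


def test_evaluate_returns_report(tiny_dataset):
    batch, _ = tiny_dataset
    net = build_network(ModelConfig(sr=0.05, num_classes=4), seed=0)
    rep = evaluate(net, batch)
    assert 0.0 <= rep.accuracy <= 1.0
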