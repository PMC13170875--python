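"""Joint model: loss primitives, fusion, aggregation, training contract."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crisisdetect import (
    ModelConfig,
    aggregate_segments,
    classification_loss,
    fit,
    gated_fusion,
    label_bce,
    predict_labels,
    predict_proba,
    reconstruction_loss,
    total_loss,
)
from crisisdetect.model import _batch_loss, _Network, BCE_CLIP
from crisisdetect.nn import Adam, Tensor

# --------------------------------------------------------------------------
# loss primitives (hand-computable oracles)


def test_reconstruction_loss_cases(rng):
    assert reconstruction_loss([[1.0, 2.0]], [[1.0, 2.0]]) == 0.0
    # one sample, two dims, unit error in each -> summed squared error 2
    assert reconstruction_loss([[1.0, 1.0]], [[0.0, 0.0]]) == pytest.approx(2.0)
    # batch-mean invariance under sample duplication
    a = rng.standard_normal((4, 6))
    b = rng.standard_normal((4, 6))
    base = reconstruction_loss(a, b)
    doubled = reconstruction_loss(np.vstack([a, a]), np.vstack([b, b]))
    assert doubled == pytest.approx(base)


def test_reconstruction_loss_shape_mismatch():
    with pytest.raises(ValueError):
        reconstruction_loss(np.zeros((2, 3)), np.zeros((2, 4)))


def test_label_bce_cases():
    assert label_bce([1.0], [0.5]) == pytest.approx(np.log(2.0), abs=1e-12)
    # perfect prediction collapses to the clip floor
    assert label_bce([1.0, 0.0], [1.0, 0.0]) == pytest.approx(-np.log(1 - BCE_CLIP), abs=1e-9)
    with pytest.raises(ValueError):
        label_bce([1.0], [1.2])


@given(
    y=st.lists(st.integers(0, 1), min_size=1, max_size=8),
    p=st.lists(st.floats(0.01, 0.99), min_size=8, max_size=8),
)
@settings(deadline=None, derandomize=True)
def test_label_bce_complement_symmetry(y, p):
    y = np.array(y, dtype=float)
    p = np.array(p[: len(y)], dtype=float)
    assert label_bce(y, p) == pytest.approx(label_bce(1 - y, 1 - p), rel=1e-12)


@pytest.mark.parametrize(
    "losses, gamma, expected",
    [
        ((1.0, 2.0, 3.0, 4.0), (1, 1, 1, 1), 10.0),
        ((1.0, 2.0, 3.0, 4.0), (0, 0, 0, 0), 0.0),
        ((1.0, 2.0, 3.0, 4.0), (1, 0.5, 0, 2), 10.0),
    ],
)
def test_classification_loss(losses, gamma, expected):
    assert classification_loss(losses, gamma) == pytest.approx(expected)


def test_classification_loss_requires_four():
    with pytest.raises(ValueError):
        classification_loss([1.0, 2.0], [1, 1])


def test_total_loss_cases():
    assert total_loss(2.0, 1.0, 1.0, 0.8) == pytest.approx(2.8)
    assert total_loss(3.0, 7.0, 1.0, 0.0) == pytest.approx(3.0)
    assert total_loss(3.0, 7.0, 0.0, 1.0) == pytest.approx(7.0)
    with pytest.raises(ValueError):
        total_loss(1.0, 1.0, -0.1, 0.8)


# --------------------------------------------------------------------------
# gated fusion


def test_gated_fusion_boundaries(rng):
    z_t = rng.standard_normal(6)
    z_a = rng.standard_normal(6)
    np.testing.assert_array_equal(gated_fusion(z_t, z_a, 1.0)[0], z_t)
    np.testing.assert_array_equal(gated_fusion(z_t, z_a, 0.0)[0], z_a)
    z, a = gated_fusion([1.0, 0.0], [0.0, 1.0], 0.5)
    np.testing.assert_allclose(z, [0.5, 0.5])
    assert a == 0.5


def test_gated_fusion_validation():
    with pytest.raises(ValueError):
        gated_fusion([1.0, 2.0], [1.0], 0.5)
    with pytest.raises(ValueError):
        gated_fusion([1.0], [1.0], 1.5)


# --------------------------------------------------------------------------
# segment aggregation


def test_aggregate_mean_cases():
    seg = np.array([[3.0, -1.0]])
    np.testing.assert_array_equal(aggregate_segments(seg, "mean"), seg[0])
    np.testing.assert_allclose(
        aggregate_segments([[1.0, 0.0], [0.0, 1.0]], "mean"), [0.5, 0.5]
    )


def test_aggregation_order_sensitivity(rng):
    segs = rng.standard_normal((3, 8))
    perm = segs[[2, 0, 1]]
    np.testing.assert_allclose(
        aggregate_segments(segs, "mean"), aggregate_segments(perm, "mean")
    )
    out = aggregate_segments(segs, "birnn", seed=0)
    out_perm = aggregate_segments(perm, "birnn", seed=0)
    assert out.shape == out_perm.shape
    assert not np.allclose(out, out_perm)


def test_aggregate_rejects_bad_input():
    with pytest.raises(ValueError):
        aggregate_segments(np.empty((0, 4)), "mean")
    with pytest.raises(ValueError):
        aggregate_segments([[1.0, 2.0]], "median")


# --------------------------------------------------------------------------
# training contract


def _tiny_data(rng, n=48, d=8):
    X = rng.standard_normal((n, d))
    y = (rng.random((n, 4)) < 0.5).astype(float)
    return X, y


def test_loss_decomposition_matches_primitives(rng):
    """The training-graph loss equals lambda1*L_rec + lambda2*sum gamma_j*BCE_j
    recomputed with the public numpy primitives."""
    cfg = ModelConfig(input_dim=8, encoder_hidden=6, latent_dim=4,
                      classifier_hidden=5, gamma=(1.0, 0.5, 2.0, 1.0),
                      lambda1=1.0, lambda2=0.8, seed=0)
    net = _Network(cfg, "text_only")
    X, y = _tiny_data(rng)
    graph_loss = float(_batch_loss(net, Tensor(X), None, y, cfg).data)

    probs, recons, _ = net.forward(Tensor(X), None)
    l_rec = reconstruction_loss(recons[0][0].data, X)
    per_label = [label_bce(y[:, j], probs.data[:, j]) for j in range(4)]
    l_clf = classification_loss(per_label, cfg.gamma)
    assert graph_loss == pytest.approx(total_loss(l_rec, l_clf, cfg.lambda1, cfg.lambda2), abs=1e-6)


def test_one_small_step_decreases_loss(rng):
    cfg = ModelConfig(input_dim=8, encoder_hidden=6, latent_dim=4, seed=1)
    net = _Network(cfg, "text_only")
    X, y = _tiny_data(rng, n=16)
    opt = Adam(net.params(), lr=1e-5)
    loss0 = _batch_loss(net, Tensor(X), None, y, cfg)
    opt.zero_grad()
    loss0.backward()
    opt.step()
    loss1 = _batch_loss(net, Tensor(X), None, y, cfg)
    assert float(loss1.data) < float(loss0.data)


def test_early_stopping_on_flat_validation(rng):
    # zero learning rate freezes the network, so validation loss is constant
    # from epoch 1 and training must stop after exactly 1 + patience epochs
    X, y = _tiny_data(rng)
    cfg = ModelConfig(input_dim=8, encoder_hidden=6, latent_dim=4,
                      learning_rate=0.0, max_epochs=50, patience=5, seed=2)
    model = fit((X, y), (X, y), cfg, "text_only")
    assert model.stopped_epoch == 1 + cfg.patience
    assert len(model.history["val_loss"]) == model.stopped_epoch


def test_runs_to_max_epochs_when_patience_never_triggers(rng):
    X, y = _tiny_data(rng)
    cfg = ModelConfig(input_dim=8, encoder_hidden=6, latent_dim=4,
                      max_epochs=8, patience=40, seed=3)
    model = fit((X, y), (X, y), cfg, "text_only")
    assert model.stopped_epoch == cfg.max_epochs
    assert len(model.history["train_loss"]) == cfg.max_epochs


def test_fit_rejects_bad_input(rng):
    X, y = _tiny_data(rng)
    cfg = ModelConfig(input_dim=8, encoder_hidden=6, latent_dim=4)
    with pytest.raises(ValueError):
        fit((X[:0], y[:0]), (X, y), cfg, "text_only")
    with pytest.raises(ValueError):
        fit((X, y), (X, y), cfg, "holographic")
    with pytest.raises(ValueError):
        fit((X, y[:, :2]), (X, y), cfg, "text_only")


def test_fit_deterministic_given_seed(rng):
    X, y = _tiny_data(rng)
    cfg = ModelConfig(input_dim=8, encoder_hidden=6, latent_dim=4,
                      max_epochs=5, patience=40, seed=9)
    m1 = fit((X, y), (X, y), cfg, "text_only")
    m2 = fit((X, y), (X, y), cfg, "text_only")
    assert m1.history == m2.history
    np.testing.assert_array_equal(predict_proba(m1, X), predict_proba(m2, X))


# --------------------------------------------------------------------------
# prediction


def test_predict_labels_matches_bruteforce(rng):
    probs = rng.random((100, 4))
    labels = predict_labels(probs, 0.5)
    expected = np.array([[1 if p >= 0.5 else 0 for p in row] for row in probs])
    np.testing.assert_array_equal(labels, expected)


def test_predict_labels_boundaries():
    probs = np.full((1, 4), 0.5)
    np.testing.assert_array_equal(predict_labels(probs, 0.5), np.ones((1, 4), dtype=int))
    probs = np.full((2, 4), 0.99)
    np.testing.assert_array_equal(predict_labels(probs, 0.999), np.zeros((2, 4), dtype=int))
    with pytest.raises(ValueError):
        predict_labels(np.array([[1.2, 0.5, 0.5, 0.5]]))


def test_predict_proba_validates_dim(rng):
    X, y = _tiny_data(rng)
    cfg = ModelConfig(input_dim=8, encoder_hidden=6, latent_dim=4,
                      max_epochs=2, patience=40, seed=4)
    model = fit((X, y), (X, y), cfg, "text_only")
    probs = predict_proba(model, X)
    assert probs.shape == (len(X), 4)
    assert np.all((probs >= 0) & (probs <= 1))
    with pytest.raises(ValueError):
        predict_proba(model, np.zeros((3, 5)))
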