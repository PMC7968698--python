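"""Architecture contracts: output probabilities, shape chain, determinism."""

import numpy as np
import pytest

from trapnet.capsule import dynamic_routing, predict_vectors, squash
from trapnet.models import (
    HyperParams,
    TrapClassifier,
    TrainingResult,
    _CapsNet,
    build_capsnet,
    build_cnn2,
    build_cnn13,
    n_parameters,
    predict,
    train,
)
from trapnet.nnet import Tensor


SMALL_CNN2 = build_cnn2((4, 8), dense=16)
SMALL_CNN13 = build_cnn13((4,) * 13)
SMALL_CAPS = build_capsnet(conv1_channels=4, primary_capsule_types=2,
                           decoder_widths=(16, 32))


@pytest.fixture(scope="module")
def tiny_fit(small_easy_dataset_module):
    hp = HyperParams(epochs=1, batch_size=16, seed=0)
    return train(SMALL_CNN2, small_easy_dataset_module, hp)


@pytest.fixture(scope="module")
def small_easy_dataset_module():
    from trapnet.labels import CATEGORIES_5
    from trapnet.synthetic import SceneParams, generate_dataset

    return generate_dataset({c: 12 for c in CATEGORIES_5}, SceneParams.easy(),
                            seed=21)


@pytest.mark.parametrize("spec", [SMALL_CNN2, SMALL_CNN13, SMALL_CAPS],
                         ids=["cnn2", "cnn13", "capsnet"])
def test_forward_probability_contract(spec, rng):
    from trapnet.models import _build_network

    net = _build_network(spec, np.random.default_rng(0))
    x = rng.random((3, 1, 60, 60)).astype(np.float32)
    probs = net.forward(Tensor(x), False, HyperParams()).data
    assert probs.shape == (3, 5)
    assert np.all(probs >= 0)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)


def test_capsnet_shape_chain_invariant():
    spec = build_capsnet()
    chain = spec.shape_chain
    assert chain["conv1_side"] == 52               # (60 - 9)/1 + 1
    assert chain["primary_grid_side"] == 22        # (52 - 9)/2 + 1
    assert chain["primary_grid_side"] == ((60 - 9) // 1 + 1 - 9) // 2 + 1
    assert chain["primary_capsule_types"] == 32
    assert chain["primary_capsule_dim"] == 8
    assert chain["n_primary_capsules"] == 22 * 22 * 32
    assert chain["class_capsule_dim"] == 16
    assert chain["n_class_capsules"] == 5


def test_capsnet_forward_grid_matches_arithmetic(rng):
    """An actual forward pass produces the 22x22 primary grid the valid
    convolution arithmetic predicts."""
    net = _CapsNet(SMALL_CAPS, np.random.default_rng(0))
    x = Tensor(rng.random((2, 1, 60, 60)).astype(np.float32))
    h = net.conv1(x).relu()
    assert h.shape[2:] == (52, 52)
    h2 = net.conv2(h)
    assert h2.shape[2:] == (22, 22)
    v = net.class_capsules(x, HyperParams(routing_iterations=2))
    assert v.shape == (2, 5, 16)
    lengths = np.linalg.norm(v.data, axis=-1)
    assert np.all(lengths < 1.0)


def test_capsnet_probs_are_normalized_lengths(rng):
    net = _CapsNet(SMALL_CAPS, np.random.default_rng(0))
    hp = HyperParams(routing_iterations=2)
    x = Tensor(rng.random((2, 1, 60, 60)).astype(np.float32))
    v = net.class_capsules(x, hp).data
    lengths = np.sqrt((v ** 2).sum(axis=-1) + 1e-12)
    probs = net.forward(x, False, hp).data
    np.testing.assert_allclose(probs, lengths / lengths.sum(axis=1, keepdims=True),
                               atol=1e-6)


def test_capsnet_layer_routing_matches_reference(rng):
    """The network's in-graph routing agrees with the standalone capsule
    math on the same prediction vectors."""
    net = _CapsNet(SMALL_CAPS, np.random.default_rng(3))
    hp = HyperParams(routing_iterations=3)
    x = Tensor(rng.random((1, 1, 60, 60)).astype(np.float32))
    v_net = net.class_capsules(x, hp).data[0]
    # rebuild u_hat outside the graph with the reference primitives
    h = net.conv1(x).relu()
    h2 = net.conv2(h)
    t, d = 2, 8
    u = (h2.data.reshape(1, t, d, 22 * 22).transpose(0, 1, 3, 2)
         .reshape(net.n_caps, d))
    u = squash(u, axis=-1)
    w = net.w.data.reshape(net.n_caps, d, 5, 16).transpose(0, 2, 3, 1)
    u_hat = predict_vectors(w, u)
    _, v_ref = dynamic_routing(u_hat, iterations=3)
    np.testing.assert_allclose(v_net, v_ref, atol=1e-5)


def test_parameter_count_ordering():
    assert n_parameters(build_cnn2()) < n_parameters(build_cnn13())


def test_fit_and_predict_contracts(tiny_fit, small_easy_dataset_module):
    ds = small_easy_dataset_module
    assert 0.0 <= tiny_fit.validation_accuracy <= 1.0
    assert len(tiny_fit.history) == 1
    probs = predict(tiny_fit, ds.split("test").images)
    assert probs.shape == (len(ds.split("test")), 5)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
    # batch order is preserved
    one_by_one = np.vstack([predict(tiny_fit, ds.split("test").images[i:i + 1])
                            for i in range(3)])
    np.testing.assert_allclose(probs[:3], one_by_one, atol=1e-6)
    assert "cnn2" in tiny_fit.summary()


def test_fit_rejects_empty_validation(small_easy_dataset_module):
    ds = small_easy_dataset_module
    train_only = ds.take(np.flatnonzero(ds.manifest["split"] == "train"))
    clf = TrapClassifier(SMALL_CNN2, train_only)
    with pytest.raises(ValueError, match="validation"):
        clf.fit(HyperParams(epochs=1))


def test_same_seed_same_first_epoch_loss(small_easy_dataset_module):
    hp = HyperParams(epochs=1, batch_size=16, seed=5)
    a = train(SMALL_CNN2, small_easy_dataset_module, hp)
    b = train(SMALL_CNN2, small_easy_dataset_module, hp)
    assert a.history["loss"].iloc[0] == b.history["loss"].iloc[0]
    assert a.validation_accuracy == b.validation_accuracy


def test_wrong_image_shape_rejected(tiny_fit):
    with pytest.raises(ValueError):
        tiny_fit.predict(np.zeros((2, 61, 60)))


def test_bad_hyperparams_rejected():
    with pytest.raises(ValueError):
        HyperParams(learning_rate=0)
    with pytest.raises(ValueError):
        HyperParams(epochs=0)
    with pytest.raises(ValueError):
        HyperParams(routing_iterations=0)


def test_save_load_roundtrip(tmp_path, tiny_fit, small_easy_dataset_module):
    path = tmp_path / "model.npz"
    tiny_fit.save(path)
    back = TrainingResult.load(path)
    assert back.validation_accuracy == tiny_fit.validation_accuracy
    x = small_easy_dataset_module.images[:4]
    np.testing.assert_allclose(back.predict(x), tiny_fit.predict(x), atol=1e-6)


def test_capsnet_decoder_reconstructs_shape(rng, small_easy_dataset_module):
    ds = small_easy_dataset_module
    hp = HyperParams(epochs=1, batch_size=16, seed=0, routing_iterations=2)
    fit = train(SMALL_CAPS, ds, hp)
    x = ds.images[:3].astype(np.float32)[:, None]
    from trapnet.data import onehot
    from trapnet.labels import CATEGORIES_5

    recon = fit.network.reconstruct(Tensor(x), onehot(ds.labels[:3], CATEGORIES_5), hp)
    assert recon.shape == (3, 60, 60)
    assert recon.min() >= 0.0 and recon.max() <= 1.0
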