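"""Capsule math core vs brute-force loop oracles.

Oracles here are written deliberately without vectorized shortcuts: plain
Python loops over capsules, parents and vector components.
"""

import math

import numpy as np
import pytest

from trapnet.capsule import dynamic_routing, predict_vectors, squash


# -- oracles ------------------------------------------------------------------

def squash_oracle(vec):
    n2 = sum(x * x for x in vec)
    n = math.sqrt(n2) + 1e-300
    return [(n2 / (1 + n2)) * (x / n) for x in vec]


def predict_oracle(w, u):
    n_in, n_out, d_out, d_in = w.shape
    out = np.zeros((n_in, n_out, d_out))
    for i in range(n_in):
        for j in range(n_out):
            for k in range(d_out):
                out[i, j, k] = sum(w[i, j, k, l] * u[i, l] for l in range(d_in))
    return out


def routing_oracle(u_hat, iterations):
    n_in, n_out, d = u_hat.shape
    b = np.zeros((n_in, n_out))
    for it in range(iterations):
        c = np.zeros_like(b)
        for i in range(n_in):
            exps = [math.exp(b[i, j] - max(b[i])) for j in range(n_out)]
            tot = sum(exps)
            for j in range(n_out):
                c[i, j] = exps[j] / tot
        v = np.zeros((n_out, d))
        for j in range(n_out):
            s = [sum(c[i, j] * u_hat[i, j, k] for i in range(n_in)) for k in range(d)]
            v[j] = squash_oracle(s)
        if it < iterations - 1:
            for i in range(n_in):
                for j in range(n_out):
                    b[i, j] += sum(u_hat[i, j, k] * v[j, k] for k in range(d))
    return c, v


# -- squash -------------------------------------------------------------------

def test_squash_zero_maps_to_zero():
    np.testing.assert_array_equal(squash(np.zeros(4)), np.zeros(4))


def test_squash_3_4_vector_hand_value():
    # |s| = 5 so the factor is 25/26/5 and |v| = 25/26
    v = squash(np.array([3.0, 4.0]))
    np.testing.assert_allclose(v, [25 / 26 * 3 / 5, 25 / 26 * 4 / 5], atol=1e-12)
    assert np.linalg.norm(v) == pytest.approx(25 / 26, abs=1e-12)


def test_squash_length_monotone_to_one():
    u = np.array([1.0, 0.0, 0.0])
    lengths = [np.linalg.norm(squash(t * u)) for t in (0.5, 1, 2, 10, 100, 1e4)]
    assert all(b > a for a, b in zip(lengths, lengths[1:]))
    assert all(l < 1.0 for l in lengths)
    assert lengths[-1] > 0.999


def test_squash_preserves_direction(rng):
    s = rng.normal(size=7)
    v = squash(s)
    cos = v @ s / (np.linalg.norm(v) * np.linalg.norm(s))
    assert cos == pytest.approx(1.0, abs=1e-12)


def test_squash_rejects_nonfinite():
    with pytest.raises(ValueError):
        squash(np.array([1.0, np.nan]))


# -- prediction vectors -------------------------------------------------------

def test_predict_identity_and_scaling():
    u = np.array([[1.0, -1.0]])
    w = np.eye(2)[None, None, :, :]
    np.testing.assert_array_equal(predict_vectors(w, u)[0, 0], u[0])
    np.testing.assert_array_equal(predict_vectors(2 * w, u)[0, 0], [2.0, -2.0])


def test_predict_matches_loop_oracle(rng):
    w = rng.normal(size=(4, 3, 16, 8))
    u = rng.normal(size=(4, 8))
    np.testing.assert_allclose(predict_vectors(w, u), predict_oracle(w, u),
                               atol=1e-12)


def test_predict_rejects_mismatch(rng):
    with pytest.raises(ValueError):
        predict_vectors(rng.normal(size=(4, 3, 16, 8)), rng.normal(size=(4, 9)))


# -- dynamic routing ----------------------------------------------------------

def test_single_parent_couplings_are_one(rng):
    u_hat = rng.normal(size=(5, 1, 4))
    for iterations in (1, 2, 4):
        c, _ = dynamic_routing(u_hat, iterations)
        np.testing.assert_allclose(c, 1.0, atol=1e-12)


def test_one_iteration_equals_uniform_closed_form(rng):
    u_hat = rng.normal(size=(4, 3, 4))
    c, v = dynamic_routing(u_hat, iterations=1)
    np.testing.assert_allclose(c, 1.0 / 3.0, atol=1e-15)
    s = u_hat.mean(axis=0) * 4 / 3  # sum_i (1/3) u_hat[i,j]
    expect = np.array([squash_oracle(s[j]) for j in range(3)])
    np.testing.assert_allclose(v, expect, atol=1e-10)


@pytest.mark.parametrize("shape,iters", [
    ((2, 2, 2), 1), ((3, 2, 4), 2), ((4, 3, 4), 3), ((4, 3, 3), 5),
])
def test_routing_matches_loop_oracle(shape, iters, rng):
    u_hat = rng.normal(size=shape)
    c, v = dynamic_routing(u_hat, iters)
    co, vo = routing_oracle(u_hat, iters)
    np.testing.assert_allclose(c, co, atol=1e-10)
    np.testing.assert_allclose(v, vo, atol=1e-10)
    np.testing.assert_allclose(c.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(np.linalg.norm(v, axis=-1) < 1.0)


def test_consensus_parent_coupling_grows():
    """When every input predicts the same vector for parent 0 and noise for
    parent 1, coupling to parent 0 rises monotonically with iterations."""
    n_in, d = 4, 3
    u_hat = np.zeros((n_in, 2, d))
    u_hat[:, 0, :] = [1.0, 0.0, 0.0]
    rng = np.random.default_rng(7)
    u_hat[:, 1, :] = rng.normal(scale=0.3, size=(n_in, d))
    prev = None
    for iters in (1, 2, 3, 4):
        c, _ = dynamic_routing(u_hat, iters)
        mean_c0 = c[:, 0].mean()
        if prev is not None:
            assert mean_c0 > prev
        prev = mean_c0


def test_routing_rejects_bad_iterations(rng):
    with pytest.raises(ValueError):
        dynamic_routing(rng.normal(size=(2, 2, 2)), 0)
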