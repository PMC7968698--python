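"""Capsule-network mathematical core: squash, prediction vectors, routing.

A capsule is a group of neurons whose joint activity is a vector: the
vector's length encodes the probability that the feature the capsule
represents is present, and its orientation encodes the feature's pose.
Three primitives connect a layer of input capsules i to a layer of parent
capsules j:

* ``squash`` — the nonlinearity ``v = (|s|^2 / (1 + |s|^2)) * s / |s|``
  mapping any vector's length into [0, 1) while preserving its direction;
* ``predict_vectors`` — the affine predictions ``u_hat[j|i] = W[i,j] @ u[i]``
  each input capsule makes for each parent;
* ``dynamic_routing`` — an agreement-driven reweighting: coupling
  coefficients ``c[i,j] = softmax_j(b[i,j])`` mix the predictions into
  ``s[j] = sum_i c[i,j] u_hat[j|i]``, parents are squashed to ``v[j]``, and
  the routing logits grow by the dot-product agreement ``u_hat[j|i] . v[j]``
  so that predictions pointing with the consensus gain coupling.

These functions are pure NumPy and operate on single capsule layers; the
network layers in :mod:`trapnet.models` reuse the same arithmetic inside the
autodiff graph.
"""

from __future__ import annotations

import numpy as np

from scipy.special import softmax

_EPS = 1e-12  # guards the norm in squash against division by zero


def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Squash vectors along ``axis`` to length < 1, preserving direction.

    ``v = (|s|^2 / (1 + |s|^2)) * s / |s|``; the zero vector maps to itself.
    """
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("squash input must be finite")
    sq = np.sum(s * s, axis=axis, keepdims=True)
    norm = np.sqrt(sq + _EPS)
    return (sq / (1.0 + sq)) * s / norm


def predict_vectors(w: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Affine prediction vectors ``u_hat[i, j] = w[i, j] @ u[i]``.

    Parameters
    ----------
    w : array (n_in, n_out, d_out, d_in)
        Per-(input, parent) affine weight matrices.
    u : array (n_in, d_in)
        Output vectors of the lower capsule layer.

    Returns
    -------
    array (n_in, n_out, d_out)
    """
    w = np.asarray(w, dtype=float)
    u = np.asarray(u, dtype=float)
    if w.ndim != 4 or u.ndim != 2 or w.shape[0] != u.shape[0] or w.shape[3] != u.shape[1]:
        raise ValueError(
            f"non-conformable shapes: w {w.shape}, u {u.shape} "
            "(expected (n_in, n_out, d_out, d_in) and (n_in, d_in))"
        )
    return np.einsum("ijkl,il->ijk", w, u)


def dynamic_routing(
    u_hat: np.ndarray, iterations: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Route prediction vectors to parent capsules by iterative agreement.

    Logits ``b`` start at zero, so the first pass mixes predictions
    uniformly over parents.  Each iteration computes couplings
    ``c = softmax_j(b)``, parent inputs ``s[j] = sum_i c[i,j] u_hat[i,j]``
    and outputs ``v[j] = squash(s[j])``; on all but the final iteration the
    logits accumulate the agreement ``b[i,j] += u_hat[i,j] . v[j]``.

    Parameters
    ----------
    u_hat : array (n_in, n_out, d_out)
        Prediction vectors from :func:`predict_vectors`.
    iterations : int
        Number of routing passes, >= 1.

    Returns
    -------
    (c, v) : arrays (n_in, n_out) and (n_out, d_out)
        Final coupling coefficients (rows sum to 1) and parent outputs.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    if u_hat.ndim != 3:
        raise ValueError(f"u_hat must be (n_in, n_out, d_out), got {u_hat.shape}")
    if iterations < 1:
        raise ValueError("routing needs at least one iteration")
    n_in, n_out, _ = u_hat.shape
    b = np.zeros((n_in, n_out))
    for it in range(iterations):
        c = softmax(b, axis=1)
        s = np.einsum("ij,ijk->jk", c, u_hat)
        v = squash(s, axis=-1)
        if it < iterations - 1:
            b = b + np.einsum("ijk,jk->ij", u_hat, v)
    return c, v
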