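"""Neural-network layers and the Adam optimizer on top of the autodiff core.

Layers hold their parameters as ``Tensor`` objects and expose
``__call__(x, train)``; ``train`` switches batch-statistics and dropout
behaviour.  All randomness (initialization, dropout masks) flows through a
``numpy.random.Generator`` supplied by the caller, so training is
reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, batchnorm_train, conv2d, maxpool2d, softmax


class Layer:
    def parameters(self) -> list[Tensor]:
        return []

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3/9x9-style convolution, NCHW; He-normal weight init."""

    def __init__(self, c_in, c_out, k, stride=1, pad=0, rng=None, bias=True):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = Tensor(
            rng.normal(0.0, scale, (c_out, c_in, k, k)).astype(np.float32),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(c_out, np.float32), requires_grad=True) if bias else None
        self.stride, self.pad = stride, pad

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def __call__(self, x, train=False):
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        scale = np.sqrt(2.0 / n_in)
        self.w = Tensor(
            rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(n_out, np.float32), requires_grad=True)

    def parameters(self):
        return [self.w, self.b]

    def __call__(self, x, train=False):
        return x @ self.w + self.b


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial dims for 4-D input).

    Training uses batch statistics inside the graph and tracks exponential
    running averages; :meth:`start_accumulate` / :meth:`finish_accumulate`
    replace those averages with exact population statistics over whatever
    batches are pushed through between the two calls (a post-training
    calibration pass with the final weights), which evaluation then uses
    as constants.
    """

    def __init__(self, n_ch, momentum=0.9, eps=1e-5):
        self.gamma = Tensor(np.ones(n_ch, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch, np.float32), requires_grad=True)
        self.running_mean = np.zeros(n_ch, np.float32)
        self.running_var = np.ones(n_ch, np.float32)
        self.momentum, self.eps = momentum, eps
        self._acc = None

    def parameters(self):
        return [self.gamma, self.beta]

    def start_accumulate(self):
        self._acc = [0.0, 0.0, 0]  # sum, sum of squares, count (per channel)

    def finish_accumulate(self):
        s, ss, n = self._acc
        if n > 0:
            mean = s / n
            self.running_mean = mean.astype(np.float32)
            self.running_var = np.maximum(ss / n - mean ** 2, 0.0).astype(np.float32)
        self._acc = None

    def __call__(self, x, train=False):
        spatial = x.ndim == 4
        axes = (0, 2, 3) if spatial else (0,)
        shape = (1, -1, 1, 1) if spatial else (1, -1)
        if train:
            out, mu, var = batchnorm_train(x, self.gamma, self.beta, self.eps)
            if self._acc is not None:
                n = x.data.size // x.shape[1 if spatial else -1]
                self._acc[0] += x.data.sum(axis=axes).ravel().astype(np.float64)
                self._acc[1] += (x.data ** 2).sum(axis=axes).ravel().astype(np.float64)
                self._acc[2] += n
            else:
                m = self.momentum
                self.running_mean = (m * self.running_mean
                                     + (1 - m) * mu).astype(np.float32)
                self.running_var = (m * self.running_var
                                    + (1 - m) * var).astype(np.float32)
            return out
        mu = Tensor(self.running_mean.reshape(shape))
        var = Tensor(self.running_var.reshape(shape))
        xn = (x - mu) / ((var + self.eps) ** 0.5)
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p, rng):
        self.p, self.rng = p, rng
        self.enabled = True

    def __call__(self, x, train=False):
        if not train or not self.enabled or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / np.float32(1.0 - self.p)
        return x * Tensor(mask.astype(x.data.dtype))


class ReLU(Layer):
    def __call__(self, x, train=False):
        return x.relu()


class MaxPool(Layer):
    def __init__(self, k=2):
        self.k = k

    def __call__(self, x, train=False):
        return maxpool2d(x, self.k)


class Flatten(Layer):
    def __call__(self, x, train=False):
        return x.reshape(x.shape[0], -1)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def __call__(self, x, train=False):
        for l in self.layers:
            x = l(x, train=train)
        return x


def cross_entropy(probs: Tensor, onehot: np.ndarray, smoothing: float = 0.0,
                  eps: float = 1e-12) -> Tensor:
    """Mean categorical cross-entropy of predicted probabilities.

    ``smoothing`` mixes the targets with the uniform distribution
    ((1-s)*y + s/K), which keeps the optimum at finite logits — on noisy or
    ambiguous labels plain one-hot targets push logits toward saturation.
    """
    y = np.asarray(onehot)
    if smoothing > 0:
        y = (1.0 - smoothing) * y + smoothing / y.shape[1]
    logp = (probs + eps).log()
    return -(logp * Tensor(y.astype(np.float32))).sum() * (1.0 / probs.shape[0])


def softmax_head(logits: Tensor) -> Tensor:
    return softmax(logits, axis=-1)


class Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(self, params: list[Tensor], lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8, clipnorm: float | None = 5.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clipnorm = clipnorm
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        if self.clipnorm is not None:
            total = np.sqrt(sum(
                float((p.grad ** 2).sum()) for p in self.params if p.grad is not None
            ))
            if total > self.clipnorm:
                scale = self.clipnorm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= scale
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
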