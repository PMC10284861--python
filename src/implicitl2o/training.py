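"""Jacobian-free backpropagation (JFB) training.

Standard backpropagation through an implicit model would store the derivative
graph of every fixed-point iteration — memory linear in the iteration count.
JFB instead runs the fixed-point phase with no derivative tracking and
backpropagates through a *single* final application of the model operator at
the approximate fixed point.  The resulting update is a preconditioned
gradient, and the derivative-graph size is constant in the number of
fixed-point steps.

A trainable model exposes the small protocol consumed here:

``param_arrays()``
    name -> ndarray of current weights.
``apply_param_arrays(arrays)``
    install updated weights (followed by ``project_params`` to restore
    constraints, e.g. nonnegative thresholds or spectral normalization).
``solve(D, tol, max_iter)``
    the untracked fixed-point phase (batched); returns an opaque state.
``traced_step(params, state, D)``
    one tracked application of the model operator at the state, using the
    autodiff Tensors in ``params``; returns the output Tensor.
``output_of(state)``
    the model output stored in a solver state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import autodiff as ad

__all__ = ["TrainConfig", "JfbResult", "jfb_forward", "train", "Adam"]


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    lr: float = 1e-3
    lr_decay: float = 1.0      # multiplicative per-epoch decay
    fp_tol: float = 1e-5
    fp_max_iter: int = 100
    seed: int = 0
    loss: str = "mse"

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.fp_max_iter) < 1:
            raise ValueError("epochs, batch_size and fp_max_iter must be positive")
        if self.lr <= 0 or self.fp_tol <= 0:
            raise ValueError("lr and fp_tol must be positive")
        if self.loss != "mse":
            raise ValueError(f"unsupported loss {self.loss!r}")


class JfbResult(NamedTuple):
    x_K: np.ndarray          # untracked approximate fixed point
    x_final: ad.Tensor       # one tracked step from x_K; holds the graph
    params: dict             # name -> Tensor leaf (gradients land here)
    state: object            # full solver state at x_K


def jfb_forward(model, d, cfg: TrainConfig) -> JfbResult:
    """Fixed-point phase without derivative tracking, then one tracked step.

    Derivative information exists only for the final application: the graph
    rooted at ``x_final`` contains a constant number of nodes no matter how
    many iterations ``solve`` took.
    """
    state = model.solve(d, cfg.fp_tol, cfg.fp_max_iter)
    params = {k: ad.param(v) for k, v in model.param_arrays().items()}
    x_final = model.traced_step(params, state, d)
    return JfbResult(x_K=model.output_of(state), x_final=x_final,
                     params=params, state=state)


class Adam:
    """Adam over a dict of named numpy parameters."""

    def __init__(self, shapes, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = {}
        for k, p in params.items():
            g = grads.get(k)
            if g is None:
                out[k] = p
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            out[k] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def _as_columns(dataset):
    """Accept an iterable of (d, x_target) pairs or a (D, X) array pair;
    return column-stacked (m, N) and (n, N) arrays."""
    if isinstance(dataset, tuple) and len(dataset) == 2 and \
            isinstance(dataset[0], np.ndarray):
        D, X = dataset
        return np.asarray(D, float), np.asarray(X, float)
    ds, xs = [], []
    for d, x in dataset:
        ds.append(np.asarray(d, float))
        xs.append(np.asarray(x, float))
    if not ds:
        raise ValueError("training dataset is empty")
    return np.stack(ds, axis=1), np.stack(xs, axis=1)


def train(model, dataset, cfg: TrainConfig):
    """JFB training loop with mean-squared-error loss and Adam.

    Deterministic given ``cfg.seed`` (batch shuffling uses a private
    generator; no global RNG is touched).  A diverging batch is skipped with
    a warning rather than aborting the run.  Returns ``(model, history)``
    where ``history`` holds per-epoch mean losses.
    """
    D, X = _as_columns(dataset)
    if D.shape[1] == 0:
        raise ValueError("training dataset is empty")
    n_samples = D.shape[1]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam({k: v.shape for k, v in model.param_arrays().items()}, lr=cfg.lr)
    history = []
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr * cfg.lr_decay ** epoch
        order = rng.permutation(n_samples)
        losses = []
        for start in range(0, n_samples, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            d_b, x_b = D[:, idx], X[:, idx]
            try:
                res = jfb_forward(model, d_b, cfg)
            except Exception as exc:  # divergence in the forward phase
                warnings.warn(f"skipping batch after forward failure: {exc}")
                continue
            loss = ad.mse(res.x_final, x_b)
            ad.backward(loss, seed=1.0)
            losses.append(float(loss.value))
            grads = {k: t.grad for k, t in res.params.items() if t.grad is not None}
            new = opt.step(model.param_arrays(), grads)
            model.apply_param_arrays(new)
            model.project_params()
        history.append(float(np.mean(losses)) if losses else float("nan"))
    return model, history
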