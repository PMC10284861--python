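"""Proximal and projection primitives.

These are the building blocks every iteration map in the package is composed
from: soft-thresholding (the prox of the l1 norm), Euclidean ball and box
projections, and a small learned proximal network used as a data-driven
regularizer.  All primitives are nonexpansive, which is what keeps the
composed fixed-point iterations convergent.
"""

from __future__ import annotations

import json

import numpy as np

from . import autodiff as ad

__all__ = [
    "shrink",
    "project_ball",
    "project_box",
    "prox_l1",
    "LearnedProx",
    "learned_prox_residual",
]


def shrink(x, theta):
    """Soft-threshold ``sign(x) * max(|x| - theta, 0)`` componentwise.

    ``sign(0)`` is taken as 0, which keeps the map continuous.
    """
    if theta < 0:
        raise ValueError("shrink threshold must be nonnegative")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - theta, 0.0)


def project_ball(w, center, delta):
    """Euclidean projection onto the closed ball ``B(center, delta)``.

    For 2-d input each column is projected onto the corresponding column of
    ``center`` (batch mode); ``delta`` may then be a scalar or per-column.
    """
    if np.any(np.asarray(delta) < 0):
        raise ValueError("ball radius must be nonnegative")
    w = np.asarray(w, dtype=float)
    center = np.asarray(center, dtype=float)
    if w.shape != center.shape:
        raise ValueError(f"dimension mismatch: {w.shape} vs {center.shape}")
    diff = w - center
    r = np.linalg.norm(diff, axis=0) if w.ndim == 2 else np.linalg.norm(diff)
    scale = np.where(r > delta, np.divide(delta, np.where(r > 0, r, 1.0)), 1.0)
    return center + scale * diff


def project_box(x, lo=0.0, hi=1.0):
    """Componentwise clamp onto ``[lo, hi]``."""
    if lo > hi:
        raise ValueError("box bounds require lo <= hi")
    return np.clip(np.asarray(x, dtype=float), lo, hi)


def prox_l1(x, weight):
    """Prox of ``weight * ||.||_1`` — identical to :func:`shrink`."""
    return shrink(x, weight)


class LearnedProx:
    """A data-driven proximal operator guaranteed 1-Lipschitz.

    The map is the average ``x -> 0.5*x + 0.5*g(x)`` with
    ``g(x) = V2 tanh(V1 x + b1) + b2`` and both affine layers spectrally
    normalized to unit norm, so ``g`` is 1-Lipschitz and the whole map is
    averaged with alpha = 1/2 — exactly the contract the fixed-point
    convergence theory needs.  ``V2`` is initialized to zero, so an untrained
    instance is the prox of the quadratic ``0.5*||.||^2`` (a gentle pull
    toward zero).
    """

    def __init__(self, dim, hidden=32, seed=0):
        rng = np.random.default_rng(seed)
        self.dim = int(dim)
        self.hidden = int(hidden)
        self.weights = {
            "V1": rng.standard_normal((hidden, dim)) / np.sqrt(dim),
            "b1": np.zeros(hidden),
            "V2": np.zeros((dim, hidden)),
            "b2": np.zeros(dim),
        }
        self.seed = int(seed)
        self.normalize()

    # -- spectral normalization -------------------------------------------
    def normalize(self):
        """Rescale both affine layers to spectral norm <= 1 (re-applied after
        every optimizer step so the 1-Lipschitz certificate survives
        training)."""
        for key in ("V1", "V2"):
            V = self.weights[key]
            if V.size:
                s = np.linalg.norm(V, 2)
                if s > 1.0:
                    self.weights[key] = V / s
        self.lipschitz_certified = True

    # -- application -------------------------------------------------------
    def apply(self, x):
        w = self.weights
        h = np.tanh(w["V1"] @ x + (w["b1"][:, None] if np.ndim(x) == 2 else w["b1"]))
        g = w["V2"] @ h + (w["b2"][:, None] if np.ndim(x) == 2 else w["b2"])
        return 0.5 * np.asarray(x, dtype=float) + 0.5 * g

    __call__ = apply

    def apply_traced(self, x, params):
        """The same map on autodiff nodes; ``params`` maps names to Tensors."""
        batched = (x.shape if isinstance(x, ad.Tensor) else np.shape(x))
        b1, b2 = params["b1"], params["b2"]
        if len(batched) == 2:
            b1 = ad.Tensor(b1.value[:, None], [(b1, lambda g: g.sum(axis=1))]) if isinstance(b1, ad.Tensor) else b1
            b2 = ad.Tensor(b2.value[:, None], [(b2, lambda g: g.sum(axis=1))]) if isinstance(b2, ad.Tensor) else b2
        h = ad.tanh(ad.add(ad.matvec(params["V1"], x), b1))
        g = ad.add(ad.matvec(params["V2"], h), b2)
        return ad.add(ad.scale(x, 0.5), ad.scale(g, 0.5))

    # -- serialization -----------------------------------------------------
    def save(self, path):
        """Plain-text checkpoint: JSON manifest line + flattened weights."""
        manifest = {
            "dim": self.dim,
            "hidden": self.hidden,
            "seed": self.seed,
            "spectral_norm": self.lipschitz_certified,
            "keys": list(self.weights),
        }
        with open(path, "w") as fh:
            fh.write(json.dumps(manifest) + "\n")
            for key in self.weights:
                flat = self.weights[key].ravel()
                fh.write(" ".join(repr(float(v)) for v in flat) + "\n")

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            manifest = json.loads(fh.readline())
            prox = cls(manifest["dim"], manifest["hidden"], manifest["seed"])
            for key in manifest["keys"]:
                vals = np.array([float(v) for v in fh.readline().split()])
                prox.weights[key] = vals.reshape(prox.weights[key].shape)
        prox.normalize()
        return prox


def learned_prox_residual(x, prox):
    """``||x - prox(x)||`` — zero iff ``x`` is a fixed point of the learned
    proximal, i.e. a local minimizer of the data-driven regularizer."""
    x = np.asarray(x, dtype=float)
    out = prox.apply(x) if hasattr(prox, "apply") else prox(x)
    return float(np.linalg.norm(x - out))
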