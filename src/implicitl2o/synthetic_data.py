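"""Synthetic data emulating the two study settings.

* Dictionary recovery: hidden sparse codes ``s`` in R^r mapped through a
  fixed transform ``M`` into signals ``x = M s`` in R^n, observed through an
  under-determined Gaussian measurement matrix ``A`` (m < n) as ``d = A x``.
  Full-scale defaults n=250, r=50, m=100.
* Sparse-angle CT: random-ellipse phantoms in [0,1], parallel-beam sinograms,
  and per-beam multiplicative Gaussian noise at a configured relative level
  (default 1.5%).  Presets: "full" (128 px, 30 angles, 183 beams) and
  "desk" (32 px, 10 angles, 47 beams).

Everything is generated from explicit seeds; no downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .linops import RadonGeometry, build_radon_map

__all__ = [
    "DictionaryInstance",
    "CtInstance",
    "CT_PRESETS",
    "generate_dictionary_dataset",
    "generate_phantom",
    "add_beam_noise",
    "generate_ct_dataset",
]

#: default number of nonzeros in a hidden code (10% of the full-scale r=50)
DEFAULT_SPARSITY = 5

CT_PRESETS = {
    "full": RadonGeometry(128, 30, 183),
    "desk": RadonGeometry(32, 10, 47),
}


@dataclass
class DictionaryInstance:
    M: np.ndarray        # (n, r) hidden transform (shared across a dataset)
    s_true: np.ndarray   # (r,) sparse code
    x_true: np.ndarray   # (n,) = M @ s_true
    A: np.ndarray        # (m, n) measurement matrix (shared)
    d: np.ndarray        # (m,) = A @ x_true


@dataclass
class CtInstance:
    phantom: np.ndarray          # (side, side), values in [0,1]
    sinogram_clean: np.ndarray   # (n_rays,)
    sinogram_noisy: np.ndarray
    geometry: RadonGeometry
    noise_level: float


def generate_dictionary_dataset(n=250, r=50, m=100, sparsity=DEFAULT_SPARSITY,
                                count=100, seed=0) -> List[DictionaryInstance]:
    """One (M, A) pair per dataset, fresh sparse codes per instance.

    ``M`` has unit-norm Gaussian columns; ``A`` has N(0, 1/m) entries (the
    standard compressed-sensing ensemble); supports are uniform without
    replacement and magnitudes standard normal.
    """
    if sparsity > r:
        raise ValueError("sparsity cannot exceed the code dimension")
    if not m < n:
        raise ValueError("the measurement system must be under-determined (m < n)")
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n, r))
    M /= np.linalg.norm(M, axis=0)
    A = rng.standard_normal((m, n)) / np.sqrt(m)
    out = []
    for _ in range(count):
        s = np.zeros(r)
        if sparsity > 0:
            support = rng.choice(r, size=sparsity, replace=False)
            s[support] = rng.standard_normal(sparsity)
        x = M @ s
        out.append(DictionaryInstance(M=M, s_true=s, x_true=x, A=A, d=A @ x))
    return out


def generate_phantom(image_side, n_ellipses=6, seed=0):
    """Superposition of random ellipses, clipped to [0,1]."""
    if image_side < 4:
        raise ValueError("image_side must be >= 4")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:image_side, 0:image_side]
    yy = (yy + 0.5) / image_side - 0.5
    xx = (xx + 0.5) / image_side - 0.5
    img = np.zeros((image_side, image_side))
    for _ in range(n_ellipses):
        cx, cy = rng.uniform(-0.3, 0.3, size=2)
        ax_, ay = rng.uniform(0.05, 0.35, size=2)
        phi = rng.uniform(0, np.pi)
        amp = rng.uniform(0.2, 0.8)
        c, s = np.cos(phi), np.sin(phi)
        u = (xx - cx) * c + (yy - cy) * s
        v = -(xx - cx) * s + (yy - cy) * c
        img += amp * (((u / ax_) ** 2 + (v / ay) ** 2) <= 1.0)
    return np.clip(img, 0.0, 1.0)


def add_beam_noise(sinogram, level, seed=0):
    """Per-beam multiplicative noise ``out_i = sino_i * (1 + eps_i)`` with
    ``eps_i ~ N(0, level^2)``; zero-valued beams stay zero."""
    if level < 0:
        raise ValueError("noise level must be nonnegative")
    sino = np.asarray(sinogram, dtype=float)
    if level == 0:
        return sino.copy()
    rng = np.random.default_rng(seed)
    return sino * (1.0 + level * rng.standard_normal(sino.shape))


def generate_ct_dataset(geometry, count=10, noise_level=0.015, seed=0,
                        n_ellipses=6):
    """Phantoms plus clean and noisy sinograms under one Radon geometry.

    ``geometry`` may be a :class:`RadonGeometry` or a preset name
    ("full" or "desk").  Returns ``(instances, radon_map)`` so callers reuse
    the (deterministic) system matrix.
    """
    if isinstance(geometry, str):
        geometry = CT_PRESETS[geometry]
    radon = build_radon_map(geometry)
    out = []
    for i in range(count):
        phantom = generate_phantom(geometry.image_side, n_ellipses=n_ellipses,
                                   seed=seed + 7919 * i)
        clean = radon.forward(phantom.ravel())
        noisy = add_beam_noise(clean, noise_level, seed=seed + 7919 * i + 1)
        out.append(CtInstance(phantom=phantom, sinogram_clean=clean,
                              sinogram_noisy=noisy, geometry=geometry,
                              noise_level=noise_level))
    return out, radon
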