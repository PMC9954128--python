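"""Quasi-probability densities from SSP memories.

The dot product of two encodings approximates a shift-invariant kernel
(sinc for uniformly sampled phase slopes), so the mean of the encodings of
a data set is a compressed kernel density estimate: evaluating it at a
query point is one dot product.  The kernel takes negative values, so the
raw score is a quasi-probability; a ReLU with offset xi (chosen so the
result integrates to one) converts it to a proper density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .ssp import SSPSpace

__all__ = ["induced_kernel", "QuasiDensity", "fit_quasi_density", "evaluate_density"]


def induced_kernel(space: SSPSpace, x, x_prime) -> np.ndarray:
    """Similarity phi(x) . phi(x'); depends only on x - x'."""
    return np.sum(space.encode(x) * space.encode(x_prime), axis=-1)


@dataclass
class QuasiDensity:
    """Memory vector (mean of encoded samples) plus the ReLU correction xi.

    ``kernel_mass`` is the integral of the induced kernel (length_scale^m
    for uniformly sampled phase slopes); dividing by it puts the raw score
    on the density scale, so xi only has to trim the kernel's negative
    lobes.
    """

    memory: np.ndarray
    n: int
    space: SSPSpace
    xi: float
    support: tuple  # per-dimension (lo, hi)
    grid_resolution: int
    kernel_mass: float = 1.0

    def quasi(self, x) -> np.ndarray:
        """Kernel-scale quasi-density (may be negative)."""
        return self.space.similarity(self.memory, np.asarray(x, dtype=float)) / self.kernel_mass

    def __call__(self, x) -> np.ndarray:
        return evaluate_density(self, x)


def _support_grid(support, resolution: int):
    axes = [np.linspace(lo, hi, resolution) for lo, hi in support]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    cell = np.prod([(hi - lo) / (resolution - 1) for lo, hi in support])
    return mesh.reshape(-1, len(support)), cell


def fit_quasi_density(
    space: SSPSpace,
    data: np.ndarray,
    support: Sequence[tuple[float, float]] | None = None,
    pad_length_scales: float = 3.0,
    grid_resolution: int = 200,
) -> QuasiDensity:
    """Fit the SSP kernel density estimate and solve for the offset xi.

    The normalization integral of max(0, memory . phi(x) - xi) over the
    support is continuous and strictly decreasing in xi (until it reaches
    zero), so the xi with unit integral is found by bracketing + Brent.
    The default support is the data bounding box padded by three length
    scales, discretized at ``grid_resolution`` points per dimension.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] == 0:
        raise ValueError("need at least one data point")
    if data.shape[1] != space.m:
        raise ValueError("data dimension does not match the space")
    memory = space.encode(data).mean(axis=0)
    if support is None:
        pad = pad_length_scales * space.length_scale
        support = [(data[:, j].min() - pad, data[:, j].max() + pad) for j in range(space.m)]
    support = [tuple(map(float, s)) for s in support]
    kernel_mass = space.length_scale**space.m if space.kind == "random" else 1.0
    pts, cell = _support_grid(support, grid_resolution)
    scores = space.similarity(memory, pts) / kernel_mass

    def integral(xi: float) -> float:
        return float(np.maximum(scores - xi, 0.0).sum() * cell)

    lo, hi = float(scores.min()) - 1.0, float(scores.max())
    if integral(lo) < 1.0:
        raise ValueError("support too small to normalize the density")
    xi = brentq(lambda t: integral(t) - 1.0, lo, hi, xtol=1e-12)
    return QuasiDensity(
        memory, data.shape[0], space, float(xi), tuple(support), grid_resolution, kernel_mass
    )


def evaluate_density(qd: QuasiDensity, x) -> np.ndarray:
    """ReLU-corrected density max(0, memory . phi(x) - xi); nonnegative."""
    return np.maximum(qd.quasi(x) - qd.xi, 0.0)
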