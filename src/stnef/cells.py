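"""Spatial cell types built from SSP tuning.

Grid cells pick out one hexagonal interference module (a triplet of plane
waves 120 degrees apart) through their encoders; place cells use the
encoding of a preferred location; object-vector and border cells live in a
population whose input is the SSP of the displacement from the agent to the
nearest object or wall.  Sparsity is controlled purely through the bias
current: the firing onset is placed at a quantile of the encoder-similarity
distribution over the arena.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .neurons import LIFParams, lif_rate_inverse
from .populations import Population, static_tuning
from .ssp import SSPSpace

__all__ = [
    "gain_bias_from_similarity",
    "grid_cell_population",
    "place_cell_population",
    "vector_cell_population",
    "nearest_object_displacement",
    "wall_displacement",
    "RateMap",
    "rate_map",
    "gridness_score",
]


def gain_bias_from_similarity(
    max_rate: float,
    onset_sim: float,
    peak_sim: float,
    params: LIFParams = LIFParams(),
) -> tuple[float, float]:
    """Gain/bias so firing starts at encoder similarity ``onset_sim`` and
    reaches ``max_rate`` at ``peak_sim`` (for encoders whose similarity with
    the input does not span [-1, 1])."""
    if peak_sim <= onset_sim:
        raise ValueError("peak similarity must exceed the onset")
    J_max = lif_rate_inverse(max_rate, params)
    alpha = (J_max - params.v_threshold) / (peak_sim - onset_sim)
    beta = params.v_threshold - alpha * onset_sim
    return alpha, beta


def _sparsity_population(
    space: SSPSpace,
    encoders: np.ndarray,
    sparsity: float,
    arena: Sequence[tuple[float, float]],
    rng: np.random.Generator,
    max_rates: tuple[float, float],
    n_calib: int = 2000,
    params: LIFParams = LIFParams(),
) -> Population:
    """Assemble a population whose active fraction at a random arena location
    is ``sparsity``, by placing each neuron's onset at the (1 - sparsity)
    quantile of its similarity distribution."""
    if not (0 < sparsity <= 1):
        raise ValueError("sparsity must lie in (0, 1]")
    n = encoders.shape[0]
    lo = np.array([b[0] for b in arena])
    hi = np.array([b[1] for b in arena])
    xs = rng.uniform(lo, hi, size=(n_calib, len(arena)))
    phis = space.encode(xs)  # (n_calib, d)
    sims = phis @ encoders.T  # (n_calib, n)
    onset = np.quantile(sims, 1.0 - sparsity, axis=0)
    peak = sims.max(axis=0)
    mr = rng.uniform(*max_rates, size=n)
    gains = np.empty(n)
    biases = np.empty(n)
    for i in range(n):
        gains[i], biases[i] = gain_bias_from_similarity(mr[i], onset[i], peak[i], params)
    return Population(n, space.d, encoders, gains, biases, params)


def grid_cell_population(
    space: SSPSpace,
    n: int,
    sparsity: float = 0.1,
    arena: Sequence[tuple[float, float]] = ((-1.0, 1.0), (-1.0, 1.0)),
    seed: int | np.random.Generator | None = None,
    max_rates: tuple[float, float] = (50.0, 100.0),
) -> Population:
    """Grid cells over a hex-structured SSP space.

    Each neuron's encoder has frequency support on a single plane-wave
    triplet (one scale/orientation module) with random phases, so its
    activity is the LIF nonlinearity applied to a three-plane-wave
    interference pattern; random phases scatter the grid offsets.
    """
    if space.kind != "hex" or space.module_waves is None:
        raise ValueError("grid cells require a hex-structured space")
    rng = np.random.default_rng(seed)
    n_modules = space.module_waves.shape[0]
    d = space.d
    encoders = np.empty((n, d))
    for i in range(n):
        module = rng.integers(n_modules)
        psis = rng.uniform(-np.pi, np.pi, 3)
        spec = np.zeros(d, dtype=complex)
        for j in range(3):
            row = 1 + module * 3 + j  # positive-frequency row of this wave
            spec[row] = np.exp(1j * psis[j])
            spec[d - row] = np.conj(spec[row])
        e = np.fft.ifft(spec).real
        encoders[i] = e / np.linalg.norm(e)
    return _sparsity_population(space, encoders, sparsity, arena, rng, max_rates)


def place_cell_population(
    space: SSPSpace,
    centres: np.ndarray,
    sparsity: float = 0.1,
    arena: Sequence[tuple[float, float]] = ((-1.0, 1.0), (-1.0, 1.0)),
    seed: int | np.random.Generator | None = None,
    max_rates: tuple[float, float] = (50.0, 100.0),
) -> Population:
    """Place cells: neuron j's encoder is the encoding of its centre."""
    centres = np.atleast_2d(np.asarray(centres, dtype=float))
    rng = np.random.default_rng(seed)
    encoders = space.encode(centres)
    encoders = encoders / np.linalg.norm(encoders, axis=1, keepdims=True)
    return _sparsity_population(space, encoders, sparsity, arena, rng, max_rates)


def nearest_object_displacement(
    x: np.ndarray, objects: np.ndarray, max_range: float = np.inf
) -> Optional[np.ndarray]:
    """Vector from the agent at ``x`` to the nearest object in view (None if
    nothing is within ``max_range``)."""
    objects = np.atleast_2d(np.asarray(objects, dtype=float))
    deltas = objects - np.asarray(x, dtype=float)
    dists = np.linalg.norm(deltas, axis=1)
    k = int(np.argmin(dists))
    return deltas[k] if dists[k] <= max_range else None


def wall_displacement(x: np.ndarray, wall: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Vector from ``x`` to the closest point of a wall segment (p0, p1)."""
    p0, p1 = (np.asarray(p, dtype=float) for p in wall)
    seg = p1 - p0
    t = np.clip(np.dot(np.asarray(x) - p0, seg) / np.dot(seg, seg), 0.0, 1.0)
    return p0 + t * seg - np.asarray(x)


def vector_cell_population(
    space: SSPSpace,
    preferred_displacements: np.ndarray,
    sparsity: float = 0.15,
    displacement_range: float = 1.0,
    seed: int | np.random.Generator | None = None,
    max_rates: tuple[float, float] = (50.0, 100.0),
) -> Population:
    """Object-vector / border cells.

    The population's input is the SSP of the agent-to-target displacement
    (see ``nearest_object_displacement`` / ``wall_displacement``); encoders
    are the encodings of preferred displacement vectors, so a neuron fires
    whenever the current displacement matches its preferred one — i.e. at a
    fixed offset from every object, or hugging a wall.
    """
    prefs = np.atleast_2d(np.asarray(preferred_displacements, dtype=float))
    if prefs.shape[0] == 0:
        raise ValueError("need at least one preferred displacement")
    rng = np.random.default_rng(seed)
    encoders = space.encode(prefs)
    encoders = encoders / np.linalg.norm(encoders, axis=1, keepdims=True)
    arena = [(-displacement_range, displacement_range)] * space.m
    return _sparsity_population(space, encoders, sparsity, arena, rng, max_rates)


@dataclass
class RateMap:
    """Binned mean firing rates over a trajectory, with occupancy."""

    rates: np.ndarray  # (nx, ny) Hz; NaN where unvisited
    occupancy: np.ndarray  # seconds per bin
    extent: tuple  # (x0, x1, y0, y1)

    @property
    def valid(self) -> np.ndarray:
        return self.occupancy > 0

    def centroid(self) -> np.ndarray:
        """Rate-weighted centroid of the map in arena coordinates."""
        x0, x1, y0, y1 = self.extent
        nx, ny = self.rates.shape
        xs = np.linspace(x0, x1, nx + 1)[:-1] + (x1 - x0) / (2 * nx)
        ys = np.linspace(y0, y1, ny + 1)[:-1] + (y1 - y0) / (2 * ny)
        w = np.nan_to_num(self.rates)
        total = w.sum()
        if total == 0:
            return np.array([np.nan, np.nan])
        cx = (w.sum(axis=1) * xs).sum() / total
        cy = (w.sum(axis=0) * ys).sum() / total
        return np.array([cx, cy])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.rates).to_csv(path, index=False)


def rate_map(
    activities: np.ndarray,
    trajectory: np.ndarray,
    dt: float,
    bin_size: float,
    extent: Optional[tuple] = None,
) -> list[RateMap]:
    """Per-neuron rate maps from activity traces along a 2-D trajectory.

    ``activities``: (T, n) firing rates (or spike trains scaled to Hz);
    ``trajectory``: (T, 2) positions.  Bins with zero occupancy are NaN.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    activities = np.atleast_2d(np.asarray(activities, dtype=float))
    if extent is None:
        extent = (
            trajectory[:, 0].min(),
            trajectory[:, 0].max(),
            trajectory[:, 1].min(),
            trajectory[:, 1].max(),
        )
    x0, x1, y0, y1 = extent
    nx = max(1, int(np.ceil((x1 - x0) / bin_size)))
    ny = max(1, int(np.ceil((y1 - y0) / bin_size)))
    ix = np.clip(((trajectory[:, 0] - x0) / bin_size).astype(int), 0, nx - 1)
    iy = np.clip(((trajectory[:, 1] - y0) / bin_size).astype(int), 0, ny - 1)
    flat = ix * ny + iy
    occupancy = np.bincount(flat, minlength=nx * ny).reshape(nx, ny) * dt
    maps = []
    for j in range(activities.shape[1]):
        summed = np.bincount(flat, weights=activities[:, j], minlength=nx * ny).reshape(nx, ny)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(occupancy > 0, summed * dt / occupancy, np.nan)
        maps.append(RateMap(rates, occupancy, (x0, x1, y0, y1)))
    return maps


def gridness_score(rmap: RateMap) -> float:
    """Rotational-autocorrelation contrast.

    Correlate the spatial autocorrelogram with itself rotated by 60/120
    degrees versus 30/90/150 degrees; hexagonal fields give a positive
    contrast (min of the on-angles minus max of the off-angles).
    """
    r = np.nan_to_num(rmap.rates, nan=float(np.nanmean(rmap.rates)))
    r = r - r.mean()
    # FFT autocorrelation, cropped to the central half
    n0, n1 = r.shape
    F = np.fft.fft2(r, s=(2 * n0, 2 * n1))
    ac = np.fft.fftshift(np.fft.ifft2(F * np.conj(F)).real)
    c0, c1 = ac.shape[0] // 2, ac.shape[1] // 2
    h = min(n0, n1) // 2
    ac = ac[c0 - h : c0 + h + 1, c1 - h : c1 + h + 1]
    # mask out the central peak
    yy, xx = np.indices(ac.shape)
    rad = np.hypot(yy - h, xx - h)
    mask = (rad > 0.15 * h) & (rad <= h)

    def rot_corr(angle: float) -> float:
        rot = ndimage.rotate(ac, angle, reshape=False, order=1, mode="constant", cval=0.0)
        a, b = ac[mask], rot[mask]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        return float((a * b).sum() / denom) if denom > 0 else 0.0

    on = [rot_corr(60), rot_corr(120)]
    off = [rot_corr(30), rot_corr(90), rot_corr(150)]
    return min(on) - max(off)
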