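"""Populations and (spatio)temporal tuning curves.

A population assigns each neuron a tuning curve through the linear-nonlinear
model: the input current is a gain-scaled inner product between an encoder
(a preferred direction, or a preferred stimulus history) and the stimulus,
plus a bias, passed through the neuron's rate nonlinearity

    a_i(x) = G[ alpha_i <e_i, x> + beta_i ].

With temporal encoders the inner product runs over the stimulus history on
a lag grid, so a neuron's "preferred direction" becomes a preferred pattern
over time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .neurons import LIFParams, lif_rate, solve_gain_bias

__all__ = [
    "TemporalEncoder",
    "Population",
    "make_population",
    "static_tuning",
    "temporal_tuning",
]


@dataclass
class TemporalEncoder:
    """A preferred stimulus history, sampled on a lag grid.

    samples : array of shape (n_lags,) or (n_lags, d); ``samples[k]`` is the
        encoder evaluated at lag ``k * dt`` (lag 0 = the present stimulus,
        larger indices reach further into the past).  Causality is built in:
        nothing is defined for negative lags.
    dt : lag-grid spacing in seconds.
    """

    samples: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.samples = np.atleast_1d(np.asarray(self.samples, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("temporal encoder must be finite")

    @property
    def n_lags(self) -> int:
        return self.samples.shape[0]

    def norm(self) -> float:
        """L2 norm on the window, trapezoidal in lag."""
        w = _trapezoid_weights(self.n_lags, self.dt)
        sq = self.samples**2
        if sq.ndim > 1:
            sq = sq.sum(axis=tuple(range(1, sq.ndim)))
        return float(np.sqrt(np.sum(w * sq)))

    def normalized(self) -> "TemporalEncoder":
        n = self.norm()
        if n == 0:
            raise ValueError("cannot normalize a zero encoder")
        return TemporalEncoder(self.samples / n, self.dt)

    def inner(self, history: np.ndarray) -> float:
        """Trapezoidal inner product with a stimulus history on the same grid.

        ``history[k]`` is the stimulus ``k * dt`` seconds ago.
        """
        history = np.atleast_1d(np.asarray(history, dtype=float))
        if history.shape != self.samples.shape:
            raise ValueError(
                f"history shape {history.shape} does not match encoder grid "
                f"{self.samples.shape}"
            )
        w = _trapezoid_weights(self.n_lags, self.dt)
        prod = self.samples * history
        if prod.ndim > 1:
            prod = prod.sum(axis=tuple(range(1, prod.ndim)))
        return float(np.sum(w * prod))


def _trapezoid_weights(n: int, dt: float) -> np.ndarray:
    w = np.full(n, dt)
    if n > 1:
        w[0] = w[-1] = dt / 2
    return w


@dataclass
class Population:
    """n neurons with encoders, gains, biases and a rate model.

    encoders : (n, dim) unit vectors, or a list of TemporalEncoder (one per
        neuron) for populations with spatiotemporal tuning.
    rate : vectorized map from current to firing rate; defaults to the LIF
        closed form with ``neuron_model``.
    """

    n: int
    dim: int
    encoders: object  # np.ndarray or list[TemporalEncoder]
    gains: np.ndarray
    biases: np.ndarray
    neuron_model: LIFParams = field(default_factory=LIFParams)
    rate: Optional[Callable] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population needs at least one neuron")
        self.gains = np.asarray(self.gains, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if np.any(self.gains <= 0):
            raise ValueError("gains must be positive")
        if isinstance(self.encoders, np.ndarray):
            if self.encoders.shape != (self.n, self.dim):
                raise ValueError("encoder matrix must be (n, dim)")
            norms = np.linalg.norm(self.encoders, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError("static encoders must have unit norm")
        if self.rate is None:
            self.rate = lambda J: lif_rate(J, self.neuron_model)

    @property
    def is_temporal(self) -> bool:
        return not isinstance(self.encoders, np.ndarray)

    def currents(self, x: np.ndarray) -> np.ndarray:
        """Input currents J_i for a batch of stimuli (shape (..., dim))."""
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.dim:
            raise ValueError(f"stimulus dim {x.shape[-1]} != population dim {self.dim}")
        return self.gains * (x @ self.encoders.T) + self.biases

    def to_json(self) -> str:
        if self.is_temporal:
            enc = [{"samples": e.samples.tolist(), "dt": e.dt} for e in self.encoders]
        else:
            enc = self.encoders.tolist()
        return json.dumps(
            {
                "n": self.n,
                "dim": self.dim,
                "temporal": self.is_temporal,
                "encoders": enc,
                "gains": self.gains.tolist(),
                "biases": self.biases.tolist(),
                "neuron_model": {
                    "tau_rc": self.neuron_model.tau_rc,
                    "tau_ref": self.neuron_model.tau_ref,
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Population":
        d = json.loads(text)
        params = LIFParams(**d["neuron_model"])
        if d["temporal"]:
            enc = [TemporalEncoder(np.array(e["samples"]), e["dt"]) for e in d["encoders"]]
        else:
            enc = np.array(d["encoders"])
        return cls(d["n"], d["dim"], enc, np.array(d["gains"]), np.array(d["biases"]), params)


def make_population(
    n: int,
    dim: int,
    rng: np.random.Generator | int | None = None,
    max_rates: tuple[float, float] = (100.0, 200.0),
    intercepts: tuple[float, float] = (-1.0, 1.0),
    encoders: Optional[np.ndarray] = None,
    neuron_model: LIFParams = LIFParams(),
) -> Population:
    """Sample a population with uniformly distributed tuning properties.

    Maximum rates are drawn uniformly from ``max_rates`` (Hz, attained at
    encoder similarity 1) and firing onsets from ``intercepts``; encoders are
    uniform on the unit sphere unless given.
    """
    rng = np.random.default_rng(rng)
    if encoders is None:
        encoders = rng.standard_normal((n, dim))
        encoders /= np.linalg.norm(encoders, axis=1, keepdims=True)
    else:
        encoders = np.asarray(encoders, dtype=float)
        encoders = encoders / np.linalg.norm(encoders, axis=1, keepdims=True)
    mr = rng.uniform(*max_rates, size=n)
    ic = rng.uniform(*intercepts, size=n)
    gains = np.empty(n)
    biases = np.empty(n)
    for i in range(n):
        gains[i], biases[i] = solve_gain_bias(mr[i], ic[i], neuron_model)
    return Population(n, dim, encoders, gains, biases, neuron_model)


def static_tuning(pop: Population, x: np.ndarray) -> np.ndarray:
    """Firing rates of every neuron for stimulus x (shape (dim,) or batch)."""
    if pop.is_temporal:
        raise ValueError("population has temporal encoders; use temporal_tuning")
    return pop.rate(pop.currents(x))


def temporal_tuning(
    pop: Population, history: np.ndarray, normalize_encoders: bool = True
) -> np.ndarray:
    """Firing rates of a temporally tuned population given a stimulus history.

    ``history[k]`` is the stimulus ``k * dt`` seconds in the past, on the same
    lag grid as the encoders.  Each neuron's current is its gain times the
    (by default cosine-style, i.e. with normalized encoder) inner product of
    its preferred history with the actual one, plus its bias.
    """
    if not pop.is_temporal:
        raise ValueError("population has static encoders; use static_tuning")
    J = np.empty(pop.n)
    for i, enc in enumerate(pop.encoders):
        e = enc.normalized() if normalize_encoders else enc
        J[i] = pop.gains[i] * e.inner(history) + pop.biases[i]
    return pop.rate(J)
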