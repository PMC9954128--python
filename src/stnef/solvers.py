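"""Synaptic filters and least-squares weight solving.

Solving for synaptic weights is a ridge-regularized linear regression: the
filtered pre-synaptic activities over a set of training signals are fit to
the input currents each post-neuron needs in order to realize its assigned
tuning curve of the transformed value.  For linear-nonlinear tuning the
weight matrix is low-rank, so we usually solve for decoders (a readout of
the represented value) and recover full weights as gain * encoder x decoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .lti import LTISystem, discretize
from .populations import Population, static_tuning

__all__ = [
    "SynapticFilter",
    "Connection",
    "band_limited_noise",
    "sample_training_signals",
    "solve_decoders",
    "solve_weights",
    "map_lti_through_lowpass",
    "solve_temporal_weights",
]


@dataclass(frozen=True)
class SynapticFilter:
    """Normalized causal synaptic filter (unit DC gain).

    kind "exponential": h(t) = exp(-t/tau)/tau.
    kind "alpha":       h(t) = t * exp(-t/tau)/tau^2.
    """

    kind: str = "exponential"
    tau: float = 0.005

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "alpha"):
            raise ValueError("filter kind must be 'exponential' or 'alpha'")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def impulse_response(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        h = np.where(
            t < 0,
            0.0,
            np.exp(-t / self.tau) / self.tau
            if self.kind == "exponential"
            else t * np.exp(-t / self.tau) / self.tau**2,
        )
        return h

    def make_state(self, shape) -> np.ndarray:
        n_stages = 1 if self.kind == "exponential" else 2
        return np.zeros((n_stages,) + tuple(np.atleast_1d(shape)))

    def step(self, state: np.ndarray, x: np.ndarray, dt: float) -> np.ndarray:
        """Advance the filter one step (exact ZOH recurrence); returns output.

        The cascade form realizes the alpha synapse as two identical
        exponential stages.
        """
        a = np.exp(-dt / self.tau)
        state[0] = a * state[0] + (1 - a) * x
        if self.kind == "alpha":
            state[1] = a * state[1] + (1 - a) * state[0]
            return state[1]
        return state[0]

    def apply(self, x: np.ndarray, dt: float, axis: int = 0) -> np.ndarray:
        """Filter a sampled signal along ``axis`` (zero initial state)."""
        x = np.moveaxis(np.asarray(x, dtype=float), axis, 0)
        state = self.make_state(x.shape[1:])
        out = np.empty_like(x)
        for k in range(x.shape[0]):
            out[k] = self.step(state, x[k], dt)
        return np.moveaxis(out, 0, axis)


@dataclass
class Connection:
    """A solved pre -> post link.

    Either ``weights`` (n_post x n_pre) or the factored pair
    ``decoders`` (dim_out x n_pre, with post gains/encoders supplying the
    other factor) is populated by the solvers below.
    """

    pre: Population
    post: Optional[Population] = None
    function: Optional[Callable] = None
    filter: SynapticFilter = field(default_factory=SynapticFilter)
    regularization: float = 0.1
    weights: Optional[np.ndarray] = None
    decoders: Optional[np.ndarray] = None
    residual: Optional[float] = None

    def save(self, path) -> None:
        """Write the solved arrays (.npz) plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        arrays = {}
        if self.weights is not None:
            arrays["weights"] = self.weights
        if self.decoders is not None:
            arrays["decoders"] = self.decoders
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "filter": {"kind": self.filter.kind, "tau": self.filter.tau},
            "regularization": self.regularization,
            "residual": self.residual,
            "n_pre": self.pre.n,
            "n_post": None if self.post is None else self.post.n,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    def full_weights(self) -> np.ndarray:
        if self.weights is not None:
            return self.weights
        if self.decoders is None:
            raise ValueError("connection has not been solved")
        if self.post is None:
            raise ValueError("factored connection needs a post population")
        return (self.post.gains[:, None] * self.post.encoders) @ self.decoders


def band_limited_noise(
    n_samples: int, dt: float, bandwidth_hz: float, rng: np.random.Generator, rms: float = 1.0
) -> np.ndarray:
    """Gaussian noise with a hard spectral cutoff at ``bandwidth_hz``."""
    f = np.fft.rfftfreq(n_samples, dt)
    spec = (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)) * (f <= bandwidth_hz)
    x = np.fft.irfft(spec, n_samples)
    s = x.std()
    return x * (rms / s) if s > 0 else x


def sample_training_signals(
    dim: int,
    N: int,
    mode: str = "static",
    seed: int | np.random.Generator | None = None,
    radius: float = 1.0,
    dt: float = 1e-3,
    duration: float = 1.0,
    bandwidth_hz: float = 5.0,
):
    """Random training signals over the represented domain.

    static: ``N`` points uniform in the ball of the given radius, shape (N, dim).
    temporal: ``N`` band-limited noise signals, shape (N, n_steps, dim).
    """
    if N < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    if mode == "static":
        # uniform in the ball: direction times radius * U^(1/dim)
        v = rng.standard_normal((N, dim))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = radius * rng.random(N) ** (1.0 / dim)
        return v * r[:, None]
    if mode == "temporal":
        n_steps = int(round(duration / dt))
        out = np.empty((N, n_steps, dim))
        for k in range(N):
            for d in range(dim):
                out[k, :, d] = band_limited_noise(n_steps, dt, bandwidth_hz, rng, rms=radius)
        return out
    raise ValueError("mode must be 'static' or 'temporal'")


def _ridge_solve(A: np.ndarray, Y: np.ndarray, reg: float) -> tuple[np.ndarray, float]:
    """Ridge regression of targets Y (N x k) on activities A (N x n).

    ``reg`` scales with the largest activity, following the convention that
    the penalty is (reg * max|A|)^2 entering the Gram matrix diagonal.
    Returns (coefficients n x k, rms residual).
    """
    N = A.shape[0]
    sigma = reg * np.abs(A).max() if A.size else 0.0
    G = A.T @ A + N * sigma**2 * np.eye(A.shape[1])
    U = A.T @ Y
    if sigma == 0.0:
        rank = np.linalg.matrix_rank(G)
        if rank < A.shape[1]:
            warnings.warn("rank-deficient solve with zero regularization; using pseudo-inverse")
            X = np.linalg.pinv(A) @ Y
            res = float(np.sqrt(np.mean((A @ X - Y) ** 2)))
            return X, res
    X = np.linalg.solve(G, U)
    res = float(np.sqrt(np.mean((A @ X - Y) ** 2)))
    return X, res


def solve_decoders(
    pre: Population,
    function: Callable | np.ndarray | None,
    signals: np.ndarray,
    reg: float = 0.1,
) -> tuple[np.ndarray, float]:
    """Decoders D (dim_out x n_pre) such that f(x) is approximated by D a(x).

    ``function`` may be a callable, an array of precomputed targets
    (N x dim_out), or None for the identity.  Returns (D, rms residual).
    """
    X = np.atleast_2d(np.asarray(signals, dtype=float))
    A = static_tuning(pre, X)  # (N, n)
    if function is None:
        Y = X
    elif callable(function):
        Y = np.atleast_2d(np.array([np.atleast_1d(function(x)) for x in X], dtype=float))
    else:
        Y = np.atleast_2d(np.asarray(function, dtype=float))
    D, res = _ridge_solve(A, Y, reg)
    return D.T, res


def solve_weights(conn: Connection, signals: np.ndarray) -> np.ndarray:
    """Solve the full weight matrix for a static connection.

    The target for post-neuron i is the encoding current
    gain_i <e_i, f(x_k)> (the bias is intrinsic to the neuron); the
    regressors are the pre-population tuning-curve rates, which is what the
    filtered spike trains estimate in steady state (unit-DC-gain synapses).
    """
    X = np.atleast_2d(np.asarray(signals, dtype=float))
    A = static_tuning(conn.pre, X)
    f = conn.function
    if f is None:
        F = X
    elif callable(f):
        F = np.atleast_2d(np.array([np.atleast_1d(f(x)) for x in X], dtype=float))
    else:
        F = np.atleast_2d(np.asarray(f, dtype=float))
    post = conn.post
    if post is None:
        raise ValueError("full weight solve needs a post population")
    J_target = post.gains * (F @ post.encoders.T)  # (N, n_post)
    W, res = _ridge_solve(A, J_target, conn.regularization)
    conn.weights = W.T  # (n_post, n_pre)
    conn.residual = res
    return conn.weights


def map_lti_through_lowpass(sys: LTISystem, tau: float, filter_kind: str = "exponential"):
    """Transform (A, B) so a recurrently connected population with an
    exponential synapse of time constant ``tau`` realizes x' = A x + B u.

    The synapse integrates with a leak; compensating gives the recurrent
    transform A' = tau A + I and input transform B' = tau B.  Only valid for
    first-order exponential synapses; anything else must go through the full
    temporal regression.
    """
    if filter_kind != "exponential":
        raise ValueError(
            "low-pass dynamics compensation requires an exponential synapse; "
            "use solve_temporal_weights for general filters"
        )
    A_prime = tau * sys.A + np.eye(sys.q)
    B_prime = tau * sys.B
    return A_prime, B_prime


def solve_temporal_weights(
    pop: Population,
    sys: LTISystem,
    probe_signals: np.ndarray,
    dt: float,
    filter: SynapticFilter | None = None,
    input_filter: SynapticFilter | None = None,
    reg: float = 0.1,
    subsample: int = 4,
    residual_threshold: float | None = None,
):
    """Full temporal regression for recurrent weights realizing an LTI system.

    ``pop`` has static encoders over the q-dimensional LTI state (its
    temporal encoders are then linear combinations of the system's impulse
    response).  For each probe input signal the desired state trajectory is
    integrated, target currents are formed from the tuning curves, the
    pre-activities are filtered through the synapse, and recurrent plus
    input weights are regressed jointly on a uniform time grid.

    Returns (W_rec (n x n), W_in (n x u), residual).
    """
    if filter is None:
        filter = SynapticFilter("exponential", 0.1)
    if input_filter is None:
        input_filter = filter
    U = np.asarray(probe_signals, dtype=float)
    if U.ndim == 2:
        U = U[..., None]  # (K, T, u)
    Ad, Bd = discretize(sys, dt)
    regressors, targets = [], []
    for u in U:
        T = u.shape[0]
        x = np.zeros(sys.q)
        states = np.empty((T, sys.q))
        for k in range(T):
            x = Ad @ x + Bd @ u[k]
            states[k] = x
        rates = static_tuning(pop, states)  # (T, n)
        fa = filter.apply(rates, dt, axis=0)
        fu = input_filter.apply(u, dt, axis=0)
        J = pop.gains * (states @ pop.encoders.T)  # target encoding currents
        sl = slice(0, T, subsample)
        regressors.append(np.hstack([fa[sl], fu[sl]]))
        targets.append(J[sl])
    Areg = np.vstack(regressors)
    Y = np.vstack(targets)
    # balance the two regressor blocks (rates are O(100) Hz, inputs O(1)):
    # a uniform ridge would otherwise suppress the input pathway entirely
    n = pop.n
    col_scale = np.ones(Areg.shape[1])
    rate_rms = np.sqrt(np.mean(Areg[:, :n] ** 2)) or 1.0
    in_rms = np.sqrt(np.mean(Areg[:, n:] ** 2)) or 1.0
    col_scale[n:] = rate_rms / in_rms
    W, res = _ridge_solve(Areg * col_scale, Y, reg)
    W = W * col_scale[:, None]
    W_rec, W_in = W[:n].T, W[n:].T
    if residual_threshold is not None and res > residual_threshold:
        warnings.warn(f"temporal weight solve residual {res:.3g} above threshold")
    return W_rec, W_in, res
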