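"""Basis-generating linear time-invariant systems.

The Legendre Delay Network (LDN) is the optimal q-dimensional LTI
realization of a pure delay of length theta: its state compresses the last
theta seconds of the input, and its impulse response approximates the
shifted Legendre polynomials, an orthogonal basis on the window.  The
Modified Fourier (MF) system plays the same role with a Fourier series
basis: one slow "constant" mode plus harmonic oscillator pairs at multiples
of 1/theta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.special import eval_legendre

__all__ = [
    "LTISystem",
    "make_ldn",
    "make_modified_fourier",
    "impulse_response",
    "discretize",
    "delay_readout",
    "delay_decode",
]


@dataclass
class LTISystem:
    """State-space system x' = A x + B u with a nominal window length."""

    A: np.ndarray
    B: np.ndarray
    theta: float
    label: str = "custom"

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.asarray(self.B, dtype=float).reshape(self.A.shape[0], -1)
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.B))):
            raise ValueError("state matrices must be finite")
        if self.theta <= 0:
            raise ValueError("theta must be positive")

    @property
    def q(self) -> int:
        return self.A.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {"A": self.A.tolist(), "B": self.B.tolist(), "theta": self.theta, "label": self.label}
        )

    @classmethod
    def from_json(cls, text: str) -> "LTISystem":
        d = json.loads(text)
        return cls(np.array(d["A"]), np.array(d["B"]), d["theta"], d["label"])


def make_ldn(q: int, theta: float) -> LTISystem:
    """Legendre Delay Network of order ``q`` over a window of ``theta`` s.

    Closed form (i, j zero-based):

        A[i, j] = (2i + 1)/theta * (-1 if i < j else (-1)^(i - j + 1))
        B[i]    = (2i + 1)/theta * (-1)^i

    For q = 1 this reduces to the [0/1] Pade approximant of the delay
    exp(-theta s): A = [-1/theta], B = [1/theta].
    """
    if q < 1:
        raise ValueError("order q must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be positive")
    qr = np.arange(q)
    D = (2 * qr + 1)[:, None] / theta
    i, j = np.meshgrid(qr, qr, indexing="ij")
    A = np.where(i < j, -1.0, (-1.0) ** (i - j + 1)) * D
    B = ((2 * qr + 1) * (-1.0) ** qr / theta)[:, None]
    return LTISystem(A, B, theta, label="LDN")


def make_modified_fourier(q: int, theta: float, damping: float = 1.0) -> LTISystem:
    """Fourier-basis-generating LTI system of odd order ``q``.

    One decaying "constant" mode plus (q - 1)/2 harmonic oscillator pairs at
    angular frequencies 2*pi*k/theta, all sharing a decay rate
    ``damping / theta`` so the impulse response is a (damped) Fourier series
    on the window.  With ``damping = 0`` the dynamics matrix is exactly the
    family of pure rotations used by the spacetime trajectory integrator.
    For q = 1 the system is a first-order low-pass.
    """
    if q < 1 or q % 2 == 0:
        raise ValueError("order q must be odd (constant mode + sine/cosine pairs)")
    if theta <= 0:
        raise ValueError("theta must be positive")
    gamma = damping / theta
    A = np.zeros((q, q))
    B = np.zeros((q, 1))
    A[0, 0] = -gamma
    B[0, 0] = 1.0 / theta
    for k in range(1, (q - 1) // 2 + 1):
        w = 2 * np.pi * k / theta
        r, c = 2 * k - 1, 2 * k
        A[r, r] = A[c, c] = -gamma
        A[r, c] = w
        A[c, r] = -w
        B[r, 0] = 2.0 / theta  # cosine channel receives the impulse
    return LTISystem(A, B, theta, label="MF")


def discretize(sys: LTISystem, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Zero-order-hold one-step update matrices (Ad, Bd).

    Exact for inputs held constant over each step:
    ``x[k+1] = Ad @ x[k] + Bd @ u[k]`` with Ad = expm(A dt) and
    Bd = A^{-1} (Ad - I) B, evaluated via an augmented matrix exponential so
    singular A is handled too.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    q, u = sys.q, sys.B.shape[1]
    M = np.zeros((q + u, q + u))
    M[:q, :q] = sys.A * dt
    M[:q, q:] = sys.B * dt
    E = expm(M)
    return E[:q, :q], E[:q, q:]


def impulse_response(sys: LTISystem, t_grid: np.ndarray) -> np.ndarray:
    """Response of each state dimension to a unit-mass impulse at t = 0.

    Returns an array of shape (len(t_grid), q): ``expm(A t) @ B`` evaluated
    on the grid (single-input systems).  At t = 0+ this equals B.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < 0):
        raise ValueError("impulse response is causal; t_grid must be nonnegative")
    if t_grid.size >= 2:
        steps = np.diff(t_grid)
        if np.any(steps <= 0):
            raise ValueError("t_grid must be strictly increasing")
    out = np.empty((t_grid.size, sys.q))
    # exact stepping via the matrix exponential between grid points
    x = None
    prev_t = None
    for k, t in enumerate(t_grid):
        if x is None:
            x = (expm(sys.A * t) @ sys.B)[:, 0]
        else:
            x = expm(sys.A * (t - prev_t)) @ x
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("impulse-response integration diverged")
        out[k] = x
        prev_t = t
    return out


def delay_readout(sys: LTISystem, theta_prime: float, n_grid: int = 512) -> np.ndarray:
    """Linear readout w such that ``w @ x(t)`` estimates u(t - theta_prime).

    For the LDN the readout evaluates the shifted Legendre polynomials at the
    requested lag (realization sign convention resolved numerically against
    the impulse response); for other systems it is built by least-squares
    projection of a lag-delta onto the numerically integrated impulse
    response basis.
    """
    if not (0 <= theta_prime <= sys.theta):
        raise ValueError("theta_prime must lie inside the window [0, theta]")
    if sys.label == "LDN":
        r = theta_prime / sys.theta
        i = np.arange(sys.q)
        return eval_legendre(i, 2 * r - 1)
    # generic path: the state is x(t) = integral h(s) u(t-s) ds with h the
    # impulse response; regress u(t - theta') on x over random histories
    t = np.linspace(0, sys.theta, n_grid)
    H = impulse_response(sys, t)  # (n_grid, q)
    dt = t[1] - t[0]
    rng = np.random.default_rng(0)
    U = rng.standard_normal((n_grid, 256))
    # smooth the histories a little so the regression is well conditioned
    k = np.exp(-np.linspace(-2, 2, 21) ** 2)
    k /= k.sum()
    U = np.apply_along_axis(lambda u: np.convolve(u, k, mode="same"), 0, U)
    X = H.T @ U * dt  # states for each history (q, 256)
    idx = int(round(theta_prime / sys.theta * (n_grid - 1)))
    target = U[idx]
    w, *_ = np.linalg.lstsq(X.T, target, rcond=None)
    return w


def delay_decode(state: np.ndarray, theta_prime: float, sys: LTISystem) -> float:
    """Estimate the input as it was ``theta_prime`` seconds ago from the state."""
    w = delay_readout(sys, theta_prime)
    return float(w @ np.asarray(state, dtype=float))
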