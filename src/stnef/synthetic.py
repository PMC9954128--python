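"""Synthetic input generators.

Every experiment in the package runs on generated data: torque-driven
pendulum traces, bouncing-ball paths, smooth random walks standing in for
foraging-rodent trajectories (the arena geometry and run length mirror the
published setups; the paths themselves are synthetic), and drifting
gratings for the motion-tuning demonstration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solvers import band_limited_noise

__all__ = [
    "PendulumParams",
    "gen_pendulum",
    "gen_bouncing_ball",
    "gen_trajectory_2d",
    "gen_grating",
    "trajectory_to_csv",
    "trajectory_from_csv",
]


@dataclass(frozen=True)
class PendulumParams:
    """Point-mass single-joint pendulum: ml^2 phi'' = tau - mgl sin(phi) - c phi'."""

    mass: float = 1.0
    length: float = 1.0
    gravity: float = 9.81
    damping: float = 0.1

    @property
    def small_angle_period(self) -> float:
        return 2 * np.pi * np.sqrt(self.length / self.gravity)


def gen_pendulum(
    duration: float,
    dt: float,
    seed: int | np.random.Generator | None = None,
    params: PendulumParams = PendulumParams(),
    torque_rms: float = 1.0,
    torque_bandwidth_hz: float = 1.0,
    sensory_delay: float = 0.05,
    phi0: float = 0.0,
    omega0: float = 0.0,
    torque: np.ndarray | None = None,
) -> pd.DataFrame:
    """Integrate the pendulum under filtered-white-noise torque (RK4).

    Returns a frame with columns t, torque, phi, omega, phi_delayed (the
    angle ``sensory_delay`` seconds ago, zero-padded at the start).
    """
    n = int(round(duration / dt))
    if torque is None:
        rng = np.random.default_rng(seed)
        torque = band_limited_noise(n, dt, torque_bandwidth_hz, rng, rms=torque_rms)
    else:
        torque = np.asarray(torque, dtype=float)
        if torque.shape[0] != n:
            raise ValueError("torque trace length must match duration/dt")
    ml2 = params.mass * params.length**2
    mgl = params.mass * params.gravity * params.length

    def deriv(state, tau_k):
        phi, omega = state
        return np.array([omega, (tau_k - mgl * np.sin(phi) - params.damping * omega) / ml2])

    state = np.array([phi0, omega0], dtype=float)
    phi = np.empty(n)
    omega = np.empty(n)
    for k in range(n):
        tau_k = torque[k]
        k1 = deriv(state, tau_k)
        k2 = deriv(state + dt / 2 * k1, tau_k)
        k3 = deriv(state + dt / 2 * k2, tau_k)
        k4 = deriv(state + dt * k3, tau_k)
        state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        phi[k], omega[k] = state
    shift = int(round(sensory_delay / dt))
    phi_delayed = np.concatenate([np.full(shift, phi0), phi[: n - shift]])
    t = np.arange(1, n + 1) * dt
    return pd.DataFrame(
        {"t": t, "torque": torque, "phi": phi, "omega": omega, "phi_delayed": phi_delayed}
    )


def gen_bouncing_ball(
    duration: float,
    dt: float,
    box: tuple[float, float] = (1.0, 1.0),
    x0: tuple[float, float] = (0.31, 0.57),
    v0: tuple[float, float] = (0.37, 0.23),
    walls: bool = True,
) -> pd.DataFrame:
    """Straight-line motion with exact specular, lossless wall reflections.

    Positions are evaluated by folding the free path: reflecting off the
    walls of [0, Lx] x [0, Ly] is a triangle-wave map of the unbounded
    coordinate, so speed is conserved to machine precision.  With
    ``walls=False`` the ball travels in a straight line (linear-motion
    control).
    """
    n = int(round(duration / dt))
    t = np.arange(1, n + 1) * dt
    out = {}
    for i, (axis, L) in enumerate(zip("xy", box)):
        free = x0[i] + v0[i] * t
        if walls:
            period = 2 * L
            saw = np.mod(free, period)
            out[axis] = np.where(saw <= L, saw, period - saw)
        else:
            out[axis] = free
    return pd.DataFrame({"t": t, **out})


def gen_trajectory_2d(
    duration: float = 60.0,
    dt: float = 0.01,
    arena: str = "circle",
    diameter: float = 1.8,
    box: tuple[float, float] = (1.8, 1.8),
    mean_speed: float = 0.15,
    speed_tau: float = 0.7,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Smooth random walk inside a circular or rectangular arena.

    Velocity is an Ornstein-Uhlenbeck-style low-pass-filtered white noise
    with the requested mean speed; the walk reflects off the boundary.
    Defaults mirror a 60 s foraging run in a 180 cm circular arena (metres).
    Columns: t, x, y, vx, vy.  Synthetic stand-in for recorded rodent paths.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    # OU velocity, then rescale to the requested mean speed
    v = np.zeros((n, 2))
    a = np.exp(-dt / speed_tau)
    drive = rng.standard_normal((n, 2))
    vk = np.zeros(2)
    for k in range(n):
        vk = a * vk + np.sqrt(1 - a * a) * drive[k]
        v[k] = vk
    speeds = np.linalg.norm(v, axis=1)
    v *= mean_speed / max(speeds.mean(), 1e-12)

    r = diameter / 2.0
    pos = np.zeros((n, 2))
    p = np.zeros(2)
    for k in range(n):
        cand = p + v[k] * dt
        if arena == "circle":
            if np.linalg.norm(cand) > r:
                # reflect this and future velocity about the boundary normal
                normal = cand / np.linalg.norm(cand)
                v[k:] = v[k:] - 2 * (v[k:] @ normal)[:, None] * normal
                cand = p + v[k] * dt
                if np.linalg.norm(cand) > r:  # corner case: clamp inside
                    cand = cand / np.linalg.norm(cand) * (r - 1e-9)
        else:
            for i, L in enumerate(box):
                if cand[i] < -L / 2 or cand[i] > L / 2:
                    v[k:, i] = -v[k:, i]
                    cand = p + v[k] * dt
                    cand[i] = np.clip(cand[i], -L / 2 + 1e-9, L / 2 - 1e-9)
        p = cand
        pos[k] = p
    t = np.arange(1, n + 1) * dt
    return pd.DataFrame({"t": t, "x": pos[:, 0], "y": pos[:, 1], "vx": v[:, 0], "vy": v[:, 1]})


def gen_grating(
    direction: str,
    spatial_freq: float,
    speed: float,
    grid: int,
    duration: float,
    dt: float,
) -> np.ndarray:
    """Drifting unit-amplitude sinusoidal grating.

    Returns an array of shape (T, grid, grid): frames of
    sin(2 pi f (u - s t)) where u is the coordinate along the drift
    direction ('up' | 'down' | 'left' | 'right').
    """
    axis = {"up": 1, "down": 1, "left": 0, "right": 0}[direction]
    sign = {"up": -1.0, "down": 1.0, "left": 1.0, "right": -1.0}[direction]
    n = int(round(duration / dt))
    coords = np.linspace(0, 1, grid, endpoint=False)
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    u = xx if axis == 0 else yy
    t = np.arange(n)[:, None, None] * dt
    return np.sin(2 * np.pi * spatial_freq * (u[None] + sign * speed * t))


def trajectory_to_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def trajectory_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
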