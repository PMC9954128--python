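"""Path integration and trajectory (temporal) integration with SSPs.

In the frequency domain the encoding of the agent's position is a bank of
unit phasors; moving with velocity v rotates phasor j at angular rate
a_j . v (a velocity-controlled oscillator).  The ideal integrator applies
those rotations exactly; the neural integrator realizes each conjugate
pair's rotation with a recurrently connected spiking population that
represents (Re, Im, normalized rate) and whose recurrent weights are solved
by least squares through the synaptic low-pass.

Temporal integration reuses the same machinery with constant baseline
rotation rates b: the memory Phi accumulates the encoding of the present
value while continuously shifting old content further into the past,
Phi' = IDFT{ib} (*) Phi + phi(x(t)) — a linear (circulant / block-rotation)
system, the same dynamics matrix family as the Modified Fourier basis
generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import Network
from .populations import Population, make_population
from .solvers import SynapticFilter, sample_training_signals, solve_decoders
from .ssp import SSPSpace

__all__ = [
    "path_integrate_ideal",
    "path_integrate_neural",
    "make_time_phases",
    "encode_spacetime",
    "temporal_integrate",
    "trajectory_similarity_map",
    "neural_temporal_integrator",
]


def _pairs_to_vector(space: SSPSpace, phasors: np.ndarray) -> np.ndarray:
    """Assemble the real d-vector from positive-frequency phasors."""
    d = space.d
    spec = np.empty(d, dtype=complex)
    spec[0] = 1.0
    spec[1 : space.n_pairs + 1] = phasors
    spec[space.n_pairs + 1 :] = np.conj(phasors[::-1])
    return np.fft.ifft(spec).real


def path_integrate_ideal(
    space: SSPSpace,
    x0: np.ndarray,
    velocity: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Exact phase-rotation stepping of the velocity-controlled oscillators.

    velocity : (T, m) sampled at dt.  Returns (T, d) SSP trajectory; step k
    multiplies each positive-frequency phasor by exp(i a_j . v_k dt), so a
    constant velocity reproduces encode(x0 + v T) exactly and the phasor
    magnitudes never drift.
    """
    velocity = np.atleast_2d(np.asarray(velocity, dtype=float))
    A_free = space.free_rows  # (n_pairs, m)
    phasors = np.exp(1j * (A_free @ np.asarray(x0, dtype=float)))
    out = np.empty((velocity.shape[0], space.d))
    for k, v in enumerate(velocity):
        phasors = phasors * np.exp(1j * (A_free @ v) * dt)
        out[k] = _pairs_to_vector(space, phasors)
    return out


def _oscillator_population(
    n: int, seed: int, max_rates=(100.0, 200.0)
) -> Population:
    # 3-D representation (Re, Im, normalized rotation rate)
    return make_population(n, 3, rng=seed, max_rates=max_rates)


def path_integrate_neural(
    space: SSPSpace,
    x0: np.ndarray,
    velocity: np.ndarray,
    dt: float = 1e-3,
    neurons_per_oscillator: int = 500,
    tau: float = 0.1,
    omega_max: Optional[float] = None,
    decode_bounds: Optional[Sequence[tuple[float, float]]] = None,
    decode_every: int = 100,
    seed: int = 0,
) -> dict:
    """Spiking path integrator: one recurrent population per conjugate pair.

    Population j represents z = (Re phasor_j, Im phasor_j, u_j) with
    u_j = a_j . v / omega_max the normalized rotation rate (fed as input).
    The recurrent connection, solved through the synaptic low-pass of time
    constant ``tau``, realizes the nonlinear rotation
    (Re, Im)' = omega_max u (-Im, Re).  All oscillator populations share one
    solved weight set (they realize identical dynamics) and are simulated as
    a batch.  The position is read off the decoded SSP by similarity-grid
    search every ``decode_every`` steps.

    Returns dict with keys: ssp (T_dec, d), positions (T_dec, m),
    times (T_dec,), reliable (T_dec,) bool.
    """
    velocity = np.atleast_2d(np.asarray(velocity, dtype=float))
    T = velocity.shape[0]
    A_free = space.free_rows
    n_osc = A_free.shape[0]
    # per-oscillator rate range: oscillator j never sees |a_j . v| above its
    # own bound, so its represented rate stays well spread over [-1, 1]
    if omega_max is None:
        omega_max_j = 1.05 * np.abs(A_free @ velocity.T).max(axis=1)
    else:
        omega_max_j = np.full(n_osc, float(omega_max))
    omega_max_j = np.maximum(omega_max_j, 1e-6)
    if decode_bounds is None:
        decode_bounds = [(-1.0, 1.0)] * space.m

    pop = _oscillator_population(neurons_per_oscillator, seed)
    rng = np.random.default_rng(seed + 1)

    # train where the state actually lives: phasors near the unit circle,
    # normalized rates over [-1, 1].  The recurrent target decomposes into a
    # product term (the rotation), a radial stabilizer kappa (1 - |z|^2) z
    # counteracting amplitude drift of the decoded limit cycle, and the
    # identity; solving the three readouts separately lets every oscillator
    # share one solved population despite different rate scalings.
    kappa = 10.0
    N = 4000
    ang = rng.uniform(-np.pi, np.pi, N)
    rad = rng.uniform(0.6, 1.25, N)
    re, im = rad * np.cos(ang), rad * np.sin(ang)
    u = rng.uniform(-1, 1, N)
    Z = np.stack([re, im, u], axis=1)
    r2 = re**2 + im**2
    D_prod, _ = solve_decoders(pop, np.stack([u * (-im), u * re], axis=1), Z, reg=0.01)
    D_rad, _ = solve_decoders(pop, np.stack([(1 - r2) * re, (1 - r2) * im], axis=1), Z, reg=0.01)
    D_id, _ = solve_decoders(pop, Z[:, :2], Z, reg=0.01)

    from .neurons import LIFState, lif_spike_step

    # batched simulation across oscillators: states (n_osc, n)
    n = pop.n
    state = LIFState.zeros(n_osc * n)
    filt_rec = np.zeros((n_osc, 2))  # filtered recurrent decode
    filt_in = np.zeros((n_osc, 1))  # filtered rate input
    a_syn = np.exp(-dt / tau)

    phas0 = np.exp(1j * (A_free @ np.asarray(x0, dtype=float)))
    # initialize the filtered recurrent value at the encoded start position
    filt_rec[:, 0] = phas0.real
    filt_rec[:, 1] = phas0.imag

    enc = pop.encoders  # (n, 3)
    gains, biases = pop.gains, pop.biases
    prod_scale = (tau * omega_max_j)[:, None]
    out_ssp, out_pos, out_t, out_rel = [], [], [], []
    readout = np.zeros((n_osc, 2))
    for k in range(T):
        u_k = (A_free @ velocity[k]) / omega_max_j  # (n_osc,)
        filt_in = a_syn * filt_in + (1 - a_syn) * u_k[:, None]
        x_rep = np.concatenate([filt_rec, filt_in], axis=1)  # (n_osc, 3)
        J = gains * (x_rep @ enc.T) + biases
        sp = lif_spike_step(state, J.ravel(), dt, pop.neuron_model).reshape(n_osc, n) / dt
        dec_rec = prod_scale * (sp @ D_prod.T) + tau * kappa * (sp @ D_rad.T) + sp @ D_id.T
        dec_state = sp @ D_id.T
        filt_rec = a_syn * filt_rec + (1 - a_syn) * dec_rec
        readout = a_syn * readout + (1 - a_syn) * dec_state
        if (k + 1) % decode_every == 0:
            phasors = readout[:, 0] + 1j * readout[:, 1]
            v_ssp = _pairs_to_vector(space, phasors)
            x_hat, peak, rel = space.decode(v_ssp, decode_bounds)
            out_ssp.append(v_ssp)
            out_pos.append(x_hat)
            out_t.append((k + 1) * dt)
            out_rel.append(rel)
    return {
        "ssp": np.asarray(out_ssp),
        "positions": np.asarray(out_pos),
        "times": np.asarray(out_t),
        "reliable": np.asarray(out_rel),
    }


def make_time_phases(
    space: SSPSpace, time_scale: float = 1.0, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Baseline rotation rates b (rad/s per component) for spacetime coding.

    Built like a 1-D stratified phase draw with length scale ``time_scale``
    (seconds per radian), returned as the free (positive-frequency) rates of
    length n_pairs.
    """
    rng = np.random.default_rng(seed)
    n_free = space.n_pairs
    u = (rng.permutation(n_free) + rng.random(n_free)) / n_free
    return (2 * np.pi * u - np.pi) / time_scale


def encode_spacetime(space: SSPSpace, b_free: np.ndarray, x, t: float) -> np.ndarray:
    """Joint encoding IDFT exp(i (A x + b t)); equals bind(phi(x), phi_time(t))."""
    x = np.asarray(x, dtype=float)
    phases = space.free_rows @ x + b_free * t
    return _pairs_to_vector(space, np.exp(1j * phases))


def temporal_integrate(
    space: SSPSpace,
    b_free: np.ndarray,
    xs: np.ndarray,
    dt: float,
    decay: float = 0.0,
) -> np.ndarray:
    """Step the trajectory memory Phi' = IDFT{ib} (*) Phi + phi(x(t)).

    Frequency-domain stepping: component j rotates by exp(i b_j dt) per step
    and accumulates the encoding of the current value (times dt).  With
    b = 0 this is a pure running sum of encodings.  ``decay`` adds an
    optional forgetting rate (1/s); default none.  Returns (T, d).
    """
    xs = np.atleast_2d(np.asarray(xs, dtype=float))
    T = xs.shape[0]
    rot = np.exp((1j * b_free - decay) * dt)
    phi_freq = np.exp(1j * (xs @ space.free_rows.T))  # (T, n_pairs)
    mem = np.zeros(space.n_pairs, dtype=complex)
    dc = 0.0
    dc_decay = np.exp(-decay * dt)
    out = np.empty((T, space.d))
    for k in range(T):
        mem = rot * mem + phi_freq[k] * dt
        dc = dc * dc_decay + dt  # zero-frequency channel (unit DC per encoding)
        out[k] = _pairs_to_vector_with_dc(space, mem, dc)
    return out


def _pairs_to_vector_with_dc(space: SSPSpace, phasors: np.ndarray, dc: float | None) -> np.ndarray:
    """Like _pairs_to_vector but with an explicit zero-frequency accumulator.

    The memory's DC component integrates 1 per second of input (each
    encoding has unit DC), which the pair-only bookkeeping must restore.
    """
    d = space.d
    spec = np.empty(d, dtype=complex)
    spec[0] = dc if dc is not None else 0.0
    spec[1 : space.n_pairs + 1] = phasors
    spec[space.n_pairs + 1 :] = np.conj(phasors[::-1])
    return np.fft.ifft(spec).real


def trajectory_similarity_map(
    space: SSPSpace,
    b_free: np.ndarray,
    Phi: np.ndarray,
    value_grid: np.ndarray,
    lag_grid: np.ndarray,
) -> np.ndarray:
    """Similarity surface S[lag, value] = Phi . phi(value, lag).

    A sample stored at time tau carries the accumulated rotation for its
    elapsed time, so probing at elapsed lag L recalls x(t_now - L): the
    memory of a trajectory shows a ridge along (L, x(t_now - L)), blurring
    at older lags.
    """
    S = np.empty((lag_grid.size, value_grid.size))
    for i, lag in enumerate(lag_grid):
        for j, val in enumerate(value_grid):
            probe = encode_spacetime(space, b_free, np.atleast_1d(val), lag)
            S[i, j] = float(Phi @ probe)
    return S


def neural_temporal_integrator(
    space: SSPSpace,
    b_free: np.ndarray,
    xs: np.ndarray,
    dt: float = 1e-3,
    neurons_per_pair: int = 300,
    tau: float = 0.1,
    radius: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Spiking realization of the trajectory memory.

    Each conjugate pair's (Re, Im) sub-state rotates at the fixed rate b_j;
    because the rates are constant the dynamics are linear and the
    population only needs to represent (Re, Im).  The recurrent transform is
    the low-pass-compensated rotation tau*A + I; the drive phi(x(t)) enters
    through the input transform tau*B = tau*I.  The DC channel is a pure
    integral of the input and is accumulated directly.  Returns the decoded
    memory (T, d), scaled back to the ideal integrator's units.
    """
    from .neurons import LIFState, lif_spike_step

    xs = np.atleast_2d(np.asarray(xs, dtype=float))
    T = xs.shape[0]
    n_pairs = space.n_pairs
    pop = make_population(neurons_per_pair, 2, rng=seed)
    rng = np.random.default_rng(seed + 1)
    Z = sample_training_signals(2, 1500, seed=rng, radius=1.1)
    # per-pair rotation differs only by the angle; solve one decoder for the
    # identity readout and apply the rotation as a 2x2 transform on it
    D_id, _ = solve_decoders(pop, None, Z, reg=0.01)

    n = pop.n
    state = LIFState.zeros(n_pairs * n)
    filt = np.zeros((n_pairs, 2))
    a_syn = np.exp(-dt / tau)
    phi_freq = np.exp(1j * (xs @ space.free_rows.T))  # (T, n_pairs)
    cosb, sinb = np.cos(b_free), np.sin(b_free)
    M = np.empty((n_pairs, 2, 2))  # tau*A + I per pair
    M[:, 0, 0] = 1.0
    M[:, 1, 1] = 1.0
    M[:, 0, 1] = -tau * b_free
    M[:, 1, 0] = tau * b_free
    enc, gains, biases = pop.encoders, pop.gains, pop.biases
    out = np.empty((T, space.d))
    dc = 0.0
    readout = np.zeros((n_pairs, 2))
    for k in range(T):
        inp = np.stack([phi_freq[k].real, phi_freq[k].imag], axis=1)  # (n_pairs, 2)
        x_rep = filt  # represented (Re, Im) / radius
        J = gains * (x_rep @ enc.T) + biases
        sp = lif_spike_step(state, J.ravel(), dt, pop.neuron_model).reshape(n_pairs, n) / dt
        dec = sp @ D_id.T  # (n_pairs, 2) decoded state (normalized units)
        rec = np.einsum("pij,pj->pi", M, dec)
        drive = rec + tau * inp / radius
        filt = a_syn * filt + (1 - a_syn) * drive
        readout = a_syn * readout + (1 - a_syn) * dec
        dc += dt
        # deconvolve the readout low-pass at each component's baseline
        # rotation rate (transfer 1/(1 + i tau b) on a rotating phasor)
        phasors = (readout[:, 0] + 1j * readout[:, 1]) * (1 + 1j * tau * b_free) * radius
        out[k] = _pairs_to_vector_with_dc(space, phasors, dc)
    return out
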