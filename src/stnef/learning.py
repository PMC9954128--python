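"""Online error-driven learning: PES and the Learned Legendre Predictor.

PES is a delta rule on decoders, delta_w_i = -lr * a_i * err, applied to the
readout of a spiking population whose represented error is supplied by the
experiment.  The pendulum task wires it to a recurrent population with
time-cell tuning (two Legendre-delay systems over torque and delayed angle
in one population) to learn the arm's present angle from delayed feedback.

The LLP predicts a whole future window: prediction coefficients M map the
context activity to Legendre coefficients of the predicted trajectory over
[t, t + theta].  Because the error for a prediction only becomes available
once the future arrives, the rule keeps Legendre-delay memories of the past
activities and past prediction coefficients; when an observation z(t)
arrives it is compared, across stored lags r, against what was predicted
for time t at time t - r, and M moves along the (linear) gradient expressed
entirely through Legendre-basis evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import eval_legendre

from .lti import LTISystem, discretize, make_ldn
from .neurons import LIFState, lif_spike_step
from .populations import Population, make_population, static_tuning
from .solvers import solve_decoders, sample_training_signals
from .synthetic import PendulumParams, gen_pendulum, gen_bouncing_ball
from .ssp import make_encoding_matrix, bind

__all__ = [
    "PESState",
    "pes_update",
    "run_pendulum_prediction",
    "LLPState",
    "llp_update",
    "llp_predict",
    "find_stable_learning_rate",
    "run_ball_prediction",
]


# ---------------------------------------------------------------------------
# PES


@dataclass
class PESState:
    """Decoders being learned plus the learning rate."""

    decoders: np.ndarray  # (dim_out, n)
    learning_rate: float

    def __post_init__(self) -> None:
        self.decoders = np.atleast_2d(np.asarray(self.decoders, dtype=float))


def pes_update(state: PESState, activities: np.ndarray, error: np.ndarray, dt: float) -> PESState:
    """delta_w_i = -lr/n * a_i * error, scaled by dt.

    ``error`` is the represented-space error (prediction minus target), so
    positive error with positive activity decreases the weight.
    """
    a = np.asarray(activities, dtype=float)
    e = np.atleast_1d(np.asarray(error, dtype=float))
    state.decoders -= state.learning_rate / a.size * np.outer(e, a) * dt
    return state


# ---------------------------------------------------------------------------
# Pendulum prediction (PES + dual-LDN time-cell population)


def run_pendulum_prediction(
    duration: float = 200.0,
    dt: float = 1e-3,
    seed: int = 0,
    n_neurons: int = 1000,
    q: int = 7,
    theta: float = 0.5,
    sensory_delay: float = 0.05,
    learning_rate: float = 0.01,
    tau_rec: float = 0.05,
    tau_readout: float = 0.05,
    pendulum: PendulumParams = PendulumParams(),
    torque_rms: float = 1.0,
    torque_bandwidth_hz: float = 1.0,
    torque_input: bool = True,
) -> dict:
    """Learn the pendulum's current angle online from torque and delayed angle.

    A single recurrent spiking population realizes two Legendre-delay
    systems (order ``q``, window ``theta``) over the two input channels, so
    its neurons have time-cell tuning over the joint stimulus history.  PES
    learns the readout of the current angle phi(t) from all-zero initial
    decoders; the error is the difference between the prediction and the
    true angle.  Reports the RMSE over the final quarter, normalized by the
    angle's RMS.
    """
    rng = np.random.default_rng(seed)
    trace = gen_pendulum(
        duration,
        dt,
        seed=rng,
        params=pendulum,
        torque_rms=torque_rms,
        torque_bandwidth_hz=torque_bandwidth_hz,
        sensory_delay=sensory_delay,
    )
    torque = trace["torque"].to_numpy()
    phi = trace["phi"].to_numpy()
    phi_delayed = trace["phi_delayed"].to_numpy()

    # normalize the two input channels to unit-ish range
    u_scales = np.array([3 * torque.std(), 3 * max(phi_delayed.std(), 1e-9)])
    U = np.stack([torque, phi_delayed], axis=1) / u_scales
    if not torque_input:
        U[:, 0] = 0.0  # ablation: the plant still feels the torque, the
        # network does not see it

    # two identical LDNs stacked block-diagonally; the represented state is
    # diag-normalized so the population tuning covers it
    ldn = make_ldn(q, theta)
    A_blk = np.kron(np.eye(2), ldn.A)
    B_blk = np.kron(np.eye(2), ldn.B)
    Ad = np.kron(np.eye(2), discretize(ldn, dt)[0])
    Bd = np.kron(np.eye(2), discretize(ldn, dt)[1])
    # reference (ideal) state trajectory to calibrate the normalization
    X = np.empty((U.shape[0], 2 * q))
    x = np.zeros(2 * q)
    for k in range(U.shape[0]):
        x = Ad @ x + Bd @ U[k]
        X[k] = x
    scale = 1.0 / np.maximum(3 * X.std(axis=0), 1e-9)
    S = np.diag(scale)
    S_inv = np.diag(1.0 / scale)

    sys2 = LTISystem(S @ A_blk @ S_inv, S @ B_blk, theta, label="dual-LDN")
    A_rec = tau_rec * sys2.A + np.eye(2 * q)  # low-pass compensated recurrence
    B_in = tau_rec * sys2.B

    pop = make_population(n_neurons, 2 * q, rng=rng)
    Z = sample_training_signals(2 * q, 4000, seed=rng, radius=1.0)
    D_id, _ = solve_decoders(pop, None, Z, reg=0.01)

    state = LIFState.zeros(n_neurons)
    state.voltage = rng.random(n_neurons)
    a_rec = np.exp(-dt / tau_rec)
    a_out = np.exp(-dt / tau_readout)
    filt_state = np.zeros(2 * q)
    pes = PESState(np.zeros((1, n_neurons)), learning_rate)
    # the learned readout runs on synaptically filtered activities: raw
    # spike trains would bias the delta-rule equilibrium through their shot
    # noise (the filtered trains are what a downstream synapse sees anyway)
    filt_act = np.zeros(n_neurons)
    predictions = np.empty(U.shape[0])
    enc, gains, biases = pop.encoders, pop.gains, pop.biases
    for k in range(U.shape[0]):
        x_rep = filt_state  # synapse-filtered recurrent + input drive
        J = gains * (enc @ x_rep) + biases
        spikes = lif_spike_step(state, J, dt, pop.neuron_model) / dt
        dec = D_id @ spikes
        drive = A_rec @ dec + B_in @ (U[k])
        filt_state = a_rec * filt_state + (1 - a_rec) * drive
        filt_act = a_out * filt_act + (1 - a_out) * spikes
        pred = float((pes.decoders @ filt_act)[0])
        predictions[k] = pred
        error = pred - phi[k]
        pes_update(pes, filt_act, error, dt)

    n_last = U.shape[0] // 4
    sl = slice(U.shape[0] - n_last, None)
    rmse = float(np.sqrt(np.mean((predictions[sl] - phi[sl]) ** 2)))
    nrmse = rmse / float(np.sqrt(np.mean(phi[sl] ** 2)))
    return {
        "nrmse": nrmse,
        "rmse": rmse,
        "predictions": predictions,
        "phi": phi,
        "t": trace["t"].to_numpy(),
        "error_trace": predictions - phi,
        "diverged": bool(nrmse > 1.0),
    }


# ---------------------------------------------------------------------------
# LLP


def _legendre_basis(q: int, r: np.ndarray) -> np.ndarray:
    """phi_q(r) = P_q(2 r - 1) for normalized window position r in [0, 1]."""
    i = np.arange(q)
    return eval_legendre(i[None, :], 2 * np.asarray(r, dtype=float)[:, None] - 1)


@dataclass
class LLPState:
    """Prediction coefficients plus the Legendre-delay memories.

    M : (n, q, o) maps activities to Legendre coefficients of the predicted
        trajectory of the o-dimensional observation over [t, t + theta].
    mem_act : (q_a, n) LDN memory of the activity history.
    mem_coef : (q_a, q * o) LDN memory of the history of emitted coefficients.
    """

    M: np.ndarray
    theta: float
    learning_rate: float
    mem_act: np.ndarray
    mem_coef: np.ndarray
    Ad: np.ndarray
    Bd: np.ndarray
    lag_fracs: np.ndarray
    lag_decoders: np.ndarray  # (K, q_a): activity/coef memory readout at lags
    lead_basis: np.ndarray  # (K, q): prediction basis evaluated at the lags
    lead_basis_pre: np.ndarray  # lead basis times the inverse lag Gram matrix

    @classmethod
    def create(
        cls,
        n: int,
        q: int,
        obs_dim: int,
        theta: float,
        dt: float,
        learning_rate: float,
        q_a: int = 12,
        n_lags: int = 16,
    ) -> "LLPState":
        ldn = make_ldn(q_a, theta)
        Ad, Bd = discretize(ldn, dt)
        fr = (np.arange(n_lags) + 0.5) / n_lags  # lag fractions r/theta
        from .lti import delay_readout

        lag_dec = np.stack([delay_readout(ldn, f * theta) for f in fr])
        lead = _legendre_basis(q, fr)
        # precondition the update by the inverse Gram of the lead basis at
        # the lags (normalized LMS): leaves the rule's fixed point unchanged
        # but equalizes convergence speed across Legendre orders
        gram = lead.T @ lead / n_lags
        lead_pre = lead @ np.linalg.inv(gram)
        return cls(
            M=np.zeros((n, q, obs_dim)),
            theta=theta,
            learning_rate=learning_rate,
            mem_act=np.zeros((q_a, n)),
            mem_coef=np.zeros((q_a, q * obs_dim)),
            Ad=Ad,
            Bd=Bd,
            lag_fracs=fr,
            lag_decoders=lag_dec,
            lead_basis=lead,
            lead_basis_pre=lead_pre,
        )


def llp_predict(state: LLPState, activities: np.ndarray, leads: np.ndarray) -> np.ndarray:
    """Evaluate the current predicted trajectory at lead times in [0, theta]."""
    coef = np.einsum("nqo,n->qo", state.M, activities)
    basis = _legendre_basis(state.M.shape[1], np.asarray(leads, dtype=float) / state.theta)
    return basis @ coef.reshape(state.M.shape[1], -1)


def llp_update(state: LLPState, activities: np.ndarray, observation: np.ndarray, dt: float) -> LLPState:
    """One step of the LLP: emit coefficients, learn from the arriving truth.

    The observation z(t) is compared against the predictions that were made
    for time t across the stored lags r (decoded from the coefficient
    memory); the gradient step on M routes the per-lag errors through the
    stored activities (decoded from the activity memory) and the Legendre
    basis at the corresponding leads.  Everything is linear in the stored
    quantities; no observation later than t is used.
    """
    a = np.asarray(activities, dtype=float)
    z = np.atleast_1d(np.asarray(observation, dtype=float))
    n, q, o = state.M.shape
    # error across stored lags
    a_past = state.lag_decoders @ state.mem_act  # (K, n)
    c_past = (state.lag_decoders @ state.mem_coef).reshape(-1, q, o)  # (K, q, o)
    z_hat = np.einsum("kq,kqo->ko", state.lead_basis, c_past)  # (K, o)
    err = z[None, :] - z_hat  # (K, o)
    w = dt / state.lag_fracs.size
    state.M += state.learning_rate * w * np.einsum(
        "kn,kq,ko->nqo", a_past, state.lead_basis_pre, err
    )
    # emit current coefficients and push everything into the memories
    coef = np.einsum("nqo,n->qo", state.M, a)
    state.mem_act = state.Ad @ state.mem_act + np.outer(state.Bd[:, 0], a)
    state.mem_coef = state.Ad @ state.mem_coef + np.outer(state.Bd[:, 0], coef.ravel())
    return state


def find_stable_learning_rate(
    run: Callable[[float], float],
    start: float = 1e-5,
    factor: float = 2.0,
    max_steps: int = 12,
) -> float:
    """Doubling search for the largest stable learning rate.

    ``run`` maps a learning rate to a final normalized error; a rate is
    unstable when the error is not finite or exceeds 1 (worse than
    predicting zero).  Returns the largest tested stable rate.
    """
    best = None
    lr = start
    for _ in range(max_steps):
        score = run(lr)
        if np.isfinite(score) and score <= 1.0:
            best = lr
            lr *= factor
        else:
            break
    if best is None:
        raise RuntimeError("no stable learning rate found at or above the start value")
    return best


# ---------------------------------------------------------------------------
# Bouncing-ball prediction experiment


def _context_activities(
    context: str,
    positions: np.ndarray,
    velocities: np.ndarray,
    dt: float,
    n_ctx: int,
    seed: int,
    theta_ctx: float = 0.5,
    q_ctx: int = 6,
    ssp_dim: int = 61,
    ssp_length_scale: float = 0.3,
) -> np.ndarray:
    """Rate-neuron activities for the three context encodings."""
    rng = np.random.default_rng(seed)
    T = positions.shape[0]
    if context == "ldn_linear":
        # raw Legendre-delay features plus a constant channel: a linear
        # readout control for which straight-line extrapolation is exactly
        # representable
        ldn = make_ldn(q_ctx, theta_ctx)
        Ad, Bd = discretize(ldn, dt)
        X = np.empty((T, 2 * q_ctx))
        x = np.zeros((q_ctx, 2))
        for k in range(T):
            x = Ad @ x + Bd @ positions[k][None, :]
            X[k] = x.ravel(order="F")
        X /= np.maximum(3 * np.abs(X).max(axis=0), 1e-9)
        return np.hstack([X, np.ones((T, 1))])
    if context == "ldn":
        ldn = make_ldn(q_ctx, theta_ctx)
        Ad, Bd = discretize(ldn, dt)
        X = np.empty((T, 2 * q_ctx))
        x = np.zeros((q_ctx, 2))
        centered = positions - 0.5
        for k in range(T):
            x = Ad @ x + Bd @ centered[k][None, :]
            X[k] = x.ravel(order="F")
        X /= np.maximum(3 * X.std(axis=0), 1e-9)
        feats = X
    elif context == "ssp":
        space = make_encoding_matrix(ssp_dim, 2, "random", ssp_length_scale, seed=rng)
        feats = space.encode(positions)
    elif context == "ssp_speed":
        space_p = make_encoding_matrix(ssp_dim, 2, "random", ssp_length_scale, seed=rng)
        space_v = make_encoding_matrix(ssp_dim, 2, "random", 1.0, seed=rng)
        fp = space_p.encode(positions)
        fv = space_v.encode(velocities)
        feats = np.stack([bind(fp[k], fv[k]) for k in range(T)])
    else:
        raise ValueError("context must be 'ldn', 'ldn_linear', 'ssp' or 'ssp_speed'")
    dim = feats.shape[1]
    pop = make_population(n_ctx, dim, rng=rng, max_rates=(60.0, 120.0), intercepts=(-0.6, 0.8))
    norms = np.linalg.norm(feats, axis=1, keepdims=True)
    feats = feats / np.maximum(norms.max(), 1e-9)
    return static_tuning(pop, feats) / 100.0  # activities in ~[0, 2]


def run_ball_prediction(
    context: str = "ldn",
    duration: float = 100.0,
    dt: float = 0.005,
    horizon: float = 0.5,
    q: int = 10,
    n_ctx: int = 250,
    learning_rate: float | None = None,
    seed: int = 0,
    walls: bool = True,
    rmse_window: float = 1.0,
) -> dict:
    """LLP learning to predict a bouncing ball 0.5 s into the future.

    Returns the hindsight windowed RMSE trace: at each time t the emitted
    predicted window [t, t + horizon] is compared against the realized path,
    and the per-step errors are averaged over ``rmse_window`` seconds.
    """
    ball = gen_bouncing_ball(duration + horizon, dt, walls=walls)
    pos = ball[["x", "y"]].to_numpy()
    vel = np.gradient(pos, dt, axis=0)
    T = int(round(duration / dt))
    acts = _context_activities(context, pos[: T], vel[: T], dt, n_ctx, seed)
    if learning_rate is None:
        # largest rate that stayed stable over long runs in the doubling search
        learning_rate = {"ldn": 1e-3, "ssp": 1e-3, "ssp_speed": 1e-3, "ldn_linear": 0.2}[context]
    state = LLPState.create(acts.shape[1], q, 2, horizon, dt, learning_rate)
    leads = np.linspace(0, horizon, 11)
    errs = np.empty(T)
    lead_steps = (leads / dt).round().astype(int)
    for k in range(T):
        llp_update(state, acts[k], pos[k], dt)
        zhat = llp_predict(state, acts[k], leads)  # (len(leads), 2)
        future = pos[k + lead_steps]
        errs[k] = float(np.sqrt(np.mean(np.sum((zhat - future) ** 2, axis=1))))
    w = max(1, int(round(rmse_window / dt)))
    kernel = np.ones(w) / w
    windowed = np.convolve(errs, kernel, mode="valid")
    return {
        "windowed_rmse": windowed,
        "raw_rmse": errs,
        "t": np.arange(1, T + 1) * dt,
        "learning_rate": learning_rate,
    }
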