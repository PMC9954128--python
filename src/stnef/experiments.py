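"""End-to-end experiment drivers shared by the CLI, tests and acceptance
runs.

Each driver generates its own inputs, builds and simulates the network, and
returns the measured quantities in a plain dict.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .cells import grid_cell_population, gridness_score, rate_map
from .engine import Network
from .lti import LTISystem, delay_readout, discretize, make_ldn
from .neurons import LIFState, lif_spike_step
from .populations import Population, make_population, static_tuning
from .solvers import (
    SynapticFilter,
    band_limited_noise,
    sample_training_signals,
    solve_decoders,
    solve_temporal_weights,
)
from .ssp import make_encoding_matrix
from .synthetic import gen_trajectory_2d

__all__ = [
    "run_time_cells",
    "run_grid_cells",
    "run_path_integration",
    "run_trajectory_memory",
    "run_kde",
    "run_square_network",
]


def run_time_cells(
    n_neurons: int = 200,
    q: int = 7,
    theta: float = 0.5,
    dt: float = 1e-3,
    seed: int = 0,
    off_fraction: float = 0.5,
    pulse_width: float = 0.05,
    settle: float = 0.05,
) -> dict:
    """Recurrent spiking time-cell network from Legendre-delay encoders.

    Each neuron is assigned a target delay theta_i (biased toward shorter
    delays); its temporal encoder is the delay readout of the Legendre-delay
    state at theta_i, i.e. a bump at that lag, realized as a static encoder
    over the (normalized) q-dimensional state.  Half the neurons are
    "off"-neurons responding to negative pulses.  Recurrent and input
    weights are solved by the full temporal regression; the network is then
    pulsed and per-neuron peak times are compared with the assigned delays.
    """
    rng = np.random.default_rng(seed)
    ldn = make_ldn(q, theta)

    # normalize the state scale against the response to the test pulse, so
    # encoder similarities sweep through ~[0, 1] during the experiment
    Ad, Bd = discretize(ldn, dt)
    n_ref = int(2 * theta / dt)
    u_ref = np.zeros(n_ref)
    u_ref[: int(pulse_width / dt)] = 1.0
    x = np.zeros(q)
    X = np.empty((n_ref, q))
    for k in range(n_ref):
        x = Ad @ x + Bd[:, 0] * u_ref[k]
        X[k] = x
    scale = 1.0 / np.maximum(np.abs(X).max(axis=0), 1e-9)
    S = np.diag(scale)
    sysn = LTISystem(S @ ldn.A @ np.diag(1.0 / scale), S @ ldn.B, theta, label="LDN")

    # delays biased toward shorter values; spread grows with the delay
    theta_i = theta * rng.beta(1.5, 2.5, n_neurons)
    encoders = np.empty((n_neurons, q))
    off = rng.random(n_neurons) < off_fraction
    for i in range(n_neurons):
        w = delay_readout(ldn, theta_i[i]) / scale  # readout on normalized state
        w = w / np.linalg.norm(w)
        encoders[i] = -w if off[i] else w
    pop = make_population(
        n_neurons, q, rng=rng, encoders=encoders, intercepts=(0.0, 0.6), max_rates=(100.0, 200.0)
    )

    # probe with both pulses (the test condition) and gentle noise so the
    # regression covers the visited region of state space
    n_probe = int(4 * theta / dt)
    probe_list = []
    for _ in range(6):
        p = np.zeros(n_probe)
        onset = rng.integers(0, n_probe // 2)
        width = rng.integers(int(0.02 / dt), int(0.1 / dt))
        p[onset : onset + width] = rng.choice([-1.0, 1.0])
        probe_list.append(p)
    for _ in range(6):
        probe_list.append(band_limited_noise(n_probe, dt, 5.0, rng, rms=0.3))
    probes = np.stack(probe_list)
    W_rec, W_in, res = solve_temporal_weights(
        pop, sysn, probes, dt, filter=SynapticFilter("exponential", 0.1), reg=0.01
    )

    # pulse response of the spiking network
    T = int((theta * 1.6 + settle + pulse_width) / dt)
    state = LIFState.zeros(n_neurons)
    state.voltage = rng.random(n_neurons)
    tau = 0.1
    a_syn = np.exp(-dt / tau)
    filt_a = np.zeros(n_neurons)
    filt_u = 0.0
    acts = np.empty((T, n_neurons))
    read_tau = 0.02
    a_read = np.exp(-dt / read_tau)
    read = np.zeros(n_neurons)
    for k in range(T):
        t = k * dt
        u = 1.0 if settle <= t < settle + pulse_width else 0.0
        J = W_rec @ filt_a + W_in[:, 0] * filt_u + pop.biases
        spikes = lif_spike_step(state, J, dt, pop.neuron_model) / dt
        filt_a = a_syn * filt_a + (1 - a_syn) * spikes
        filt_u = a_syn * filt_u + (1 - a_syn) * u
        read = a_read * read + (1 - a_read) * spikes
        acts[k] = read

    on_idx = np.flatnonzero(~off)
    t_grid = np.arange(T) * dt - settle
    peaks = np.array([t_grid[np.argmax(acts[:, i])] for i in on_idx])
    peak_rates = acts[:, on_idx].max(axis=0)
    active = peak_rates > 5.0  # Hz; silent neurons carry no timing signal
    rho = float(spearmanr(theta_i[on_idx][active], peaks[active]).statistic)

    # unimodality: count prominent peaks of the smoothed activity (spike
    # noise produces shallow ripples that do not count as extra modes)
    from scipy.signal import find_peaks

    kern = np.ones(int(0.05 / dt))
    kern /= kern.size

    def n_modes(trace: np.ndarray) -> int:
        sm = np.convolve(trace, kern, mode="same")
        pk, _ = find_peaks(sm, prominence=0.35 * sm.max())
        return max(1, len(pk))

    unimodal = np.array([n_modes(acts[:, i]) == 1 for i in on_idx[active]])
    return {
        "activities": acts,
        "theta_i": theta_i,
        "peaks": peaks,
        "on_idx": on_idx,
        "active": active,
        "spearman_rho": rho,
        "unimodal_fraction": float(unimodal.mean()),
        "solve_residual": res,
    }


def run_grid_cells(
    n_neurons: int = 40,
    sparsity: float = 0.15,
    duration: float = 300.0,
    traj_dt: float = 0.02,
    length_scale: float = 0.15,
    scale_range: tuple[float, float] = (1.0, 2.5),
    diameter: float = 1.8,
    bin_size: float = 0.06,
    seed: int = 0,
) -> dict:
    """Grid-cell rate maps on a synthetic foraging trajectory."""
    space = make_encoding_matrix(
        0, 2, "hex", length_scale=length_scale, seed=seed, scale_range=scale_range
    )
    r = diameter / 2
    arena = [(-r, r), (-r, r)]
    pop = grid_cell_population(space, n_neurons, sparsity=sparsity, arena=arena, seed=seed + 1)
    traj = gen_trajectory_2d(
        duration=duration, dt=traj_dt, arena="circle", diameter=diameter, mean_speed=0.25,
        seed=seed + 2,
    )
    pos = traj[["x", "y"]].to_numpy()
    acts = static_tuning(pop, space.encode(pos))
    maps = rate_map(acts, pos, traj_dt, bin_size=bin_size)
    gridness = np.array([gridness_score(m) for m in maps])
    return {
        "space": space,
        "population": pop,
        "maps": maps,
        "gridness": gridness,
        "positive_fraction": float((gridness > 0).mean()),
        "median_gridness": float(np.median(gridness)),
    }


def run_path_integration(
    duration: float = 60.0,
    dt: float = 1e-3,
    diameter: float = 1.8,
    d: int = 25,
    length_scale: float = 0.35,
    neurons_per_oscillator: int = 1500,
    decode_every: int = 500,
    seed: int = 0,
) -> dict:
    """Spiking path integration on a synthetic circular-arena trajectory."""
    from .dynamics import path_integrate_neural

    space = make_encoding_matrix(d, 2, "random", length_scale=length_scale, seed=seed)
    traj = gen_trajectory_2d(
        duration=duration, dt=dt, arena="circle", diameter=diameter, mean_speed=0.15,
        seed=seed + 1,
    )
    pos = traj[["x", "y"]].to_numpy()
    vel = traj[["vx", "vy"]].to_numpy()
    r = diameter / 2
    res = path_integrate_neural(
        space,
        np.zeros(2),
        vel,
        dt=dt,
        neurons_per_oscillator=neurons_per_oscillator,
        decode_bounds=[(-1.05 * r, 1.05 * r)] * 2,
        decode_every=decode_every,
        seed=seed,
    )
    idx = (res["times"] / dt).round().astype(int) - 1
    truth = pos[idx]
    err = np.linalg.norm(res["positions"] - truth, axis=1)
    return {
        "decoded": res["positions"],
        "truth": truth,
        "times": res["times"],
        "errors": err,
        "median_error": float(np.median(err)),
        "max_error": float(err.max()),
        "space": space,
        "velocity": vel,
        "positions_full": pos,
    }


def run_trajectory_memory(
    duration: float = 2.0,
    dt: float = 1e-3,
    d: int = 61,
    length_scale: float = 0.3,
    time_scale: float = 1.0,
    neurons_per_pair: int = 300,
    seed: int = 0,
) -> dict:
    """Scalar trajectory memory: ideal vs spiking temporal integration.

    The input is a ramp x(t) = t (so the similarity ridge over (lag, value)
    has slope -1); the spiking integrator is compared with the ideal one
    after a 0.5 s settle.
    """
    from .dynamics import make_time_phases, neural_temporal_integrator, temporal_integrate, trajectory_similarity_map

    space = make_encoding_matrix(d, 1, "random", length_scale=length_scale, seed=seed)
    b = make_time_phases(space, time_scale, seed=seed + 1)
    T = int(duration / dt)
    ts = np.arange(1, T + 1) * dt
    xs = ts[:, None].copy()  # ramp: value equals elapsed time
    ideal = temporal_integrate(space, b, xs, dt)
    neural = neural_temporal_integrator(
        space, b, xs, dt=dt, neurons_per_pair=neurons_per_pair, radius=2.0, seed=seed
    )
    settle = int(0.5 / dt)
    num = np.linalg.norm(neural[settle:] - ideal[settle:], axis=1)
    den = np.linalg.norm(ideal[settle:], axis=1)
    nrmse = float(np.sqrt(np.mean((num / den) ** 2)))

    lag_grid = np.linspace(0.1, duration - 0.2, 16)
    value_grid = np.linspace(0.0, duration, 81)
    S = trajectory_similarity_map(space, b, ideal[-1], value_grid, lag_grid)
    ridge_vals = value_grid[np.argmax(S, axis=1)]
    slope = float(np.polyfit(lag_grid, ridge_vals, 1)[0])
    # ridge width at half max per lag
    widths = []
    for i in range(lag_grid.size):
        row = S[i]
        half = 0.5 * row.max()
        widths.append(float((row > half).sum() * (value_grid[1] - value_grid[0])))
    return {
        "ideal": ideal,
        "neural": neural,
        "nrmse_neural": nrmse,
        "similarity_surface": S,
        "lag_grid": lag_grid,
        "value_grid": value_grid,
        "ridge_slope": slope,
        "ridge_widths": np.asarray(widths),
    }


def run_kde(
    n_samples: int = 400,
    d: int = 301,
    length_scale: float = 0.5,
    seed: int = 0,
    centers: tuple[float, float] = (-2.0, 2.0),
    sigma: float = 0.6,
) -> dict:
    """Quasi-probability KDE of a two-Gaussian mixture."""
    from .density import fit_quasi_density

    rng = np.random.default_rng(seed)
    space = make_encoding_matrix(d, 1, "random", length_scale=length_scale, seed=seed + 1)
    comp = rng.integers(0, 2, n_samples)
    data = (np.where(comp == 0, centers[0], centers[1]) + sigma * rng.standard_normal(n_samples))[
        :, None
    ]
    qd = fit_quasi_density(space, data)
    grid = np.linspace(qd.support[0][0], qd.support[0][1], 601)
    dens = qd(grid[:, None])
    truth = 0.5 * (
        np.exp(-0.5 * ((grid - centers[0]) / sigma) ** 2)
        + np.exp(-0.5 * ((grid - centers[1]) / sigma) ** 2)
    ) / (sigma * np.sqrt(2 * np.pi))
    dx = grid[1] - grid[0]
    return {
        "qd": qd,
        "grid": grid,
        "density": dens,
        "truth": truth,
        "integral": float(dens.sum() * dx),
        "iae": float(np.abs(dens - truth).sum() * dx),
    }


def run_square_network(
    n_neurons: int = 100,
    duration: float = 4.0,
    dt: float = 1e-3,
    seed: int = 0,
) -> dict:
    """Two-population spiking network computing y = x^2 through its weights."""
    net = Network(dt=dt, seed=seed)
    x_fn = lambda t: [np.sin(2 * np.pi * 0.5 * t)]
    inp = net.add_node(x_fn)
    pre = net.add_ensemble(make_population(n_neurons, 1, rng=seed), label="x")
    post = net.add_ensemble(make_population(n_neurons, 1, rng=seed + 1), label="y")
    net.connect(inp, pre, synapse=0.005)
    X = sample_training_signals(1, 400, seed=seed + 2)
    D_sq, _ = solve_decoders(pre.pop, lambda x: x**2, X)
    net.connect(pre, post, synapse=0.005, decoders=D_sq)
    D_out, _ = solve_decoders(post.pop, None, X)
    readout = net.connect(post, None, synapse=0.02, decoders=D_out)
    probe = net.probe(readout)
    net.run(duration)
    y = probe.trace()[:, 0]
    t = np.arange(1, y.size + 1) * dt
    lag = 0.032  # two feedforward synapses + readout filter
    target = np.sin(2 * np.pi * 0.5 * (t - lag)) ** 2
    sl = slice(int(0.3 / dt), None)
    nrmse = float(
        np.sqrt(np.mean((y[sl] - target[sl]) ** 2)) / np.std(target[sl])
    )
    return {"t": t, "x": np.sin(2 * np.pi * 0.5 * t), "y_decoded": y, "nrmse": nrmse}
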