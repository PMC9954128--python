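"""Neuron response models.

The leaky integrate-and-fire (LIF) neuron is the workhorse: it has a
closed-form steady-state rate response, which is what makes least-squares
weight solving cheap, while the actual spiking model is used at simulation
time.  Rate surrogates (ReLU, sigmoid) are provided for non-spiking models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LIFParams",
    "lif_rate",
    "lif_rate_inverse",
    "lif_spike_step",
    "LIFState",
    "relu_rate",
    "sigmoid_rate",
    "solve_gain_bias",
]


@dataclass(frozen=True)
class LIFParams:
    """Parameters of the leaky integrate-and-fire neuron.

    tau_rc : membrane time constant in seconds.
    tau_ref : absolute refractory period in seconds.
    v_threshold : firing threshold on the dimensionless membrane voltage
        (fixed at 1 by the usual normalization of the input current).
    """

    tau_rc: float = 0.02
    tau_ref: float = 0.002
    v_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_rc <= 0:
            raise ValueError("tau_rc must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be nonnegative")

    @property
    def max_rate_bound(self) -> float:
        """Refractory-limited firing-rate asymptote, 1/tau_ref (Hz)."""
        return np.inf if self.tau_ref == 0 else 1.0 / self.tau_ref


def lif_rate(J, params: LIFParams = LIFParams()):
    """Steady-state LIF firing rate G[J] in Hz for input current ``J``.

    Zero at and below threshold; above it,
    ``1 / (tau_ref + tau_rc * log(1 / (1 - v_th / J)))``.
    Total, continuous and nondecreasing in J.
    """
    J = np.asarray(J, dtype=float)
    out = np.zeros_like(J)
    above = J > params.v_threshold
    if np.any(above):
        Ja = J[above]
        out[above] = 1.0 / (
            params.tau_ref + params.tau_rc * np.log1p(params.v_threshold / (Ja - params.v_threshold))
        )
    return out if out.ndim else float(out)


def lif_rate_inverse(rate, params: LIFParams = LIFParams()):
    """Current J such that ``lif_rate(J) == rate`` (rate in (0, 1/tau_ref))."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate <= 0) or np.any(rate >= params.max_rate_bound):
        raise ValueError("rate must lie strictly between 0 and 1/tau_ref")
    # invert: 1/rate - tau_ref = tau_rc * log(1 + v_th/(J - v_th))
    z = np.expm1((1.0 / rate - params.tau_ref) / params.tau_rc)
    J = params.v_threshold / z + params.v_threshold
    return J if J.ndim else float(J)


def relu_rate(J, gain_hz: float = 1.0):
    """Rectified-linear rate surrogate (Hz per unit suprathreshold current)."""
    return gain_hz * np.maximum(0.0, np.asarray(J, dtype=float) - 1.0)


def sigmoid_rate(J, max_rate: float = 100.0, slope: float = 1.0):
    """Logistic rate surrogate saturating at ``max_rate`` Hz."""
    return max_rate / (1.0 + np.exp(-slope * (np.asarray(J, dtype=float) - 1.0)))


@dataclass
class LIFState:
    """Mutable per-neuron state for time-stepped LIF simulation."""

    voltage: np.ndarray
    refractory: np.ndarray  # remaining refractory time (s)

    @classmethod
    def zeros(cls, n: int) -> "LIFState":
        return cls(np.zeros(n), np.zeros(n))


def lif_spike_step(state: LIFState, J, dt: float, params: LIFParams = LIFParams()):
    """Advance the spiking LIF model one step of length ``dt``.

    Uses the exact exponential update of dV/dt = (J - V)/tau_rc over the
    non-refractory portion of the step.  Returns the number of spikes per
    neuron this step (0 or 1).  On a spike the voltage resets to 0 and the
    neuron is held for ``tau_ref``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    J = np.broadcast_to(np.asarray(J, dtype=float), state.voltage.shape)

    # portion of this step spent integrating (refractory time eats the rest)
    t_live = np.clip(dt - state.refractory, 0.0, dt)
    state.refractory = np.maximum(0.0, state.refractory - dt)

    decay = np.exp(-t_live / params.tau_rc)
    state.voltage = state.voltage * decay + J * (1.0 - decay)

    spiked = state.voltage >= params.v_threshold
    spikes = spiked.astype(float)
    if np.any(spiked):
        # exact time spent above threshold inside the step: invert the
        # exponential approach V(t) = J + (V0 - J) e^{-t/tau_rc}; crediting it
        # against the refractory hold makes the period dt-independent
        v = state.voltage[spiked]
        j = J[spiked]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_over = params.tau_rc * np.log((j - params.v_threshold) / (j - v))
        t_over = np.clip(np.nan_to_num(t_over), 0.0, dt)
        state.voltage[spiked] = 0.0
        state.refractory[spiked] = np.maximum(params.tau_ref - t_over, 0.0)
    state.voltage = np.maximum(state.voltage, -1.0)  # clamp hyperpolarization
    return spikes


def solve_gain_bias(max_rate: float, intercept: float, params: LIFParams = LIFParams()):
    """Gain alpha and bias beta realizing a tuning curve with the given
    firing onset and maximum.

    The neuron is silent for encoder similarity below ``intercept`` and fires
    at ``max_rate`` Hz at similarity 1; both conditions invert the closed-form
    rate response exactly:

        G[alpha * intercept + beta] = 0  (current at threshold)
        G[alpha * 1 + beta] = max_rate
    """
    if not (0 < max_rate < params.max_rate_bound):
        raise ValueError(f"max_rate must lie in (0, {params.max_rate_bound}) Hz")
    if not (-1 <= intercept < 1):
        raise ValueError("intercept must lie in [-1, 1)")
    J_max = lif_rate_inverse(max_rate, params)
    alpha = (J_max - params.v_threshold) / (1.0 - intercept)
    beta = params.v_threshold - alpha * intercept
    return alpha, beta
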