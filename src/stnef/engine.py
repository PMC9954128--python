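"""Time-stepped spiking-network simulator.

Deterministic execution order per step: input nodes are evaluated, spikes
and node outputs propagate through each connection's synaptic filter,
post-synaptic currents are formed (weights x filtered activity + bias),
neuron states advance, probes record.  Spike trains carry amplitude 1/dt so
their filtered versions estimate rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .neurons import LIFState, lif_spike_step
from .populations import Population
from .solvers import SynapticFilter

__all__ = ["Node", "Ensemble", "NetConnection", "Probe", "Network"]


class Node:
    """Signal source: a constant vector or a callable of time."""

    def __init__(self, output, size: Optional[int] = None, label: str = ""):
        self.fn = output if callable(output) else None
        self.const = None if callable(output) else np.atleast_1d(np.asarray(output, dtype=float))
        self.size = size if size is not None else (len(self.const) if self.const is not None else 1)
        self.label = label
        self.value = np.zeros(self.size)

    def eval(self, t: float) -> np.ndarray:
        if self.fn is not None:
            self.value = np.atleast_1d(np.asarray(self.fn(t), dtype=float))
        else:
            self.value = self.const
        return self.value


class Ensemble:
    """A population plus its spiking state inside a network."""

    def __init__(self, pop: Population, label: str = ""):
        if pop.is_temporal:
            raise ValueError("the engine simulates populations with static encoders")
        self.pop = pop
        self.label = label
        self.state = LIFState.zeros(pop.n)
        self.spikes = np.zeros(pop.n)  # amplitude 1/dt
        self.x_input = np.zeros(pop.dim)  # represented-space drive
        self.j_input = np.zeros(pop.n)  # direct current drive

    def current(self) -> np.ndarray:
        p = self.pop
        return p.gains * (p.encoders @ self.x_input) + p.biases + self.j_input


@dataclass
class PESRule:
    """Online decoder learning: delta_d = -lr/n * a * error^T per second."""

    learning_rate: float
    error: object = None  # Node or callable(t) -> error vector


class NetConnection:
    """pre -> post with a synaptic filter.

    pre: Node or Ensemble.  post: Ensemble or None (probe-only endpoint).
    Exactly one route is used:
      * decoders (dim x n_pre): the filtered decoded value enters the post
        population's represented space (optionally through ``transform``);
      * weights (n_post x n_pre): filtered spikes inject currents directly;
      * node pre: the (transformed) node output is filtered into post space.
    """

    def __init__(
        self,
        pre,
        post,
        synapse: SynapticFilter | float | None = 0.005,
        decoders: Optional[np.ndarray] = None,
        weights: Optional[np.ndarray] = None,
        transform: Optional[np.ndarray] = None,
        learning: Optional[PESRule] = None,
        label: str = "",
    ):
        self.pre, self.post, self.label = pre, post, label
        if isinstance(synapse, (int, float)):
            synapse = SynapticFilter("exponential", float(synapse)) if synapse else None
        self.synapse = synapse
        self.decoders = None if decoders is None else np.asarray(decoders, dtype=float)
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self.transform = None if transform is None else np.atleast_2d(np.asarray(transform, dtype=float))
        self.learning = learning
        self._fstate = None
        self._learn_fstate = None
        self.output = None

    def learned_activities(self, dt: float) -> np.ndarray:
        """Per-neuron pre activities filtered through this synapse (Hz)."""
        spikes = self.pre.spikes
        if self.synapse is None:
            return spikes
        if self._learn_fstate is None:
            self._learn_fstate = self.synapse.make_state(spikes.shape)
        return self.synapse.step(self._learn_fstate, spikes, dt)

    def _raw_output(self) -> np.ndarray:
        if isinstance(self.pre, Node):
            val = self.pre.value
        else:
            if self.weights is not None:
                val = self.weights @ self.pre.spikes
            elif self.decoders is not None:
                val = self.decoders @ self.pre.spikes
            else:
                raise ValueError(f"connection {self.label!r} has no decoders or weights")
        if self.transform is not None:
            val = self.transform @ val
        return val

    def propagate(self, dt: float) -> np.ndarray:
        raw = self._raw_output()
        if self.synapse is None:
            self.output = raw
        else:
            if self._fstate is None:
                self._fstate = self.synapse.make_state(raw.shape)
            self.output = self.synapse.step(self._fstate, raw, dt)
        if self.post is not None:
            if self.weights is not None:
                self.post.j_input += self.output
            else:
                self.post.x_input += self.output
        return self.output


class Probe:
    def __init__(self, target, attr: str = "output", synapse: float | None = None):
        self.target, self.attr = target, attr
        self.synapse = SynapticFilter("exponential", synapse) if synapse else None
        self._fstate = None
        self.data: list[np.ndarray] = []

    def sample(self, dt: float) -> None:
        if self.attr == "output":
            val = self.target.output if isinstance(self.target, NetConnection) else self.target.value
        elif self.attr == "spikes":
            val = self.target.spikes
        elif self.attr == "voltage":
            val = self.target.state.voltage
        else:
            raise ValueError(f"unknown probe attribute {self.attr!r}")
        val = np.asarray(val, dtype=float)
        if self.synapse is not None:
            if self._fstate is None:
                self._fstate = self.synapse.make_state(val.shape)
            val = self.synapse.step(self._fstate, val, dt)
        self.data.append(val.copy())

    def trace(self) -> np.ndarray:
        return np.asarray(self.data)


class Network:
    """Container for nodes, ensembles, connections and probes."""

    def __init__(self, dt: float = 1e-3, seed: int | None = None):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.dt = dt
        self.rng = np.random.default_rng(seed)
        self.nodes: list[Node] = []
        self.ensembles: list[Ensemble] = []
        self.connections: list[NetConnection] = []
        self.probes: list[Probe] = []
        self.t = 0.0

    def add_node(self, output, **kw) -> Node:
        node = Node(output, **kw)
        self.nodes.append(node)
        return node

    def add_ensemble(self, pop: Population, **kw) -> Ensemble:
        ens = Ensemble(pop, **kw)
        self.ensembles.append(ens)
        return ens

    def connect(self, pre, post, **kw) -> NetConnection:
        conn = NetConnection(pre, post, **kw)
        if isinstance(pre, Node) and pre not in self.nodes:
            self.nodes.append(pre)
        self.connections.append(conn)
        return conn

    def probe(self, target, **kw) -> Probe:
        p = Probe(target, **kw)
        self.probes.append(p)
        return p

    def step(self) -> None:
        dt = self.dt
        for node in self.nodes:
            node.eval(self.t)
        for ens in self.ensembles:
            ens.x_input[:] = 0.0
            ens.j_input[:] = 0.0
        for conn in self.connections:
            conn.propagate(dt)
        for ens in self.ensembles:
            J = ens.current()
            if not np.all(np.isfinite(J)):
                bad = np.flatnonzero(~np.isfinite(J))[:5]
                raise FloatingPointError(
                    f"non-finite current in ensemble {ens.label!r} at t={self.t:.4f}s "
                    f"(neurons {bad.tolist()})"
                )
            ens.spikes = lif_spike_step(ens.state, J, dt, ens.pop.neuron_model) / dt
        for conn in self.connections:
            if conn.learning is not None and conn.decoders is not None:
                err = conn.learning.error
                e = np.atleast_1d(np.asarray(err.value if isinstance(err, Node) else err(self.t), dtype=float))
                # learn on the filtered activities the synapse transmits, not
                # raw spikes: shot noise would otherwise bias the fixed point
                a = conn.learned_activities(dt)
                conn.decoders -= (
                    conn.learning.learning_rate / conn.pre.pop.n * np.outer(e, a) * dt
                )
        for probe in self.probes:
            probe.sample(dt)
        self.t += dt

    def run(self, duration: float) -> None:
        n_steps = int(round(duration / self.dt))
        for _ in range(n_steps):
            self.step()
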