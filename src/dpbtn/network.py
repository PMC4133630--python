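"""Signed weighted signaling networks and their stochastic Boolean threshold dynamics.

A network on N proteins is a weighted directed graph: ``weights[i, j]`` is the
regulatory effect of node i on node j (positive = activation, negative =
inhibition, zero = no edge), and ``basal[i]`` sets the basal activation
tendency of node i in the absence of any regulation.  Each node is a Boolean
variable updated synchronously in discrete model time; the probability that a
node switches on is a logistic function of the weighted sum of its active
regulators, with a global steepness (stochasticity) parameter ``gamma``.
Experimental interventions clamp nodes: knocked-down nodes are held "off" and
overexpressed nodes "on" at every model time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


@dataclass
class SignalingNetwork:
    """Weighted directed network with stochastic threshold dynamics.

    Parameters
    ----------
    weights : (N, N) ndarray
        ``weights[i, j]`` is the effect of node i on node j.
    basal : (N,) ndarray
        Basal weights w0; under the default prior assumption these are <= 0
        (unregulated proteins tend to be off).
    gamma : float
        Positive steepness of the logistic update; large values make the
        dynamics nearly deterministic.
    node_names : list of str, optional
        Unique labels; defaults to "1".."N" (1-based, matching the usual
        numbering of small pathway diagrams).
    allow_self_loops : bool
        Self-edges are zeroed and rejected unless explicitly enabled.
    """

    weights: np.ndarray
    basal: np.ndarray
    gamma: float
    node_names: list[str] = field(default=None)  # type: ignore[assignment]
    allow_self_loops: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.basal = np.asarray(self.basal, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be a square matrix")
        if self.basal.shape != (n,):
            raise ValueError(f"basal must have length {n}")
        if not np.all(np.isfinite(self.weights)) or not np.all(np.isfinite(self.basal)):
            raise ValueError("weights and basal must be finite")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not self.allow_self_loops and np.any(np.diag(self.weights) != 0.0):
            raise ValueError("self-loops are disabled; diagonal of weights must be zero")
        if self.node_names is None:
            self.node_names = [str(i + 1) for i in range(n)]
        if len(self.node_names) != n or len(set(self.node_names)) != n:
            raise ValueError("node_names must be unique and of length N")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def copy(self) -> "SignalingNetwork":
        return SignalingNetwork(
            self.weights.copy(), self.basal.copy(), self.gamma,
            list(self.node_names), self.allow_self_loops,
        )

    def adjacency(self) -> np.ndarray:
        """Binary (N, N) presence matrix of the network's edges."""
        return (self.weights != 0.0).astype(int)


@dataclass(frozen=True)
class Experiment:
    """One perturbation condition: which nodes are clamped off/on."""

    clamped_off: frozenset = frozenset()
    clamped_on: frozenset = frozenset()
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "clamped_off", frozenset(self.clamped_off))
        object.__setattr__(self, "clamped_on", frozenset(self.clamped_on))
        if self.clamped_off & self.clamped_on:
            raise ValueError("a node cannot be clamped both off and on")


@dataclass
class PerturbationDesign:
    """Ordered collection of K perturbation experiments on an N-node network."""

    n_nodes: int
    experiments: list[Experiment]

    def __post_init__(self) -> None:
        if len(self.experiments) < 1:
            raise ValueError("need at least one experiment")
        for e in self.experiments:
            for i in e.clamped_off | e.clamped_on:
                if not 0 <= i < self.n_nodes:
                    raise IndexError(f"clamped node index {i} out of range")

    def __len__(self) -> int:
        return len(self.experiments)

    def clamp_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (K, N) masks of clamped-off and clamped-on nodes."""
        k, n = len(self.experiments), self.n_nodes
        off = np.zeros((k, n), dtype=bool)
        on = np.zeros((k, n), dtype=bool)
        for idx, e in enumerate(self.experiments):
            off[idx, list(e.clamped_off)] = True
            on[idx, list(e.clamped_on)] = True
        return off, on


def _check_state(state: np.ndarray, n: int) -> np.ndarray:
    state = np.asarray(state)
    if state.shape != (n,):
        raise ValueError(f"state must have length {n}")
    if not np.isin(state, (0, 1)).all():
        raise ValueError("state must be binary (0/1)")
    return state.astype(np.int8)


def apply_clamps(state: np.ndarray, experiment: Experiment) -> np.ndarray:
    """Return a copy of ``state`` with the experiment's clamps enforced."""
    out = np.array(state, dtype=np.int8, copy=True)
    if experiment.clamped_off:
        out[..., list(experiment.clamped_off)] = 0
    if experiment.clamped_on:
        out[..., list(experiment.clamped_on)] = 1
    return out


def activation_probability(net: SignalingNetwork, state: np.ndarray, i: int) -> float:
    """P(v_i(t+1) = 1 | v(t)) under the logistic threshold rule.

    Equals ``expit(gamma * (w0_i + sum_j w_ji v_j))``; strictly inside (0, 1)
    for finite weights and exactly 0.5 when the net input is zero.
    """
    state = _check_state(state, net.n_nodes)
    if not 0 <= i < net.n_nodes:
        raise IndexError(f"node index {i} out of range")
    x = net.basal[i] + state @ net.weights[:, i]
    return float(expit(net.gamma * x))


def activation_probabilities(net: SignalingNetwork, states: np.ndarray) -> np.ndarray:
    """Vectorized update probabilities for a batch of states (..., N)."""
    return expit(net.gamma * (net.basal + states @ net.weights))


def step(
    net: SignalingNetwork,
    state: np.ndarray,
    experiment: Experiment,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous stochastic update; clamps are re-applied after the draw."""
    state = _check_state(state, net.n_nodes)
    p = activation_probabilities(net, state)
    nxt = (rng.random(net.n_nodes) < p).astype(np.int8)
    return apply_clamps(nxt, experiment)


@dataclass
class Trajectory:
    """A simulated path: (n_steps + 1, N) binary states under one experiment."""

    states: np.ndarray
    experiment: Experiment

    @property
    def n_steps(self) -> int:
        return self.states.shape[0] - 1


def simulate(
    net: SignalingNetwork,
    init: np.ndarray,
    experiment: Experiment,
    n_steps: int,
    rng: np.random.Generator,
) -> Trajectory:
    """Simulate ``n_steps`` synchronous updates from a clamped initial state."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    init = apply_clamps(_check_state(init, net.n_nodes), experiment)
    states = np.empty((n_steps + 1, net.n_nodes), dtype=np.int8)
    states[0] = init
    for t in range(n_steps):
        states[t + 1] = step(net, states[t], experiment, rng)
    return Trajectory(states=states, experiment=experiment)


def transition_matrix(net: SignalingNetwork, experiment: Experiment | None = None) -> np.ndarray:
    """Exact (2^N, 2^N) Markov transition matrix of the synchronous dynamics.

    Intended for small N (exhaustive enumeration); used for exact marginals
    and as an oracle for the stochastic simulator.  State s is encoded with
    node i as bit i (node 0 = least significant bit).
    """
    n = net.n_nodes
    if n > 12:
        raise ValueError("transition_matrix is exponential in N; refuse N > 12")
    if experiment is None:
        experiment = Experiment()
    n_states = 2 ** n
    states = ((np.arange(n_states)[:, None] >> np.arange(n)) & 1).astype(np.int8)
    p_on = activation_probabilities(net, states)  # (2^N, N)
    # clamps override the stochastic update
    if experiment.clamped_off:
        p_on[:, list(experiment.clamped_off)] = 0.0
    if experiment.clamped_on:
        p_on[:, list(experiment.clamped_on)] = 1.0
    tgt = states[None, :, :]  # (1, 2^N, N) target states
    probs = np.where(tgt == 1, p_on[:, None, :], 1.0 - p_on[:, None, :])
    return probs.prod(axis=2)


def state_index(state: np.ndarray) -> int:
    """Encode a binary state vector as the integer row index of transition_matrix."""
    state = np.asarray(state, dtype=int)
    return int((state << np.arange(state.size)).sum())
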