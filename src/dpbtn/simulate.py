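"""Synthetic perturbation time-course data for benchmarking network inference.

Three generator families mirror a standard simulation-study design:

* ``sn1``: a 7-node feedforward reference network driven by the stochastic
  threshold dynamics (gamma = 10, edge weights 1, basal -0.25); systematic
  single knockdowns of every node plus two combinatorial knockdowns, with
  binary observations at the perturbation time and after 6 model steps.
* ``sn1a``: the same network and scheme with overexpression (clamp-on)
  instead of knockdown.
* ``sn2``: the feedforward network extended by a negative feedback edge from
  node 7 to node 4; dynamics are a deterministic strict-majority rule and
  noise enters only through a continuous measurement model (class-dependent
  normal means, scaled-inverse-chi-squared variances), measured at model
  steps 0, 4 and 6 and then discretized by a midpoint threshold.

Noise injection (flipping a fraction of observed values) and missing-node
masking (removing all observations of a random node subset) emulate
measurement error and unobserved proteins.  Random 7-node connected networks
stand in for pathway-database topologies and reuse the sn2 protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import MISSING, ObservationDataset
from .network import (
    Experiment,
    PerturbationDesign,
    SignalingNetwork,
    apply_clamps,
    simulate,
)

#: 1-based edge list of the 7-node feedforward reference topology.
#: Node 1 is the receptor (no incoming edges).  Node 5 has the redundant
#: parent pair {3, 4} and node 7 the pair {4, 6}: because any single active
#: parent suffices to activate a target, these convergence points are
#: exactly what the combinatorial knockdowns (3,4) and (4,6) of the study
#: design are needed to disambiguate.
SN1_EDGES: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 3), (2, 4), (3, 5), (4, 5), (5, 6), (4, 7), (6, 7),
)

#: The feedback extension: node 7 inhibits node 4, closing the negative loop
#: 4 -> 5 -> 6 -> 7 -> 4 (and the short branch 4 -> 7 -> 4).
SN2_FEEDBACK_EDGE: tuple[int, int] = (7, 4)

#: Combinatorial perturbations used alongside the 7 single-node ones.
COMBINATORIAL_TARGETS: tuple[tuple[int, int], ...] = ((3, 4), (4, 6))


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-data protocol (defaults = the sn1 study design)."""

    gamma_sim: float = 10.0
    w_value: float = 1.0
    w0_value: float = -0.25
    n_sim_steps: int = 6
    measurement_step_indices: tuple[int, ...] = (0, 6)
    # sn2 measurement model
    active_mean_loc: float = 1.0
    inactive_mean_loc: float = 0.0
    mean_sd: float = 0.1
    var_df: float = 5.0
    var_scale: float = 0.04


@dataclass
class LabeledDataset:
    """A generated dataset together with its gold-standard topology."""

    dataset: ObservationDataset
    gold: np.ndarray  # (N, N) binary adjacency of the generating network
    network: SignalingNetwork
    provenance: dict = field(default_factory=dict)


def _network_from_edges(
    edges: Sequence[tuple[int, int]],
    n_nodes: int,
    w_value: float,
    w0_value: float,
    gamma: float,
    negative_edges: Sequence[tuple[int, int]] = (),
) -> SignalingNetwork:
    W = np.zeros((n_nodes, n_nodes))
    for i, j in edges:
        W[i - 1, j - 1] = w_value
    for i, j in negative_edges:
        W[i - 1, j - 1] = -w_value
    return SignalingNetwork(
        weights=W, basal=np.full(n_nodes, w0_value), gamma=gamma
    )


def sn1_fixture(config: GeneratorConfig | None = None) -> SignalingNetwork:
    """The 7-node feedforward reference network (weights 1, w0 -0.25, gamma 10)."""
    c = config or GeneratorConfig()
    return _network_from_edges(SN1_EDGES, 7, c.w_value, c.w0_value, c.gamma_sim)


def sn2_fixture(config: GeneratorConfig | None = None) -> SignalingNetwork:
    """The feedforward network plus the inhibitory feedback edge 7 -> 4."""
    c = config or GeneratorConfig()
    return _network_from_edges(
        SN1_EDGES, 7, c.w_value, c.w0_value, c.gamma_sim,
        negative_edges=(SN2_FEEDBACK_EDGE,),
    )


def perturbation_scheme(
    n_nodes: int,
    mode: str = "kd",
    combos: Sequence[Sequence[int]] = COMBINATORIAL_TARGETS,
    stimulate_receptor: bool | None = None,
) -> PerturbationDesign:
    """Single perturbations of every node plus the listed combinations.

    ``mode`` is "kd" (clamp off) or "oe" (clamp on); node numbers in
    ``combos`` are 1-based.  In knockdown experiments the receptor (node 1)
    is stimulated: held "on" as a known intervention for the duration of the
    experiment (a parentless node would otherwise relax back to "off" and no
    signal could propagate), unless the receptor itself is a knockdown
    target.  Overexpression experiments supply their own sustained input
    through the clamped-on targets and use no receptor stimulation.
    """
    if mode not in ("kd", "oe"):
        raise ValueError("mode must be 'kd' or 'oe'")
    if stimulate_receptor is None:
        stimulate_receptor = mode == "kd"
    targets: list[tuple[int, ...]] = [(i,) for i in range(1, n_nodes + 1)]
    targets += [tuple(c) for c in combos]
    experiments = []
    for tgt in targets:
        idx = frozenset(t - 1 for t in tgt)
        label = ("KD" if mode == "kd" else "OE") + "_" + "+".join(map(str, tgt))
        if mode == "kd":
            on = frozenset({0}) - idx if stimulate_receptor else frozenset()
            experiments.append(Experiment(clamped_off=idx, clamped_on=on, label=label))
        else:
            on = idx | (frozenset({0}) if stimulate_receptor else frozenset())
            experiments.append(Experiment(clamped_on=on, label=label))
    return PerturbationDesign(n_nodes=n_nodes, experiments=experiments)


def generate_perturbation_data(
    net: SignalingNetwork,
    design: PerturbationDesign,
    rng: np.random.Generator,
    n_steps: int = 6,
    measure_at: Sequence[int] = (0, 6),
) -> LabeledDataset:
    """Stochastic time-course data under every experiment of ``design``.

    All proteins start "off"; any sustained input (receptor stimulation,
    overexpression) enters through the experiments' clamp-on sets, applied
    to the initial state and after every synchronous update.  Observations
    are recorded at the model-step indices ``measure_at``; tau is stored as
    the true step gaps.
    """
    measure_at = sorted(int(m) for m in measure_at)
    if measure_at[0] < 0 or measure_at[-1] > n_steps:
        raise ValueError("measurement step indices must lie within [0, n_steps]")
    K, N, T = len(design), net.n_nodes, len(measure_at)
    obs = np.empty((K, T, N), dtype=np.int8)
    init = np.zeros(N, dtype=np.int8)
    for k, exp in enumerate(design.experiments):
        traj = simulate(net, init, exp, n_steps, rng)
        obs[k] = traj.states[measure_at]
    tau = np.diff(measure_at)
    ds = ObservationDataset(
        design=design, obs=obs, time_points=np.asarray(measure_at, float), tau=tau
    )
    return LabeledDataset(
        dataset=ds, gold=net.adjacency(), network=net,
        provenance={"protocol": "stochastic", "n_steps": n_steps,
                    "measure_at": list(measure_at)},
    )


def generate_sn1_data(rng: np.random.Generator,
                      config: GeneratorConfig | None = None) -> LabeledDataset:
    """Knockdown study on the feedforward reference network (9 experiments)."""
    c = config or GeneratorConfig()
    net = sn1_fixture(c)
    design = perturbation_scheme(net.n_nodes, mode="kd")
    return generate_perturbation_data(
        net, design, rng, n_steps=c.n_sim_steps,
        measure_at=c.measurement_step_indices,
    )


def generate_overexpression_data(rng: np.random.Generator,
                                 config: GeneratorConfig | None = None) -> LabeledDataset:
    """Overexpression study (sn1a): clamp-on perturbations, no receptor input."""
    c = config or GeneratorConfig()
    net = sn1_fixture(c)
    design = perturbation_scheme(net.n_nodes, mode="oe")
    return generate_perturbation_data(
        net, design, rng, n_steps=c.n_sim_steps,
        measure_at=c.measurement_step_indices,
    )


# ---------------------------------------------------------------------------
# deterministic majority-rule dynamics + continuous measurement model (sn2)
# ---------------------------------------------------------------------------

def majority_step(net: SignalingNetwork, state: np.ndarray,
                  experiment: Experiment) -> np.ndarray:
    """Deterministic update: a node turns on iff strictly more of its active
    parents activate than inhibit it; clamps override."""
    state = np.asarray(state, dtype=np.int8)
    act = (state @ (net.weights > 0)).astype(int)
    inh = (state @ (net.weights < 0)).astype(int)
    nxt = (act > inh).astype(np.int8)
    return apply_clamps(nxt, experiment)


def majority_trajectory(net: SignalingNetwork, init: np.ndarray,
                        experiment: Experiment, n_steps: int) -> np.ndarray:
    init = apply_clamps(np.asarray(init, dtype=np.int8), experiment)
    states = np.empty((n_steps + 1, net.n_nodes), dtype=np.int8)
    states[0] = init
    for t in range(n_steps):
        states[t + 1] = majority_step(net, states[t], experiment)
    return states


def _scaled_inv_chi2(rng: np.random.Generator, df: float, scale: float,
                     size) -> np.ndarray:
    return df * scale / rng.chisquare(df, size=size)


def generate_sn2_data(
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
    net: SignalingNetwork | None = None,
    measure_at: Sequence[int] = (0, 4, 6),
    return_continuous: bool = False,
):
    """Deterministic-dynamics data with continuous measurement noise.

    True states come from the strict-majority rule on the feedback network;
    each measurement is Normal(mean, var) with the mean drawn around the
    active/inactive class location and the variance from a scaled inverse
    chi-squared distribution.  Continuous values are discretized at the
    midpoint of the two class locations to produce the model's binary input.
    """
    c = config or GeneratorConfig()
    net = net if net is not None else sn2_fixture(c)
    design = perturbation_scheme(net.n_nodes, mode="kd")
    measure_at = sorted(int(m) for m in measure_at)
    K, N, T = len(design), net.n_nodes, len(measure_at)
    true = np.empty((K, T, N), dtype=np.int8)
    init = np.zeros(N, dtype=np.int8)
    for k, exp in enumerate(design.experiments):
        states = majority_trajectory(net, init, exp, measure_at[-1])
        true[k] = states[measure_at]
    locs = np.where(true == 1, c.active_mean_loc, c.inactive_mean_loc)
    means = rng.normal(locs, c.mean_sd)
    variances = _scaled_inv_chi2(rng, c.var_df, c.var_scale, (K, T, N))
    cont = rng.normal(means, np.sqrt(variances))
    threshold = 0.5 * (c.active_mean_loc + c.inactive_mean_loc)
    obs = (cont >= threshold).astype(np.int8)
    # clamped nodes are known, not measured: record the clamp value
    off, on = design.clamp_masks()
    obs[np.broadcast_to(off[:, None, :], obs.shape)] = 0
    obs[np.broadcast_to(on[:, None, :], obs.shape)] = 1
    ds = ObservationDataset(
        design=design, obs=obs, time_points=np.asarray(measure_at, float),
        tau=np.diff(measure_at),
    )
    labeled = LabeledDataset(
        dataset=ds, gold=net.adjacency(), network=net,
        provenance={"protocol": "majority+continuous", "measure_at": list(measure_at)},
    )
    if return_continuous:
        return labeled, cont
    return labeled


def discretize_measurements(
    values: np.ndarray,
    low_reference: np.ndarray | float | None = None,
    high_reference: np.ndarray | float | None = None,
    design: PerturbationDesign | None = None,
    time_points: np.ndarray | None = None,
    tau: np.ndarray | None = None,
) -> ObservationDataset:
    """Threshold continuous measurements at the midpoint of two reference medians.

    ``low_reference``/``high_reference`` are the negative/positive control
    medians (scalars or per-node vectors).  If absent, a data-driven fallback
    uses the midpoint of a 2-means split of each node's values.  Values >=
    threshold map to 1 (ties resolve upward).  NaN values become missing.
    """
    values = np.asarray(values, dtype=float)
    K, T, N = values.shape
    if low_reference is None or high_reference is None:
        import warnings

        warnings.warn("no control references supplied; using data-driven midpoints",
                      stacklevel=2)
        thr = np.empty(N)
        for i in range(N):
            v = values[:, :, i][np.isfinite(values[:, :, i])]
            srt = np.sort(v)
            split = max(1, min(v.size - 1, int(np.searchsorted(srt, srt.mean()))))
            thr[i] = 0.5 * (srt[:split].mean() + srt[split:].mean())
    else:
        thr = 0.5 * (np.broadcast_to(np.asarray(low_reference, float), (N,))
                     + np.broadcast_to(np.asarray(high_reference, float), (N,)))
    obs = np.where(np.isnan(values), MISSING, (values >= thr).astype(int)).astype(np.int8)
    if design is None:
        design = PerturbationDesign(
            n_nodes=N, experiments=[Experiment(label=f"exp{k}") for k in range(K)]
        )
    return ObservationDataset(design=design, obs=obs, time_points=time_points, tau=tau)


# ---------------------------------------------------------------------------
# corruption operators
# ---------------------------------------------------------------------------

def inject_noise(dataset: ObservationDataset, fraction: float,
                 rng: np.random.Generator) -> ObservationDataset:
    """Flip floor(fraction * #observed) distinct observed values (0 <-> 1)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    out = dataset.copy()
    cells = np.flatnonzero(out.obs != MISSING)
    n_flip = int(np.floor(fraction * cells.size))
    if n_flip:
        chosen = rng.choice(cells, size=n_flip, replace=False)
        flat = out.obs.reshape(-1)
        flat[chosen] = 1 - flat[chosen]
    return out


def mask_missing(dataset: ObservationDataset, fraction: float,
                 rng: np.random.Generator) -> ObservationDataset:
    """Remove all observations of floor(fraction * N) randomly chosen nodes."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    out = dataset.copy()
    n_mask = int(np.floor(fraction * out.n_nodes))
    if n_mask:
        nodes = rng.choice(out.n_nodes, size=n_mask, replace=False)
        out.obs[:, :, nodes] = MISSING
    return out


# ---------------------------------------------------------------------------
# random topologies (pathway-database stand-ins)
# ---------------------------------------------------------------------------

def random_network(
    n_nodes: int,
    rng: np.random.Generator,
    edge_density: float = 0.2,
    inhibition_fraction: float = 0.3,
    ensure_connected: bool = True,
    w_value: float = 1.0,
    w0_value: float = -0.25,
    gamma: float = 10.0,
    max_tries: int = 1000,
) -> SignalingNetwork:
    """Random directed signed network at the given density, weakly connected.

    Used with the sn2 simulation protocol as a stand-in for small pathway
    subnetworks.
    """
    import networkx as nx

    n_edges = max(1, round(edge_density * n_nodes * (n_nodes - 1)))
    pairs = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]
    for _ in range(max_tries):
        idx = rng.choice(len(pairs), size=n_edges, replace=False)
        chosen = [pairs[i] for i in idx]
        g = nx.DiGraph(chosen)
        g.add_nodes_from(range(n_nodes))
        if not ensure_connected or nx.is_weakly_connected(g):
            W = np.zeros((n_nodes, n_nodes))
            signs = np.where(rng.random(n_edges) < inhibition_fraction, -1.0, 1.0)
            for (i, j), sgn in zip(chosen, signs):
                W[i, j] = sgn * w_value
            return SignalingNetwork(W, np.full(n_nodes, w0_value), gamma)
    raise RuntimeError("failed to draw a connected network; raise edge_density")
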