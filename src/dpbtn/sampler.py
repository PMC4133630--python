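"""Distributed evolutionary Monte Carlo (DEMC) sampling of the model posterior.

A population of Markov chains is partitioned into subpopulations.  Within a
subpopulation, chains evolve by two genetic operators, each followed by a
Metropolis-Hastings accept/reject step so the population targets the
posterior:

* mutation — a symmetric random-walk proposal on the weights, basal weights
  and (optionally) one tau component;
* crossover — two chains exchange the full incoming-regulation set of a
  uniformly chosen node (one column of W plus the matching w0 entry), a
  natural block because the likelihood factorizes over target nodes; the
  swap is symmetric and accepted jointly on the sum of the two log-posterior
  changes.

Every ``migration_interval`` sweeps, each subpopulation sends a copy of its
best chain to replace the worst chain of the next subpopulation on a ring.

The likelihood inside the posterior is the forward-simulation estimate of
:mod:`dpbtn.posterior` (exact when tau = 1 with complete data), making the
sampler Monte-Carlo-within-Metropolis: the cached log-posterior of the
current state is by default *not* re-estimated at each step (the cheap,
standard "stale likelihood" convention; ``refresh_current=True`` re-draws it
for sensitivity checks).

Progress is counted in *proposal steps* = likelihood evaluations (a mutation
sweep of the whole population costs m proposals, a crossover pair costs 2);
``n_steps`` and ``burn_in`` are expressed on that scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .data import ObservationDataset
from .network import SignalingNetwork
from .posterior import (
    Hyperparameters,
    LikelihoodEvaluator,
    ModelParameters,
    log_prior,
)

logger = logging.getLogger(__name__)


@dataclass
class SamplerConfig:
    """Population layout, proposal scales and schedule of the DEMC sampler."""

    n_subpops: int = 3
    chains_per_subpop: int = 4
    n_steps: int = 20_000          # proposal steps (likelihood evaluations)
    burn_in: int = 2_000           # proposal steps discarded
    thinning: int = 10             # record every `thinning`-th sweep
    sigma_w: float = 0.3
    sigma_w0: float = 0.1
    sigma_w_large: float = 2.0     # occasional large jumps (edge birth/death)
    p_large: float = 0.3           # mixture weight of the large-scale component
    p_mutation: float = 0.1        # per-parameter perturbation probability
    p_crossover: float = 0.2       # per-sweep probability of a crossover update
    tau_move_prob: float = 0.2
    migration_interval: int = 100  # in sweeps
    sample_tau: bool = True
    refresh_current: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subpops < 1 or self.chains_per_subpop < 1:
            raise ValueError("need at least one subpopulation and one chain")
        if self.burn_in >= self.n_steps:
            raise ValueError("burn_in must be smaller than n_steps")
        for p in (self.p_mutation, self.p_crossover, self.tau_move_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_crossover > 0 and self.chains_per_subpop < 2:
            raise ValueError("crossover requires >= 2 chains per subpopulation")

    @property
    def n_chains(self) -> int:
        return self.n_subpops * self.chains_per_subpop


@dataclass
class ChainState:
    """A chain's current parameters with its cached log-posterior parts."""

    params: ModelParameters
    log_lik: float
    log_pri: float
    rng: np.random.Generator

    @property
    def log_post(self) -> float:
        return self.log_lik + self.log_pri


@dataclass
class PosteriorSampleSet:
    """Thinned post-burn-in draws of Omega = (W, w0, tau) from all chains."""

    weights: np.ndarray     # (S, N, N)
    basal: np.ndarray       # (S, N)
    tau: np.ndarray         # (S, T-1)
    log_post: np.ndarray    # (S,)
    chain: np.ndarray       # (S,)
    sweep: np.ndarray       # (S,) sweep index of each draw
    config: SamplerConfig = None  # type: ignore[assignment]
    node_names: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.weights.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[1]

    def flattened(self, include_basal: bool = True) -> np.ndarray:
        """(S, P) matrix of off-diagonal weights (+ basal) per sample."""
        n = self.n_nodes
        off = ~np.eye(n, dtype=bool)
        cols = [self.weights[:, off]]
        if include_basal:
            cols.append(self.basal)
        return np.hstack(cols)


def mh_accept(current_log_post: float, proposal_log_post: float,
              rng: np.random.Generator) -> bool:
    """Metropolis accept with probability min(1, exp(proposal - current))."""
    if proposal_log_post == -np.inf:
        return False
    if proposal_log_post >= current_log_post:
        return True
    return bool(rng.random() < np.exp(proposal_log_post - current_log_post))


def mutate(params: ModelParameters, hyper: Hyperparameters,
           config: SamplerConfig, rng: np.random.Generator) -> ModelParameters:
    """Symmetric random-walk proposal on (W, w0) and one tau component.

    Each off-diagonal weight is perturbed with probability ``p_mutation`` by
    noise from a two-scale Gaussian mixture: N(0, sigma_w^2) with weight
    1 - p_large and N(0, sigma_w_large^2) with weight p_large.  The small
    scale refines existing edges; the large scale lets an edge appear or
    vanish in one move, which random-walk steps alone cross only slowly
    because intermediate weights pay the sparsity penalty before the
    likelihood rewards them.  The mixture density depends only on |step|, so
    the kernel stays symmetric.  Basal weights are perturbed likewise with
    sigma_w0.  With probability ``tau_move_prob`` one tau_t takes a +/-1
    step; a step outside the support [1, n] proposes the current value,
    keeping that kernel exactly symmetric too.
    """
    prop = params.copy()
    net = prop.network
    n = net.n_nodes
    off = ~np.eye(n, dtype=bool)
    hit = (rng.random((n, n)) < config.p_mutation) & off
    n_hit = int(hit.sum())
    scales = np.where(rng.random(n_hit) < config.p_large,
                      config.sigma_w_large, config.sigma_w)
    net.weights[hit] += rng.normal(0.0, 1.0, size=n_hit) * scales
    hit0 = rng.random(n) < config.p_mutation
    net.basal[hit0] += rng.normal(0.0, config.sigma_w0, size=int(hit0.sum()))
    if config.sample_tau and prop.tau.size and rng.random() < config.tau_move_prob:
        t = rng.integers(prop.tau.size)
        cand = prop.tau[t] + (1 if rng.random() < 0.5 else -1)
        if 1 <= cand <= hyper.n:
            prop.tau[t] = cand
    return prop


def crossover(a: ModelParameters, b: ModelParameters,
              rng: np.random.Generator) -> tuple[ModelParameters, ModelParameters, int]:
    """Swap the incoming regulations (column W[:, i] and w0[i]) of one node.

    The swap is an involution, hence a symmetric proposal; the caller accepts
    both proposals jointly on the summed log-posterior change.  Returns the
    two proposals and the chosen node index.
    """
    i = int(rng.integers(a.network.n_nodes))
    pa, pb = a.copy(), b.copy()
    col_a = pa.network.weights[:, i].copy()
    pa.network.weights[:, i] = pb.network.weights[:, i]
    pb.network.weights[:, i] = col_a
    w0a = pa.network.basal[i]
    pa.network.basal[i] = pb.network.basal[i]
    pb.network.basal[i] = w0a
    return pa, pb, i


def migrate(subpops: list[list[ChainState]], rng: np.random.Generator) -> None:
    """Ring migration: each subpopulation's best chain replaces the next one's worst.

    Copies are taken first so the move is simultaneous; the population size
    is conserved.  A single subpopulation is a no-op.
    """
    g = len(subpops)
    if g <= 1:
        return
    best = []
    for sp in subpops:
        b = max(sp, key=lambda c: c.log_post)
        best.append((b.params.copy(), b.log_lik, b.log_pri))
    for src in range(g):
        dst = (src + 1) % g
        worst_idx = min(range(len(subpops[dst])),
                        key=lambda j: subpops[dst][j].log_post)
        params, ll, lp = best[src]
        tgt = subpops[dst][worst_idx]
        tgt.params = params.copy()
        tgt.log_lik = ll
        tgt.log_pri = lp


def _init_params(dataset: ObservationDataset, hyper: Hyperparameters,
                 config: SamplerConfig, rng: np.random.Generator) -> ModelParameters:
    """Overdispersed start: draw W, w0 and tau from their priors."""
    n = dataset.n_nodes
    mu = hyper.mu_matrix(n)
    if hyper.q == 1.0:
        W = rng.laplace(mu, hyper.s)
    elif hyper.q == 2.0:
        W = rng.normal(mu, hyper.s / np.sqrt(2.0))
    else:  # generalized-normal draw via gamma transform
        mag = rng.gamma(1.0 / hyper.q, 1.0, size=(n, n)) ** (1.0 / hyper.q)
        W = mu + hyper.s * mag * rng.choice((-1.0, 1.0), size=(n, n))
    np.fill_diagonal(W, 0.0)
    w0 = -rng.gamma(hyper.s0, 1.0 / hyper.r0, size=n)
    n_tau = dataset.n_times - 1
    if config.sample_tau:
        tau = np.clip(rng.binomial(hyper.n, hyper.p, size=n_tau), 1, hyper.n)
    else:
        tau = dataset.tau.copy()
    net = SignalingNetwork(W, w0, hyper.gamma)
    return ModelParameters(net, tau)


def run_demc(dataset: ObservationDataset, hyper: Hyperparameters,
             config: SamplerConfig) -> PosteriorSampleSet:
    """Run the DEMC sampler; fully reproducible from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains + 1)
    master = np.random.default_rng(chain_seeds[-1])
    evaluator = LikelihoodEvaluator(dataset, hyper)

    chains: list[ChainState] = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        params = _init_params(dataset, hyper, config, rng)
        lp = log_prior(params, hyper)
        ll = evaluator.log_likelihood(params, rng) if np.isfinite(lp) else -np.inf
        chains.append(ChainState(params=params, log_lik=ll, log_pri=lp, rng=rng))
    if all(c.log_post == -np.inf for c in chains):
        raise RuntimeError("all chains initialized at -inf log-posterior")

    m = config.chains_per_subpop
    subpops = [chains[g * m:(g + 1) * m] for g in range(config.n_subpops)]

    rec_w, rec_w0, rec_tau, rec_lp, rec_chain, rec_sweep = [], [], [], [], [], []
    n_prop = n_acc = 0
    steps = 0
    sweep = 0
    while steps < config.n_steps:
        sweep += 1
        do_crossover = (
            config.p_crossover > 0 and m >= 2
            and master.random() < config.p_crossover
        )
        if do_crossover:
            g = int(master.integers(config.n_subpops))
            ia, ib = master.choice(m, size=2, replace=False)
            ca, cb = subpops[g][ia], subpops[g][ib]
            pa, pb, _ = crossover(ca.params, cb.params, master)
            pri_a, pri_b = log_prior(pa, hyper), log_prior(pb, hyper)
            ll_a = evaluator.log_likelihood(pa, ca.rng) if np.isfinite(pri_a) else -np.inf
            ll_b = evaluator.log_likelihood(pb, cb.rng) if np.isfinite(pri_b) else -np.inf
            steps += 2
            n_prop += 1
            new_sum = ll_a + pri_a + ll_b + pri_b
            cur_sum = ca.log_post + cb.log_post
            if mh_accept(cur_sum, new_sum, master):
                n_acc += 1
                ca.params, ca.log_lik, ca.log_pri = pa, ll_a, pri_a
                cb.params, cb.log_lik, cb.log_pri = pb, ll_b, pri_b
        else:
            for chain in chains:
                if config.refresh_current:
                    chain.log_lik = evaluator.log_likelihood(chain.params, chain.rng)
                prop = mutate(chain.params, hyper, config, chain.rng)
                pri = log_prior(prop, hyper)
                ll = evaluator.log_likelihood(prop, chain.rng) if np.isfinite(pri) else -np.inf
                steps += 1
                n_prop += 1
                if mh_accept(chain.log_post, ll + pri, chain.rng):
                    n_acc += 1
                    chain.params, chain.log_lik, chain.log_pri = prop, ll, pri
        if config.migration_interval and sweep % config.migration_interval == 0:
            migrate(subpops, master)
        if steps > config.burn_in and sweep % config.thinning == 0:
            for cid, chain in enumerate(chains):
                rec_w.append(chain.params.network.weights.copy())
                rec_w0.append(chain.params.network.basal.copy())
                rec_tau.append(chain.params.tau.copy())
                rec_lp.append(chain.log_post)
                rec_chain.append(cid)
                rec_sweep.append(sweep)

    if not rec_w:  # degenerate schedules: keep at least the final states
        for cid, chain in enumerate(chains):
            rec_w.append(chain.params.network.weights.copy())
            rec_w0.append(chain.params.network.basal.copy())
            rec_tau.append(chain.params.tau.copy())
            rec_lp.append(chain.log_post)
            rec_chain.append(cid)
            rec_sweep.append(sweep)

    acc_rate = n_acc / max(n_prop, 1)
    if not 0.05 <= acc_rate <= 0.80:
        logger.warning(
            "overall acceptance rate %.1f%% outside the 5-80%% comfort band; "
            "consider adjusting sigma_w/sigma_w0", 100 * acc_rate,
        )
    return PosteriorSampleSet(
        weights=np.asarray(rec_w),
        basal=np.asarray(rec_w0),
        tau=np.asarray(rec_tau),
        log_post=np.asarray(rec_lp),
        chain=np.asarray(rec_chain),
        sweep=np.asarray(rec_sweep),
        config=replace(config),
        node_names=[str(i + 1) for i in range(dataset.n_nodes)],
        diagnostics={"acceptance_rate": acc_rate, "n_sweeps": sweep,
                     "n_proposal_steps": steps},
    )


def psrf(traces: np.ndarray) -> float:
    """Brooks-Gelman potential scale reduction factor of scalar chain traces.

    ``traces`` is (n_chains, n_draws).  Returns the corrected R-hat; 1.0 by
    convention when every chain has zero within-chain variance.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2 or traces.shape[1] < 10:
        raise ValueError("need >= 2 chains with >= 10 draws each")
    m, n = traces.shape
    chain_means = traces.mean(axis=1)
    W = traces.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return 1.0
    B = n * chain_means.var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    r2 = (m + 1) / m * var_hat / W - (n - 1) / (m * n)
    # with zero between-chain variance r2 dips slightly below 1; clamp, since
    # values < 1 carry no extra meaning for convergence assessment
    return float(max(np.sqrt(max(r2, 0.0)), 1.0))
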