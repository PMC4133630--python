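"""Model / Results façade for dynamic probabilistic Boolean threshold networks.

Follows the familiar two-object pattern of statistical modelling packages:
:class:`ThresholdNetworkModel` binds data (an :class:`ObservationDataset`)
to the model specification (hyperparameters, optional prior network), and
``fit()`` runs the DEMC sampler, returning a
:class:`ThresholdNetworkResults` that carries the posterior draws plus the
aggregation, diagnostic and evaluation machinery.

Example
-------
>>> import numpy as np
>>> from dpbtn import simulate, ThresholdNetworkModel, SamplerConfig
>>> rng = np.random.default_rng(1)
>>> labeled = simulate.generate_sn1_data(rng)
>>> model = ThresholdNetworkModel(labeled.dataset)
>>> res = model.fit(SamplerConfig(n_steps=5000, burn_in=500, seed=1))
>>> ev = res.evaluate(labeled.gold)
>>> 0.0 <= ev.auc_roc <= 1.0
True
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import io as dpbtn_io
from .aggregate import (
    ClusterSettings,
    EdgeScoreMatrix,
    NetworkCluster,
    cluster_samples,
    discretize_network,
    edge_scores,
)
from .data import ObservationDataset
from .evaluate import EvalResult, GoldStandard, confusion_at, roc_pr
from .posterior import Hyperparameters, LikelihoodEvaluator, ModelParameters, log_prior
from .sampler import PosteriorSampleSet, SamplerConfig, psrf, run_demc


class ThresholdNetworkModel:
    """Bayesian threshold-network model bound to a perturbation time course.

    Parameters
    ----------
    dataset : ObservationDataset
        Discretized {0,1,missing} observations with their perturbation design.
    hyper : Hyperparameters, optional
        Priors, stochasticity gamma and likelihood settings (study defaults
        if omitted).
    prior_network : (N, N) ndarray, optional
        Signed prior edge expectations mu; overrides ``hyper.mu``.
    """

    def __init__(self, dataset: ObservationDataset,
                 hyper: Hyperparameters | None = None,
                 prior_network: np.ndarray | None = None) -> None:
        self.dataset = dataset
        self.hyper = hyper or Hyperparameters()
        if prior_network is not None:
            self.hyper.mu = np.asarray(prior_network, dtype=float)
        self.hyper.mu_matrix(dataset.n_nodes)  # shape check

    @classmethod
    def from_tables(cls, observations_path, design_path, n_nodes: int,
                    hyper: Hyperparameters | None = None,
                    prior_network_path=None) -> "ThresholdNetworkModel":
        """Build a model from the long-form observation and design TSV files."""
        design = dpbtn_io.read_design(design_path, n_nodes)
        dataset = dpbtn_io.read_observations(observations_path, design)
        mu = None
        if prior_network_path is not None:
            mu = dpbtn_io.read_edge_list(prior_network_path).weights
        return cls(dataset, hyper=hyper, prior_network=mu)

    def log_posterior(self, params: ModelParameters,
                      rng: np.random.Generator) -> float:
        lp = log_prior(params, self.hyper)
        if not np.isfinite(lp):
            return -np.inf
        return lp + LikelihoodEvaluator(self.dataset, self.hyper).log_likelihood(params, rng)

    def fit(self, config: SamplerConfig | None = None,
            seed: int | None = None) -> "ThresholdNetworkResults":
        """Sample the posterior with the DEMC sampler."""
        config = replace(config) if config is not None else SamplerConfig()
        if seed is not None:
            config.seed = seed
        samples = run_demc(self.dataset, self.hyper, config)
        samples.node_names = [str(i + 1) for i in range(self.dataset.n_nodes)]
        return ThresholdNetworkResults(self, samples)


class ThresholdNetworkResults:
    """Posterior sample set with aggregation, evaluation and diagnostics."""

    def __init__(self, model: ThresholdNetworkModel,
                 samples: PosteriorSampleSet) -> None:
        self.model = model
        self.samples = samples
        self._scores: EdgeScoreMatrix | None = None

    # -- point summaries ----------------------------------------------------

    def edge_scores(self) -> EdgeScoreMatrix:
        """Per-edge posterior medians of the sampled weights."""
        if self._scores is None:
            self._scores = edge_scores(self.samples)
        return self._scores

    def discretize(self, delta: float, relative: bool = False) -> np.ndarray:
        """Binary edge set from thresholding |median| at delta."""
        return discretize_network(self.edge_scores(), delta, relative=relative)

    def edge_support(self, epsilon: float | None = None) -> np.ndarray:
        """Fraction of draws with |w_ij| above epsilon (default 0.1 * s)."""
        eps = 0.1 * self.model.hyper.s if epsilon is None else epsilon
        sup = (np.abs(self.samples.weights) > eps).mean(axis=0)
        np.fill_diagonal(sup, 0.0)
        return sup

    # -- structure over the posterior ---------------------------------------

    def clusters(self, settings: ClusterSettings | None = None) -> list[NetworkCluster]:
        settings = settings or ClusterSettings(prior_scale=self.model.hyper.s)
        return cluster_samples(self.samples, settings,
                               gamma=self.model.hyper.gamma)

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, gold, mode: str = "directed") -> EvalResult:
        gold = gold if isinstance(gold, GoldStandard) else GoldStandard(gold)
        return roc_pr(self.edge_scores(), gold, mode=mode)

    def confusion_at(self, gold, delta: float, mode: str = "directed",
                     relative: bool = False) -> dict:
        gold = gold if isinstance(gold, GoldStandard) else GoldStandard(gold)
        return confusion_at(self.edge_scores(), gold, delta, mode=mode,
                            relative=relative)

    # -- diagnostics --------------------------------------------------------

    def psrf_log_post(self) -> float:
        """Brooks-Gelman PSRF of the log-posterior trace across chains."""
        return psrf(self._per_chain(self.samples.log_post))

    def psrf_weights(self) -> np.ndarray:
        """(N, N) PSRF per edge weight (NaN on the diagonal)."""
        n = self.samples.n_nodes
        out = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(n):
                if i != j:
                    out[i, j] = psrf(self._per_chain(self.samples.weights[:, i, j]))
        return out

    def _per_chain(self, values: np.ndarray) -> np.ndarray:
        chains = np.unique(self.samples.chain)
        traces = [values[self.samples.chain == c] for c in chains]
        length = min(len(t) for t in traces)
        return np.asarray([t[:length] for t in traces])

    # -- reporting ----------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        """Per-edge table: median, IQR, support fraction and sign."""
        names = self.samples.node_names
        med = self.edge_scores().scores
        q25 = np.quantile(self.samples.weights, 0.25, axis=0)
        q75 = np.quantile(self.samples.weights, 0.75, axis=0)
        sup = self.edge_support()
        rows = []
        n = len(names)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                rows.append({
                    "source": names[i], "target": names[j],
                    "median_w": med[i, j], "q25": q25[i, j], "q75": q75[i, j],
                    "support": sup[i, j],
                    "sign": "activation" if med[i, j] > 0
                            else ("inhibition" if med[i, j] < 0 else "none"),
                })
        return (pd.DataFrame(rows)
                .sort_values("support", ascending=False, kind="stable")
                .reset_index(drop=True))

    def summary(self, top: int = 15) -> str:
        d = self.samples.diagnostics
        lines = [
            "Dynamic probabilistic Boolean threshold network - posterior summary",
            "=" * 68,
            f"nodes: {self.samples.n_nodes}    "
            f"experiments: {self.model.dataset.n_experiments}    "
            f"time points: {self.model.dataset.n_times}",
            f"posterior draws: {self.samples.n_samples} "
            f"({len(np.unique(self.samples.chain))} chains)",
            f"acceptance rate: {d.get('acceptance_rate', float('nan')):.3f}    "
            f"PSRF(log posterior): {self.psrf_log_post():.3f}",
            f"median tau: {np.median(self.samples.tau, axis=0).tolist()}",
            "",
            f"top {top} edges by posterior support "
            "(median weight [IQR], support fraction):",
        ]
        df = self.summary_frame().head(top)
        for row in df.itertuples(index=False):
            lines.append(
                f"  {row.source:>3} -> {row.target:<3} "
                f"{row.median_w:+8.3f} [{row.q25:+.3f}, {row.q75:+.3f}]  "
                f"support {row.support:.2f}  {row.sign}"
            )
        return "\n".join(lines)

    def save_trace(self, path) -> None:
        dpbtn_io.write_trace(self.samples, path)
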