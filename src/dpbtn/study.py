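"""Scaled-down reproduction of the simulation study.

The full study (10^8 proposal steps per run, 100 replicate datasets per
condition) is a multi-hour computation per condition; this module fixes a
desk-scale version of the same protocol whose problem sizes are the
package's reference configuration:

* per run: 3 subpopulations x 4 chains, 2 x 10^4 proposal steps, burn-in
  2 x 10^3, R = 50 likelihood replicates (the feedback study uses the
  5 x 3 chain layout of the original and 6 x 10^4 steps);
* per condition: a handful of replicate datasets (11 for the clean
  reference, 9 elsewhere) instead of 100, summarized by median AUCs.

Every function takes a single integer seed and derives all dataset and
sampler randomness from it through ``numpy.random.SeedSequence`` spawning,
so a condition is reproducible end to end from one number.
"""

from __future__ import annotations

import numpy as np

from .evaluate import GoldStandard, roc_pr
from .model import ThresholdNetworkModel
from .posterior import Hyperparameters
from .sampler import SamplerConfig
from .simulate import (
    generate_overexpression_data,
    generate_sn1_data,
    generate_sn2_data,
    inject_noise,
    mask_missing,
)

#: Conditions of the degradation study: (generator kind, corruption, level).
CONDITIONS = {
    "sn1": ("kd", None, 0.0),
    "sn1_noise16": ("kd", "noise", 0.16),
    "sn1_noise33": ("kd", "noise", 0.33),
    "sn1_noise50": ("kd", "noise", 0.50),
    "sn1_missing16": ("kd", "missing", 0.16),
    "sn1_missing33": ("kd", "missing", 0.33),
    "sn1_missing50": ("kd", "missing", 0.50),
    "sn1a": ("oe", None, 0.0),
}


def reference_sampler_config(seed: int = 0) -> SamplerConfig:
    """The scaled-down per-run sampler settings."""
    return SamplerConfig(n_subpops=3, chains_per_subpop=4,
                         n_steps=20_000, burn_in=2_000, seed=seed)


def _sub_seeds(seed: int, n: int) -> list[int]:
    # keep derived seeds below 2^31 for portability of stored configs
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def run_condition_replicate(condition: str, seed: int,
                            config: SamplerConfig | None = None,
                            hyper: Hyperparameters | None = None) -> dict:
    """One dataset + inference + evaluation under a named study condition."""
    kind, corruption, level = CONDITIONS[condition]
    data_seed, fit_seed, corrupt_seed = _sub_seeds(seed, 3)
    rng = np.random.default_rng(data_seed)
    lab = generate_sn1_data(rng) if kind == "kd" else generate_overexpression_data(rng)
    ds = lab.dataset
    if corruption == "noise":
        ds = inject_noise(ds, level, np.random.default_rng(corrupt_seed))
    elif corruption == "missing":
        ds = mask_missing(ds, level, np.random.default_rng(corrupt_seed))
    config = config or reference_sampler_config()
    model = ThresholdNetworkModel(ds, hyper=hyper)
    res = model.fit(config, seed=fit_seed)
    ev = res.evaluate(lab.gold)
    return {"condition": condition, "auc_roc": ev.auc_roc, "auc_pr": ev.auc_pr,
            "acceptance_rate": res.samples.diagnostics["acceptance_rate"]}


def condition_benchmark(condition: str, n_replicates: int, seed: int,
                        config: SamplerConfig | None = None) -> dict:
    """Median AUCs over independent replicate datasets of one condition."""
    rows = [run_condition_replicate(condition, s, config)
            for s in _sub_seeds(seed, n_replicates)]
    aucs = np.array([r["auc_roc"] for r in rows])
    prs = np.array([r["auc_pr"] for r in rows])
    return {
        "condition": condition,
        "n": n_replicates,
        "auc_roc": aucs,
        "auc_pr": prs,
        "median_auc_roc": float(np.median(aucs)),
        "median_auc_pr": float(np.median(prs)),
    }


def sn2_feedback_run(seed: int, n_replicates: int = 3) -> dict:
    """Feedback-recovery study: fit the feedback network's data, full observations.

    Uses the original study's 5 x 3 chain layout.  Reports, per replicate and
    as medians: AUC_ROC, the posterior median weight of the feedback edge
    7 -> 4, and the quantile of its |median| among all candidate edges
    (1.0 = largest-magnitude edge score in the network).
    """
    rows = []
    for s in _sub_seeds(seed, n_replicates):
        data_seed, fit_seed = _sub_seeds(s, 2)
        lab = generate_sn2_data(np.random.default_rng(data_seed))
        config = SamplerConfig(n_subpops=5, chains_per_subpop=3,
                               n_steps=60_000, burn_in=4_000, seed=fit_seed)
        res = ThresholdNetworkModel(lab.dataset).fit(config)
        sc = res.edge_scores().scores
        n = sc.shape[0]
        fb = float(sc[6, 3])  # edge 7 -> 4 (0-based indices)
        mags = np.abs(sc[~np.eye(n, dtype=bool)])
        rows.append({
            "auc_roc": roc_pr(res.edge_scores(), GoldStandard(lab.gold)).auc_roc,
            "feedback_weight": fb,
            "feedback_rank_quantile": float((mags < abs(fb)).mean()),
        })
    return {
        "replicates": rows,
        "median_auc_roc": float(np.median([r["auc_roc"] for r in rows])),
        "median_feedback_weight": float(np.median([r["feedback_weight"] for r in rows])),
        "median_feedback_rank_quantile": float(
            np.median([r["feedback_rank_quantile"] for r in rows])),
    }
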