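"""File formats shared across the package.

Everything is plain text: tab-separated values with an explicit ``NA`` token,
UTF-8, Unix newlines, deterministic column order.  Numeric round trips are
exact to 12 significant digits (``%.12g``).

* networks: signed weighted edge list (``source  target  weight``) with a
  basal-weight sidecar (``node  w0``), or a square adjacency CSV;
* observations: long-form ``experiment  node  time_index  value`` with value
  in {0, 1, NA};
* perturbation designs: ``experiment  node  mode`` with mode in {KD, OE};
* posterior traces: one row per draw with ``sample  chain  sweep  log_post``
  followed by w_i_j, w0_i and tau_t columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import MISSING, ObservationDataset
from .network import Experiment, PerturbationDesign, SignalingNetwork
from .sampler import PosteriorSampleSet, SamplerConfig

_G = "%.17g"  # shortest exact round-trip for doubles


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_edge_list(net: SignalingNetwork, path: str | Path) -> None:
    """Edge-list TSV plus a ``<path>.basal`` sidecar of w0 values."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("source\ttarget\tweight\n")
        for i in range(net.n_nodes):
            for j in range(net.n_nodes):
                if net.weights[i, j] != 0.0:
                    fh.write(f"{net.node_names[i]}\t{net.node_names[j]}\t"
                             f"{_G % net.weights[i, j]}\n")
    with path.with_suffix(path.suffix + ".basal").open("w") as fh:
        fh.write("node\tw0\n")
        for i, name in enumerate(net.node_names):
            fh.write(f"{name}\t{_G % net.basal[i]}\n")


def read_edge_list(path: str | Path, gamma: float = 1.8) -> SignalingNetwork:
    path = Path(path)
    basal_path = path.with_suffix(path.suffix + ".basal")
    basal_df = pd.read_csv(basal_path, sep="\t", dtype={"node": str})
    names = list(basal_df["node"])
    idx = {n: i for i, n in enumerate(names)}
    W = np.zeros((len(names), len(names)))
    edges = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    for _, row in edges.iterrows():
        W[idx[row["source"]], idx[row["target"]]] = row["weight"]
    return SignalingNetwork(W, basal_df["w0"].to_numpy(float), gamma, names)


def write_adjacency_csv(net: SignalingNetwork, path: str | Path) -> None:
    df = pd.DataFrame(net.weights, index=net.node_names, columns=net.node_names)
    df.to_csv(path, float_format=_G)


def read_adjacency_csv(path: str | Path, basal: np.ndarray | None = None,
                       gamma: float = 1.8) -> SignalingNetwork:
    df = pd.read_csv(path, index_col=0)
    names = [str(c) for c in df.columns]
    W = df.to_numpy(float)
    if basal is None:
        basal = np.zeros(len(names))
    return SignalingNetwork(W, basal, gamma, names)


# ---------------------------------------------------------------------------
# designs and observations
# ---------------------------------------------------------------------------

def write_design(design: PerturbationDesign, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("experiment\tnode\tmode\n")
        for e in design.experiments:
            for i in sorted(e.clamped_off):
                fh.write(f"{e.label}\t{i + 1}\tKD\n")
            for i in sorted(e.clamped_on):
                fh.write(f"{e.label}\t{i + 1}\tOE\n")


def read_design(path: str | Path, n_nodes: int,
                experiment_order: list[str] | None = None) -> PerturbationDesign:
    df = pd.read_csv(path, sep="\t", dtype={"experiment": str, "mode": str})
    labels = experiment_order or list(dict.fromkeys(df["experiment"]))
    experiments = []
    for lab in labels:
        sub = df[df["experiment"] == lab]
        off = frozenset(int(n) - 1 for n in sub[sub["mode"] == "KD"]["node"])
        on = frozenset(int(n) - 1 for n in sub[sub["mode"] == "OE"]["node"])
        experiments.append(Experiment(clamped_off=off, clamped_on=on, label=lab))
    return PerturbationDesign(n_nodes=n_nodes, experiments=experiments)


def write_observations(dataset: ObservationDataset, path: str | Path) -> None:
    """Long-form TSV; a ``#tau:`` header comment preserves the step map."""
    with Path(path).open("w") as fh:
        fh.write("#tau:\t" + "\t".join(str(t) for t in dataset.tau) + "\n")
        fh.write("#time_points:\t"
                 + "\t".join(_G % t for t in dataset.time_points) + "\n")
        fh.write("experiment\tnode\ttime_index\tvalue\n")
        for k, e in enumerate(dataset.design.experiments):
            label = e.label or f"exp{k}"
            for t in range(dataset.n_times):
                for i in range(dataset.n_nodes):
                    v = dataset.obs[k, t, i]
                    fh.write(f"{label}\t{i + 1}\t{t}\t"
                             f"{'NA' if v == MISSING else int(v)}\n")


def read_observations(path: str | Path, design: PerturbationDesign) -> ObservationDataset:
    path = Path(path)
    tau = time_points = None
    with path.open() as fh:
        for line in fh:
            if line.startswith("#tau:"):
                tau = np.array([int(x) for x in line.split("\t")[1:]])
            elif line.startswith("#time_points:"):
                time_points = np.array([float(x) for x in line.split("\t")[1:]])
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                     dtype={"experiment": str, "value": str})
    labels = [e.label or f"exp{k}" for k, e in enumerate(design.experiments)]
    t_max = int(df["time_index"].max()) + 1
    obs = np.full((len(labels), t_max, design.n_nodes), MISSING, dtype=np.int8)
    lab_idx = {lab: k for k, lab in enumerate(labels)}
    for row in df.itertuples(index=False):
        if row.experiment not in lab_idx:
            raise ValueError(f"unknown experiment label {row.experiment!r}")
        v = MISSING if row.value == "NA" else int(row.value)
        obs[lab_idx[row.experiment], int(row.time_index), int(row.node) - 1] = v
    return ObservationDataset(design=design, obs=obs,
                              time_points=time_points, tau=tau)


# ---------------------------------------------------------------------------
# posterior traces
# ---------------------------------------------------------------------------

def write_trace(samples: PosteriorSampleSet, path: str | Path) -> None:
    n = samples.n_nodes
    names = samples.node_names or [str(i + 1) for i in range(n)]
    cols: dict[str, np.ndarray] = {
        "sample": np.arange(samples.n_samples),
        "chain": samples.chain,
        "sweep": samples.sweep,
        "log_post": samples.log_post,
    }
    for i in range(n):
        for j in range(n):
            if i != j:
                cols[f"w_{names[i]}_{names[j]}"] = samples.weights[:, i, j]
    for i in range(n):
        cols[f"w0_{names[i]}"] = samples.basal[:, i]
    for t in range(samples.tau.shape[1]):
        cols[f"tau_{t + 1}"] = samples.tau[:, t]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=_G)


def read_trace(path: str | Path) -> PosteriorSampleSet:
    df = pd.read_csv(path, sep="\t")
    w_cols = [c for c in df.columns if c.startswith("w_")]
    names = list(dict.fromkeys(c.split("_")[1] for c in w_cols))
    n = len(names)
    s = len(df)
    weights = np.zeros((s, n, n))
    for c in w_cols:
        _, src, tgt = c.split("_")
        weights[:, names.index(src), names.index(tgt)] = df[c].to_numpy()
    basal = np.column_stack([df[f"w0_{nm}"].to_numpy() for nm in names])
    tau_cols = sorted((c for c in df.columns if c.startswith("tau_")),
                      key=lambda c: int(c.split("_")[1]))
    tau = (np.column_stack([df[c].to_numpy(int) for c in tau_cols])
           if tau_cols else np.ones((s, 1), dtype=int))
    return PosteriorSampleSet(
        weights=weights, basal=basal, tau=tau,
        log_post=df["log_post"].to_numpy(float),
        chain=df["chain"].to_numpy(int), sweep=df["sweep"].to_numpy(int),
        config=SamplerConfig(), node_names=names,
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path, known_keys: set[str]) -> dict:
    """YAML config loader; unknown keys are rejected outright."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - known_keys
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return raw
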