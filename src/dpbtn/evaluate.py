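"""ROC / precision-recall evaluation of edge scores against a gold standard.

The discretization threshold delta is swept over every distinct |score|
magnitude (plus +inf for the empty network); tied magnitudes enter the
confusion counts at the same step, which makes the trapezoidal ROC area
coincide with the tie-corrected Mann-Whitney statistic.  The PR area uses
the step-wise (non-interpolated) convention, i.e. sum of precision times
recall increments.  Self-edges are excluded from the candidate universe;
undirected mode collapses ordered pairs by max |score| and ignores
direction in the gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregate import EdgeScoreMatrix


@dataclass
class GoldStandard:
    """Known generating network as a binary (N, N) directed adjacency."""

    adjacency: np.ndarray
    undirected: bool = False

    def __post_init__(self) -> None:
        self.adjacency = (np.asarray(self.adjacency) != 0).astype(int)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("gold standard must have an empty diagonal")


@dataclass
class EvalResult:
    """Threshold sweep with AUC summaries and a confusion at a named delta."""

    roc_points: pd.DataFrame   # columns: delta, fpr, tpr (specificity = 1-fpr)
    pr_points: pd.DataFrame    # columns: delta, recall, precision
    auc_roc: float
    auc_pr: float
    n_positives: int
    n_negatives: int
    degenerate: bool = False
    confusion: dict = field(default_factory=dict)


def _candidate_vectors(scores: EdgeScoreMatrix, gold: GoldStandard,
                       mode: str) -> tuple[np.ndarray, np.ndarray]:
    mag = scores.magnitudes()
    adj = gold.adjacency
    n = mag.shape[0]
    if adj.shape != (n, n):
        raise ValueError("score and gold-standard shapes differ")
    if mode == "directed":
        off = ~np.eye(n, dtype=bool)
        return mag[off], adj[off]
    if mode == "undirected":
        iu = np.triu_indices(n, k=1)
        y = np.maximum(adj, adj.T)[iu]
        s = np.maximum(mag, mag.T)[iu]
        return s, y
    raise ValueError("mode must be 'directed' or 'undirected'")


def roc_pr(scores: EdgeScoreMatrix, gold: GoldStandard,
           mode: str | None = None) -> EvalResult:
    """Full delta sweep with trapezoidal AUC_ROC and step-wise AUC_PR.

    ``mode`` defaults to the gold standard's own directedness flag.
    """
    if mode is None:
        mode = "undirected" if gold.undirected else "directed"
    s, y = _candidate_vectors(scores, gold, mode)
    P, Ng = int(y.sum()), int((1 - y).sum())
    thresholds = np.r_[np.inf, np.unique(s)[::-1]]
    tp = np.array([(s >= t)[y == 1].sum() for t in thresholds], dtype=float)
    fp = np.array([(s >= t)[y == 0].sum() for t in thresholds], dtype=float)
    degenerate = P == 0 or Ng == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = tp / P if P else np.zeros_like(tp)
        fpr = fp / Ng if Ng else np.zeros_like(fp)
        pred = tp + fp
        precision = np.where(pred > 0, tp / np.where(pred > 0, pred, 1.0), 0.0)
    auc_roc = float(np.trapezoid(tpr, fpr)) if not degenerate else float("nan")
    # step-wise PR area: sum of precision * recall increment
    d_rec = np.diff(tpr, prepend=0.0)
    auc_pr = float((precision * d_rec).sum()) if not degenerate else float("nan")
    roc_df = pd.DataFrame({"delta": thresholds, "fpr": fpr, "tpr": tpr,
                           "specificity": 1.0 - fpr, "sensitivity": tpr})
    pr_df = pd.DataFrame({"delta": thresholds, "recall": tpr,
                          "precision": precision})
    return EvalResult(
        roc_points=roc_df, pr_points=pr_df, auc_roc=auc_roc, auc_pr=auc_pr,
        n_positives=P, n_negatives=Ng, degenerate=degenerate,
    )


def confusion_at(scores: EdgeScoreMatrix, gold: GoldStandard, delta: float,
                 mode: str = "directed", relative: bool = False) -> dict:
    """Sensitivity/specificity/accuracy/precision of the delta-thresholded net.

    Precision with zero positive predictions is reported as 0.0 with the
    ``no_predictions`` flag set.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    s, y = _candidate_vectors(scores, gold, mode)
    thr = delta * s.max() if relative else delta
    pred = (s >= thr) & (s > 0)
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    no_pred = (tp + fp) == 0
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / (tp + fp + fn + tn),
        "precision": 0.0 if no_pred else tp / (tp + fp),
        "no_predictions": no_pred,
    }


def benchmark(replicates, infer_fn, mode: str = "directed") -> pd.DataFrame:
    """Run inference + evaluation over replicate (dataset, gold) pairs.

    ``infer_fn(dataset, replicate_index) -> EdgeScoreMatrix`` performs the
    inference; failures are recorded (NaN row) and excluded from medians.
    Returns a tidy frame with per-replicate AUCs; medians via
    ``summarize_benchmark``.
    """
    import logging

    rows = []
    for r, (dataset, gold) in enumerate(replicates):
        try:
            scores = infer_fn(dataset, r)
            res = roc_pr(scores, gold, mode=mode)
            rows.append({"replicate": r, "auc_roc": res.auc_roc,
                         "auc_pr": res.auc_pr, "failed": False})
        except Exception:  # noqa: BLE001 - a failed replicate must not kill the batch
            logging.getLogger(__name__).warning(
                "replicate %d failed; excluded from summaries", r, exc_info=True
            )
            rows.append({"replicate": r, "auc_roc": float("nan"),
                         "auc_pr": float("nan"), "failed": True})
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> dict:
    ok = table[~table["failed"]]
    return {
        "n": int(len(ok)),
        "median_auc_roc": float(ok["auc_roc"].median()),
        "median_auc_pr": float(ok["auc_pr"].median()),
        "iqr_auc_roc": float(ok["auc_roc"].quantile(0.75) - ok["auc_roc"].quantile(0.25)),
        "iqr_auc_pr": float(ok["auc_pr"].quantile(0.75) - ok["auc_pr"].quantile(0.25)),
    }
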