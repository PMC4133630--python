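"""Discretized perturbation time-course datasets.

The central container is :class:`ObservationDataset`: K perturbation
experiments x T measurement times x N nodes of {0, 1, missing} observations,
plus the model-step map ``tau`` giving the number of synchronous model updates
between consecutive measurement times.  Missing values are encoded as -1 in
the int8 observation array (``MISSING``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import PerturbationDesign

MISSING: int = -1


@dataclass
class ObservationDataset:
    """Observed {0,1,missing} node states for a perturbation time course.

    Parameters
    ----------
    design : PerturbationDesign
        The K experiments (clamped node sets) under which data were collected.
    obs : (K, T, N) int8 ndarray
        Observed states; -1 marks a missing observation.
    time_points : (T,) ndarray
        Real measurement times (only their order matters to the model).
    tau : (T-1,) int ndarray
        Model time steps elapsing between consecutive measurement times.
        Serves as the generating truth for simulated data and as the
        initialization when tau is sampled during inference.
    """

    design: PerturbationDesign
    obs: np.ndarray
    time_points: np.ndarray = field(default=None)  # type: ignore[assignment]
    tau: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.obs = np.asarray(self.obs, dtype=np.int8)
        if self.obs.ndim != 3:
            raise ValueError("obs must be a K x T x N array")
        k, t, n = self.obs.shape
        if k != len(self.design) or n != self.design.n_nodes:
            raise ValueError("obs shape inconsistent with design")
        if t < 2:
            raise ValueError("need at least two measurement time points")
        if not np.isin(self.obs, (MISSING, 0, 1)).all():
            raise ValueError("observations must be in {0, 1, -1 (missing)}")
        if self.time_points is None:
            self.time_points = np.arange(t, dtype=float)
        self.time_points = np.asarray(self.time_points, dtype=float)
        if self.time_points.shape != (t,):
            raise ValueError(f"time_points must have length {t}")
        if self.tau is None:
            self.tau = np.ones(t - 1, dtype=int)
        self.tau = np.asarray(self.tau, dtype=int)
        if self.tau.shape != (t - 1,):
            raise ValueError(f"tau must have length {t - 1}")
        if np.any(self.tau < 1):
            raise ValueError("every tau_t must be >= 1")
        self._validate_clamped()

    def _validate_clamped(self) -> None:
        off, on = self.design.clamp_masks()
        for k in range(self.n_experiments):
            o = self.obs[k]
            bad_off = (o[:, off[k]] == 1).any()
            bad_on = (o[:, on[k]] == 0).any()
            if bad_off or bad_on:
                warnings.warn(
                    f"experiment {k}: observations contradict clamps; "
                    "clamping takes precedence during inference",
                    stacklevel=3,
                )

    @property
    def n_experiments(self) -> int:
        return self.obs.shape[0]

    @property
    def n_times(self) -> int:
        return self.obs.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.obs.shape[2]

    @property
    def n_observed(self) -> int:
        """Number of non-missing observation cells."""
        return int((self.obs != MISSING).sum())

    def copy(self) -> "ObservationDataset":
        return ObservationDataset(
            design=self.design,
            obs=self.obs.copy(),
            time_points=self.time_points.copy(),
            tau=self.tau.copy(),
        )
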