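"""Decoupled per-gene estimation sub-problems.

A :class:`DecoupledProblem` owns everything needed to score candidate
parameter vectors for one target gene: the observed profile, the interpolated
off-target trajectories on the internal integration grid, the legal parameter
box, and the objective configuration (behavior-only relative MSE, optionally
combined with a prior-structure penalty).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import (
    ORDER_RANGE,
    OVERFLOW_CEILING,
    PRIOR_NONZERO,
    PRIOR_ZERO,
    RATE_RANGE,
    STATE_FLOOR,
    WORST_FITNESS,
    ExpressionProfile,
    FitnessConfig,
    GeneParameters,
    PriorStructure,
    interpolate_profile,
)

__all__ = ["DecoupledProblem"]


@dataclass
class DecoupledProblem:
    """Objective for estimating the S-system parameters of one gene."""

    observed: ExpressionProfile
    gene_index: int
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    prior: PriorStructure | None = None
    substeps: int = 1
    interp: str = "cubic"
    force_numpy: bool = False

    def __post_init__(self):
        n = self.observed.n_genes
        if not 0 <= self.gene_index < n:
            raise ValueError(f"gene_index {self.gene_index} outside 0..{n - 1}")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if self.fitness.weight_alpha < 1.0 and self.prior is None:
            raise ValueError("a structure-weighted objective needs a prior")
        times = self.observed.times
        steps = np.diff(times)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("decoupled integration requires uniform sampling")
        self._hstep = float(steps[0]) / self.substeps
        n_internal = (len(times) - 1) * self.substeps
        half_t = times[0] + np.arange(2 * n_internal + 1) * (self._hstep / 2.0)
        spline = interpolate_profile(self.observed, self.interp)
        self._log_half = np.ascontiguousarray(
            np.log(np.maximum(spline(half_t), STATE_FLOOR)))
        self._obs_i = np.ascontiguousarray(self.observed.values[:, self.gene_index])
        # prior masks over the 2N kinetic-order slots of this gene
        if self.prior is not None:
            known = np.concatenate((self.prior.g_known[self.gene_index],
                                    self.prior.h_known[self.gene_index]))
            self._zero_slots = known == PRIOR_ZERO
            self._nz_slots = known == PRIOR_NONZERO
            self._zpk = int(self._zero_slots.sum())
            self._nzpk = int(self._nz_slots.sum())

    # -- parameter-space geometry -------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.observed.n_genes

    @property
    def n_params(self) -> int:
        return 2 + 2 * self.n_genes

    @property
    def lower(self) -> np.ndarray:
        n = self.n_genes
        return np.concatenate(([RATE_RANGE[0]] * 2, [ORDER_RANGE[0]] * (2 * n)))

    @property
    def upper(self) -> np.ndarray:
        n = self.n_genes
        return np.concatenate(([RATE_RANGE[1]] * 2, [ORDER_RANGE[1]] * (2 * n)))

    def param_names(self) -> list[str]:
        """Human-readable labels: alpha_i, beta_i, g_ij, h_ij (1-based)."""
        i = self.gene_index + 1
        names = [f"alpha_{i}", f"beta_{i}"]
        names += [f"g_{i},{j + 1}" for j in range(self.n_genes)]
        names += [f"h_{i},{j + 1}" for j in range(self.n_genes)]
        return names

    def to_params(self, vec: np.ndarray) -> GeneParameters:
        return GeneParameters.from_vector(self.gene_index, vec)

    # -- evaluation ----------------------------------------------------------

    def behavior_error(self, positions: np.ndarray) -> np.ndarray:
        """Relative MSE of each candidate; diverged candidates get WORST_FITNESS."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        err, diverged = _kernels.batch_decoupled(
            positions, self._log_half, self._obs_i, self.gene_index,
            self._hstep, self.substeps, STATE_FLOOR, OVERFLOW_CEILING,
            mse_floor=self.fitness.mse_floor, record=False,
            force_numpy=self.force_numpy)
        err = np.where(diverged | ~np.isfinite(err), WORST_FITNESS, err)
        return err

    def structure_penalty(self, positions: np.ndarray) -> np.ndarray:
        """(sp1 + sp2)/2 of each candidate against the prior."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        ko_nz = np.abs(positions[:, 2:]) >= self.fitness.zero_threshold
        nzp = (ko_nz & self._zero_slots).sum(axis=1)
        zp = (~ko_nz & self._nz_slots).sum(axis=1)
        sp1 = nzp / self._zpk if self._zpk else np.zeros(len(positions))
        sp2 = zp / self._nzpk if self._nzpk else np.zeros(len(positions))
        return (sp1 + sp2) / 2.0

    def evaluate(self, positions: np.ndarray) -> np.ndarray:
        """Full objective of each candidate row; shape (P,)."""
        wa = self.fitness.weight_alpha
        err = self.behavior_error(positions)
        if wa == 1.0:
            return err
        return wa * err + (1.0 - wa) * self.structure_penalty(positions)

    def trajectories(self, positions: np.ndarray):
        """Predicted (P, T) decoupled trajectories and divergence flags."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        _, diverged, traj = _kernels.batch_decoupled(
            positions, self._log_half, self._obs_i, self.gene_index,
            self._hstep, self.substeps, STATE_FLOOR, OVERFLOW_CEILING,
            mse_floor=self.fitness.mse_floor, record=True,
            force_numpy=self.force_numpy)
        return traj, diverged
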