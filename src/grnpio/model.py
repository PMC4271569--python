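"""Core S-system model: parameter containers, simulation, and objective functions.

An S-system describes the expression level :math:`X_i` of each gene *i* in an
*N*-gene network by a difference of two power laws,

.. math::

    \\dot X_i \\;=\\; \\alpha_i \\prod_{j=1}^{N} X_j^{g_{ij}}
             \\;-\\; \\beta_i  \\prod_{j=1}^{N} X_j^{h_{ij}},

where the rate constants :math:`\\alpha_i, \\beta_i \\in [0, 10]` scale the
synthesis and degradation fluxes and the kinetic orders
:math:`g_{ij}, h_{ij} \\in [-3, 3]` quantify the regulatory influence of gene
*j* on gene *i* (sign = activation/repression, zero = no interaction).

The inference problem is *decoupled*: each gene's ODE is integrated on its own,
with the other genes' trajectories taken from the observed expression profile.
This module holds the reference (single-candidate) implementations; the batched
evaluator used by the optimizer lives in :mod:`grnpio.problem`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

__all__ = [
    "RATE_RANGE",
    "ORDER_RANGE",
    "STATE_FLOOR",
    "OVERFLOW_CEILING",
    "WORST_FITNESS",
    "PRIOR_ZERO",
    "PRIOR_NONZERO",
    "PRIOR_UNKNOWN",
    "GeneParameters",
    "SSystemNetwork",
    "ExpressionProfile",
    "PriorStructure",
    "StructureScore",
    "FitnessConfig",
    "NumericOverflowError",
    "SimulationDivergedError",
    "gene_derivative",
    "simulate_network",
    "simulate_gene_decoupled",
    "mse_fitness",
    "structure_priority",
    "combined_fitness",
]

#: Search range of the rate constants alpha_i and beta_i during inference.
#: (Representable systems only require non-negative rates: some published
#: benchmark systems use rate constants above 10.)
RATE_RANGE = (0.0, 10.0)
#: Search range of the kinetic orders g_ij and h_ij during inference.
ORDER_RANGE = (-3.0, 3.0)
#: States are clamped to this floor before applying power laws (negative bases
#: with fractional exponents are undefined).
STATE_FLOOR = 1e-6
#: Any state above this ceiling is treated as divergence.
OVERFLOW_CEILING = 1e6
#: Fitness assigned to candidates whose simulation diverges.
WORST_FITNESS = 1e12

# Prior-structure slot markers.
PRIOR_ZERO = 0
PRIOR_NONZERO = 1
PRIOR_UNKNOWN = -1


class NumericOverflowError(ArithmeticError):
    """A power-law evaluation produced a non-finite rate."""


class SimulationDivergedError(RuntimeError):
    """A trajectory exceeded :data:`OVERFLOW_CEILING` during integration."""

    def __init__(self, message: str, gene_index: int | None = None,
                 time_index: int | None = None):
        super().__init__(message)
        self.gene_index = gene_index
        self.time_index = time_index


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class GeneParameters:
    """S-system parameters of one gene: (alpha, beta, g[0..N-1], h[0..N-1])."""

    gene_index: int
    alpha: float
    beta: float
    g: np.ndarray
    h: np.ndarray

    def __post_init__(self):
        g = _as_float_array(self.g, "g")
        h = _as_float_array(self.h, "h")
        if g.ndim != 1 or h.ndim != 1 or len(g) != len(h):
            raise ValueError("g and h must be 1-D vectors of equal length")
        if self.gene_index < 0 or self.gene_index >= len(g):
            raise ValueError(f"gene_index {self.gene_index} outside 0..{len(g) - 1}")
        for name, value in (("alpha", self.alpha), ("beta", self.beta)):
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name}={value} must be finite and non-negative")
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "h", h)
        g.setflags(write=False)
        h.setflags(write=False)

    @property
    def n(self) -> int:
        return len(self.g)

    def to_vector(self) -> np.ndarray:
        """Flat layout used by the optimizer: [alpha, beta, g..., h...]."""
        return np.concatenate(([self.alpha, self.beta], self.g, self.h))

    @classmethod
    def from_vector(cls, gene_index: int, vec: np.ndarray) -> "GeneParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.ndim != 1 or (len(vec) - 2) % 2 != 0:
            raise ValueError("parameter vector must have length 2 + 2N")
        n = (len(vec) - 2) // 2
        return cls(gene_index, float(vec[0]), float(vec[1]),
                   vec[2:2 + n].copy(), vec[2 + n:].copy())


@dataclass(frozen=True)
class SSystemNetwork:
    """An ordered collection of N :class:`GeneParameters` plus gene labels."""

    genes: tuple
    names: tuple

    def __init__(self, genes: Sequence[GeneParameters], names: Sequence[str] | None = None):
        genes = tuple(genes)
        n = len(genes)
        if n == 0:
            raise ValueError("network needs at least one gene")
        for i, gp in enumerate(genes):
            if gp.n != n:
                raise ValueError(f"gene {i} has dimension {gp.n}, expected {n}")
            if gp.gene_index != i:
                raise ValueError(f"gene_index {gp.gene_index} at position {i}")
        if names is None:
            names = tuple(f"X{i + 1}" for i in range(n))
        names = tuple(str(s) for s in names)
        if len(names) != n:
            raise ValueError("names length does not match gene count")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def alpha(self) -> np.ndarray:
        return np.array([gp.alpha for gp in self.genes])

    @property
    def beta(self) -> np.ndarray:
        return np.array([gp.beta for gp in self.genes])

    @property
    def g(self) -> np.ndarray:
        """N x N synthesis kinetic-order matrix (row i = regulators of gene i)."""
        return np.vstack([gp.g for gp in self.genes])

    @property
    def h(self) -> np.ndarray:
        """N x N degradation kinetic-order matrix."""
        return np.vstack([gp.h for gp in self.genes])

    @classmethod
    def from_matrices(cls, alpha, beta, g, h, names=None) -> "SSystemNetwork":
        alpha = np.asarray(alpha, float)
        g = np.asarray(g, float)
        genes = [GeneParameters(i, float(alpha[i]), float(np.asarray(beta, float)[i]),
                                g[i].copy(), np.asarray(h, float)[i].copy())
                 for i in range(len(alpha))]
        return cls(genes, names)

    def equations(self) -> list[str]:
        """Render the system as canonical power-law ODE strings.

        Terms follow the field's conventional printed form, e.g.
        ``dX1/dt = 15.0*X3*X5^-0.1 - 10.0*X1^2.0``.
        """

        def term(coeff, orders):
            parts = [f"{coeff:.1f}"]
            for j, e in enumerate(orders):
                if e == 0:
                    continue
                if e == 1:
                    parts.append(f"X{j + 1}")
                else:
                    parts.append(f"X{j + 1}^{e:.1f}")
            return "*".join(parts)

        return [
            f"dX{i + 1}/dt = {term(gp.alpha, gp.g)} - {term(gp.beta, gp.h)}"
            for i, gp in enumerate(self.genes)
        ]


@dataclass(frozen=True)
class ExpressionProfile:
    """T x N matrix of non-negative concentrations with time stamps."""

    values: np.ndarray
    times: np.ndarray
    names: tuple

    def __init__(self, values, times, names=None):
        values = _as_float_array(values, "values")
        times = _as_float_array(times, "times")
        if values.ndim != 2:
            raise ValueError("values must be a T x N matrix")
        t, n = values.shape
        if t < 2:
            raise ValueError("profile needs at least two time points")
        if times.shape != (t,):
            raise ValueError("times length does not match number of rows")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("concentrations must be non-negative")
        if names is None:
            names = tuple(f"X{i + 1}" for i in range(n))
        names = tuple(str(s) for s in names)
        if len(names) != n:
            raise ValueError("names length does not match number of columns")
        values = values.copy()
        times = times.copy()
        values.setflags(write=False)
        times.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "names", names)

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PriorStructure:
    """Per-slot prior knowledge about kinetic orders.

    ``g_known`` / ``h_known`` are N x N integer matrices with entries
    :data:`PRIOR_ZERO` (no interaction), :data:`PRIOR_NONZERO` (interaction
    exists) or :data:`PRIOR_UNKNOWN` (no statement).
    """

    g_known: np.ndarray
    h_known: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.g_known, dtype=int)
        h = np.asarray(self.h_known, dtype=int)
        if g.shape != h.shape or g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("g_known and h_known must be equal square matrices")
        valid = {PRIOR_ZERO, PRIOR_NONZERO, PRIOR_UNKNOWN}
        if not set(np.unique(g)) <= valid or not set(np.unique(h)) <= valid:
            raise ValueError("prior entries must be in {zero, nonzero, unknown}")
        object.__setattr__(self, "g_known", g)
        object.__setattr__(self, "h_known", h)

    @property
    def n(self) -> int:
        return self.g_known.shape[0]

    @classmethod
    def from_network(cls, net: SSystemNetwork, zero_threshold: float = 0.1) -> "PriorStructure":
        """Derive a complete zero/nonzero prior from a reference network."""
        g_nz = (np.abs(net.g) >= zero_threshold).astype(int)
        h_nz = (np.abs(net.h) >= zero_threshold).astype(int)
        return cls(g_nz, h_nz)


@dataclass(frozen=True)
class StructureScore:
    """Counts and ratios of structural disagreement with a prior (one gene)."""

    nzp: int   # inferred non-zero where prior says zero
    zp: int    # inferred zero where prior says non-zero
    sp1: float
    sp2: float


@dataclass(frozen=True)
class FitnessConfig:
    """Weights and numeric guards of the combined objective.

    ``weight_alpha`` is the behavior/structure weighting of the combined
    objective (1 = behavior only); named to avoid collision with the rate
    constants.  ``zero_threshold`` is the magnitude below which a kinetic order
    counts as zero; ``mse_floor`` guards the relative-error denominator.
    """

    weight_alpha: float = 1.0
    zero_threshold: float = 0.1
    mse_floor: float = 1e-6

    def __post_init__(self):
        if not 0.0 <= self.weight_alpha <= 1.0:
            raise ValueError("weight_alpha must lie in [0, 1]")
        if self.zero_threshold <= 0 or self.mse_floor <= 0:
            raise ValueError("zero_threshold and mse_floor must be positive")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def gene_derivative(params: GeneParameters, state) -> float:
    """Rate of change of one gene: alpha*prod(X^g) - beta*prod(X^h).

    States are clamped to :data:`STATE_FLOOR` before the power laws are
    applied.  A non-finite result (overflow from large kinetic orders) raises
    :class:`NumericOverflowError`.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (params.n,):
        raise ValueError(f"state must have length {params.n}")
    lx = np.log(np.maximum(state, STATE_FLOOR))
    rate = params.alpha * np.exp(params.g @ lx) - params.beta * np.exp(params.h @ lx)
    if not np.isfinite(rate):
        raise NumericOverflowError(
            f"non-finite derivative for gene {params.gene_index}")
    return float(rate)


def _network_rates(alpha, beta, g, h, x):
    lx = np.log(np.maximum(x, STATE_FLOOR))
    return alpha * np.exp(g @ lx) - beta * np.exp(h @ lx)


def simulate_network(net: SSystemNetwork, x0, n_steps: int = 30, dt: float = 0.01,
                     substeps: int = 1) -> ExpressionProfile:
    """Integrate the coupled system with fixed-step classical Runge-Kutta.

    Records ``n_steps + 1`` rows (including the initial state) spaced ``dt``
    apart; each sampling interval is integrated with ``substeps`` internal RK4
    steps.  Raises :class:`SimulationDivergedError` naming the first divergent
    time index if any state exceeds :data:`OVERFLOW_CEILING`.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (net.n,):
        raise ValueError(f"x0 must have length {net.n}")
    if np.any(x0 <= 0):
        raise ValueError("initial state components must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if dt <= 0 or substeps < 1:
        raise ValueError("dt must be positive and substeps >= 1")

    alpha, beta, g, h = net.alpha, net.beta, net.g, net.h
    hstep = dt / substeps
    x = x0.copy()
    out = np.empty((n_steps + 1, net.n))
    out[0] = x
    for k in range(n_steps):
        for _ in range(substeps):
            k1 = _network_rates(alpha, beta, g, h, x)
            k2 = _network_rates(alpha, beta, g, h, np.maximum(x + hstep / 2 * k1, STATE_FLOOR))
            k3 = _network_rates(alpha, beta, g, h, np.maximum(x + hstep / 2 * k2, STATE_FLOOR))
            k4 = _network_rates(alpha, beta, g, h, np.maximum(x + hstep * k3, STATE_FLOOR))
            x = np.maximum(x + hstep / 6 * (k1 + 2 * k2 + 2 * k3 + k4), STATE_FLOOR)
        if np.any(x > OVERFLOW_CEILING) or not np.all(np.isfinite(x)):
            bad = int(np.argmax((x > OVERFLOW_CEILING) | ~np.isfinite(x)))
            raise SimulationDivergedError(
                f"state of gene {bad} diverged at time index {k + 1}",
                gene_index=bad, time_index=k + 1)
        out[k + 1] = x
    times = np.arange(n_steps + 1) * dt
    return ExpressionProfile(out, times, net.names)


def interpolate_profile(profile: ExpressionProfile, kind: str = "cubic"):
    """Interpolant of an observed profile used for decoupled integration."""
    if kind == "cubic":
        return CubicSpline(profile.times, profile.values)
    if kind == "linear":
        return interp1d(profile.times, profile.values, axis=0)
    raise ValueError(f"unknown interpolation kind {kind!r}")


def simulate_gene_decoupled(params: GeneParameters, observed: ExpressionProfile,
                            gene_index: int | None = None, substeps: int = 1,
                            interp: str = "cubic") -> np.ndarray:
    """Integrate only gene *i*'s ODE against the observed off-target genes.

    At every integration stage the states of genes ``j != i`` are interpolated
    from ``observed``; the predicted value at ``times[0]`` equals the observed
    initial value.  Returns the predicted T-vector for gene *i*.
    """
    if gene_index is None:
        gene_index = params.gene_index
    if not 0 <= gene_index < observed.n_genes:
        raise ValueError(f"gene_index {gene_index} outside profile")
    if observed.n_genes != params.n:
        raise ValueError("observed profile does not cover all genes")
    # Delegate to the batched evaluator so the reference path and the
    # optimizer's fast path are numerically identical by construction.
    from .problem import DecoupledProblem

    problem = DecoupledProblem(observed, gene_index, substeps=substeps, interp=interp)
    traj, diverged = problem.trajectories(params.to_vector()[None, :])
    if diverged[0]:
        raise SimulationDivergedError(
            f"decoupled trajectory of gene {gene_index} diverged",
            gene_index=gene_index)
    return traj[0]


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def mse_fitness(predicted, observed, floor: float = 1e-6) -> float:
    """Relative mean-squared-error fitness of a single-gene trajectory.

    ``sum_t ((pred(t) - obs(t)) / max(obs(t), floor))^2`` -- zero iff the
    trajectories coincide.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed lengths differ")
    if np.any(observed < 0):
        raise ValueError("observed values must be non-negative")
    denom = np.maximum(observed, floor)
    return float(np.sum(((predicted - observed) / denom) ** 2))


def structure_priority(params: GeneParameters, prior: PriorStructure,
                       zero_threshold: float = 0.1) -> StructureScore:
    """Score one gene's kinetic orders against prior zero/nonzero knowledge.

    An inferred order counts as zero iff its magnitude is below
    ``zero_threshold``.  ``sp1 = nzp / zPK`` penalizes inferred interactions
    the prior forbids; ``sp2 = zp / nzPK`` penalizes missing interactions the
    prior requires (each 0 when its denominator is 0).  Slots marked unknown
    are ignored.
    """
    i = params.gene_index
    if prior.n != params.n:
        raise ValueError("prior dimension does not match gene")
    inferred_nz = np.concatenate((np.abs(params.g) >= zero_threshold,
                                  np.abs(params.h) >= zero_threshold))
    known = np.concatenate((prior.g_known[i], prior.h_known[i]))
    zero_slots = known == PRIOR_ZERO
    nz_slots = known == PRIOR_NONZERO
    nzp = int(np.sum(inferred_nz & zero_slots))
    zp = int(np.sum(~inferred_nz & nz_slots))
    zpk = int(zero_slots.sum())
    nzpk = int(nz_slots.sum())
    sp1 = nzp / zpk if zpk else 0.0
    sp2 = zp / nzpk if nzpk else 0.0
    return StructureScore(nzp=nzp, zp=zp, sp1=sp1, sp2=sp2)


def combined_fitness(mse: float, score: StructureScore | None,
                     cfg: FitnessConfig) -> float:
    """Weighted objective: weight_alpha * MSE + (1 - weight_alpha) * StrPri.

    ``StrPri = (sp1 + sp2) / 2`` lies in [0, 1], commensurate with the
    per-gene relative MSE.  With ``weight_alpha = 1`` this equals the MSE
    exactly and ``score`` may be None.
    """
    wa = cfg.weight_alpha
    if wa == 1.0 or score is None:
        return float(mse)
    strpri = (score.sp1 + score.sp2) / 2.0
    return float(wa * mse + (1.0 - wa) * strpri)
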