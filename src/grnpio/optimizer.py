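"""Hybrid GA-PSO search and the integrated identification/optimization loop.

Each generation the population is ranked by fitness and split into an elite
part, refined by a particle-swarm update, and a pending part, regenerated by
genetic operators (tournament selection, blend crossover, bounded Gaussian
mutation).  Periodically the loop interleaves two extra phases:

* an **identification phase** runs m-MPSA around the population best,
  classifies parameters as sensitive/insensitive against the threshold CCR,
  and re-centers the per-parameter search bounds at the population best --
  tight (factor 2 x velocity bound) for sensitive parameters, loose (factor
  5) for insensitive ones -- regenerating every particle inside the new box;
  CCR then grows by epsilon so parameters migrate into the sensitive class
  over the run;
* an **exploration phase** regenerates every particle except the top 1% to
  keep the population diverse.

The population best (gbest) is tracked across all phases and never worsens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import GeneParameters
from .problem import DecoupledProblem
from .sensitivity import SensitivityConfig, SensitivityReport, mpsa, update_ccr

__all__ = [
    "BoundsSet",
    "PIOConfig",
    "Population",
    "PIOResult",
    "init_population",
    "rank_and_split",
    "pso_step",
    "ga_step",
    "assign_bounds",
    "exploration_phase",
    "run_pio",
]

#: Default velocity bound for rate constants (range [0, 10]).
VELOCITY_BOUND_RATE = 2.0
#: Default velocity bound for kinetic orders (range [-3, 3]).
VELOCITY_BOUND_ORDER = 1.0


@dataclass(frozen=True)
class BoundsSet:
    """Per-parameter search box plus velocity bounds and phase factors."""

    lower: np.ndarray
    upper: np.ndarray
    velocity_bound: np.ndarray
    legal_lower: np.ndarray
    legal_upper: np.ndarray
    tight_factor: float = 2.0
    loose_factor: float = 5.0
    min_width: float = 1e-3

    def __post_init__(self):
        for name in ("lower", "upper", "velocity_bound", "legal_lower", "legal_upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.lower >= self.upper):
            raise ValueError("bounds must satisfy lower < upper")
        if np.any(self.velocity_bound <= 0):
            raise ValueError("velocity bounds must be positive")

    @classmethod
    def from_problem(cls, problem: DecoupledProblem,
                     velocity_bound_rate: float = VELOCITY_BOUND_RATE,
                     velocity_bound_order: float = VELOCITY_BOUND_ORDER,
                     **kwargs) -> "BoundsSet":
        lo, hi = problem.lower, problem.upper
        vb = np.concatenate(([velocity_bound_rate] * 2,
                             [velocity_bound_order] * (problem.n_params - 2)))
        return cls(lo.copy(), hi.copy(), vb, lo.copy(), hi.copy(), **kwargs)

    @property
    def n_params(self) -> int:
        return len(self.lower)


@dataclass
class Population:
    """Array-of-struct particle swarm with local/global best bookkeeping."""

    positions: np.ndarray
    velocities: np.ndarray
    fitness: np.ndarray
    local_best_positions: np.ndarray
    local_best_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float
    generation: int = 0

    @property
    def size(self) -> int:
        return len(self.positions)

    def refresh_gbest(self) -> None:
        i = int(np.argmin(self.local_best_fitness))
        if self.local_best_fitness[i] < self.gbest_fitness:
            self.gbest_fitness = float(self.local_best_fitness[i])
            self.gbest_position = self.local_best_positions[i].copy()


@dataclass(frozen=True)
class PIOConfig:
    """All run constants of the integrated loop.

    Intervals of 0 disable the corresponding phase; with both disabled the
    loop reduces to the plain hybrid GA-PSO.
    """

    max_gen: int = 5000
    pop_size: int = 200
    randomness_rate: float = 0.5          # r: fraction regenerated by the GA
    identification_interval: int = 500
    exploration_interval: int = 1000
    elite_keep_fraction: float = 0.01
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    tournament_size: int = 2
    blx_alpha: float = 0.5
    mutation_rate: float = 0.05
    mutation_sigma_frac: float = 0.05
    velocity_bound_rate: float = VELOCITY_BOUND_RATE
    velocity_bound_order: float = VELOCITY_BOUND_ORDER
    seed: int = 0
    sensitivity: SensitivityConfig = field(default_factory=SensitivityConfig)

    def __post_init__(self):
        if not 0.0 < self.randomness_rate < 1.0:
            raise ValueError("randomness_rate must lie in (0, 1)")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not 0.0 < self.elite_keep_fraction < 1.0:
            raise ValueError("elite_keep_fraction must lie in (0, 1)")
        if self.identification_interval < 0 or self.exploration_interval < 0:
            raise ValueError("intervals must be >= 0 (0 disables)")


@dataclass
class PIOResult:
    """Outcome of one decoupled sub-problem run."""

    params: GeneParameters
    position: np.ndarray
    fitness: float
    gbest_history: np.ndarray            # per-generation gbest fitness
    phase_generations: list              # generation of each identification phase
    phase_mean_sensitivity: list         # Figure-3-style per-phase series
    phase_ccr: list
    final_report: SensitivityReport | None
    evaluations: int


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def init_population(n: int, bounds: BoundsSet, rng, problem: DecoupledProblem) -> Population:
    """Uniform random swarm inside the bounds; local bests = start positions."""
    if n < 2:
        raise ValueError("population size must be >= 2")
    rng = np.random.default_rng(rng)
    d = bounds.n_params
    positions = rng.uniform(bounds.lower, bounds.upper, (n, d))
    velocities = rng.uniform(-bounds.velocity_bound, bounds.velocity_bound, (n, d))
    fitness = problem.evaluate(positions)
    i = int(np.argmin(fitness))
    return Population(
        positions=positions,
        velocities=velocities,
        fitness=fitness,
        local_best_positions=positions.copy(),
        local_best_fitness=fitness.copy(),
        gbest_position=positions[i].copy(),
        gbest_fitness=float(fitness[i]),
    )


def rank_and_split(pop: Population, r: float):
    """Indices of the elite (best ceil((1-r)n)) and pending particles.

    Stable sort: ties are broken by particle index.
    """
    if not 0.0 < r < 1.0:
        raise ValueError("r must lie in (0, 1)")
    order = np.argsort(pop.fitness, kind="stable")
    n_elite = int(np.ceil((1.0 - r) * pop.size))
    return order[:n_elite], order[n_elite:]


def pso_step(pop: Population, elite: np.ndarray, bounds: BoundsSet,
             cfg: PIOConfig, rng, problem: DecoupledProblem) -> None:
    """Standard PSO velocity/position update of the elite particles."""
    rng = np.random.default_rng(rng)
    e = np.asarray(elite)
    if e.size == 0:
        return
    d = bounds.n_params
    r1 = rng.random((len(e), d))
    r2 = rng.random((len(e), d))
    vel = (cfg.inertia * pop.velocities[e]
           + cfg.cognitive * r1 * (pop.local_best_positions[e] - pop.positions[e])
           + cfg.social * r2 * (pop.gbest_position - pop.positions[e]))
    vel = np.clip(vel, -bounds.velocity_bound, bounds.velocity_bound)
    pos = np.clip(pop.positions[e] + vel, bounds.lower, bounds.upper)
    fit = problem.evaluate(pos)
    pop.velocities[e] = vel
    pop.positions[e] = pos
    pop.fitness[e] = fit
    improved = fit < pop.local_best_fitness[e]
    idx = e[improved]
    pop.local_best_positions[idx] = pos[improved]
    pop.local_best_fitness[idx] = fit[improved]
    pop.refresh_gbest()


def ga_step(pop: Population, pending: np.ndarray, bounds: BoundsSet,
            cfg: PIOConfig, rng, problem: DecoupledProblem) -> None:
    """Replace the pending particles by tournament-selected offspring.

    Two parents per slot (tournament over the full population), blend (BLX)
    crossover, bounded Gaussian mutation, clip to the current bounds.
    Replacements get fresh velocities; their local bests are reset to their
    own positions.
    """
    rng = np.random.default_rng(rng)
    p = np.asarray(pending)
    if p.size == 0:
        return
    m = len(p)
    d = bounds.n_params
    n = pop.size

    def tournament():
        cand = rng.integers(0, n, (m, cfg.tournament_size))
        return cand[np.arange(m), np.argmin(pop.fitness[cand], axis=1)]

    x1 = pop.positions[tournament()]
    x2 = pop.positions[tournament()]
    cmin = np.minimum(x1, x2)
    cmax = np.maximum(x1, x2)
    spread = cmax - cmin
    child = rng.uniform(cmin - cfg.blx_alpha * spread, cmax + cfg.blx_alpha * spread)
    mutate = rng.random((m, d)) < cfg.mutation_rate
    sigma = cfg.mutation_sigma_frac * (bounds.legal_upper - bounds.legal_lower)
    child = child + mutate * rng.normal(0.0, 1.0, (m, d)) * sigma
    child = np.clip(child, bounds.lower, bounds.upper)
    fit = problem.evaluate(child)
    pop.positions[p] = child
    pop.velocities[p] = rng.uniform(-bounds.velocity_bound, bounds.velocity_bound, (m, d))
    pop.fitness[p] = fit
    pop.local_best_positions[p] = child
    pop.local_best_fitness[p] = fit
    pop.refresh_gbest()


def assign_bounds(sensitive_mask: np.ndarray, gbest_position: np.ndarray,
                  bounds: BoundsSet) -> BoundsSet:
    """Re-center the search box at the population best.

    Sensitive parameters get tight intervals ``gbest_i +/- 2 * vb_i``,
    insensitive ones loose intervals with factor 5; both are clipped to the
    legal ranges.  An interval collapsed by clipping is widened to
    ``min_width`` around its clipped center.
    """
    sensitive_mask = np.asarray(sensitive_mask, dtype=bool)
    if sensitive_mask.shape != (bounds.n_params,):
        raise ValueError("classification must cover every parameter")
    factor = np.where(sensitive_mask, bounds.tight_factor, bounds.loose_factor)
    half = factor * bounds.velocity_bound
    lo = np.clip(gbest_position - half, bounds.legal_lower, bounds.legal_upper)
    hi = np.clip(gbest_position + half, bounds.legal_lower, bounds.legal_upper)
    narrow = hi - lo < bounds.min_width
    if np.any(narrow):
        center = (lo + hi) / 2.0
        lo = np.where(narrow, np.clip(center - bounds.min_width / 2,
                                      bounds.legal_lower, bounds.legal_upper), lo)
        hi = np.where(narrow, lo + bounds.min_width, hi)
        hi = np.minimum(hi, bounds.legal_upper)
        lo = np.where(narrow, hi - bounds.min_width, lo)
    return replace(bounds, lower=lo, upper=hi)


def regenerate_population(pop: Population, bounds: BoundsSet, rng,
                          problem: DecoupledProblem,
                          keep: np.ndarray | None = None) -> None:
    """Redraw particle positions uniformly inside the current bounds.

    Local bests are overwritten by the regenerated positions; the recorded
    global best is updated only if a regenerated particle improves on it.
    Particles listed in ``keep`` are left untouched.
    """
    rng = np.random.default_rng(rng)
    idx = np.arange(pop.size)
    if keep is not None and len(keep):
        idx = np.setdiff1d(idx, keep)
    if idx.size == 0:
        return
    d = bounds.n_params
    pos = rng.uniform(bounds.lower, bounds.upper, (len(idx), d))
    vel = rng.uniform(-bounds.velocity_bound, bounds.velocity_bound, (len(idx), d))
    fit = problem.evaluate(pos)
    pop.positions[idx] = pos
    pop.velocities[idx] = vel
    pop.fitness[idx] = fit
    pop.local_best_positions[idx] = pos
    pop.local_best_fitness[idx] = fit
    pop.refresh_gbest()


def exploration_phase(pop: Population, bounds: BoundsSet,
                      elite_keep_fraction: float, rng,
                      problem: DecoupledProblem) -> None:
    """Diversity restart: regenerate all but the top ceil(frac * n) particles."""
    n_keep = int(np.ceil(elite_keep_fraction * pop.size))
    order = np.argsort(pop.fitness, kind="stable")
    regenerate_population(pop, bounds, rng, problem, keep=order[:n_keep])


# ---------------------------------------------------------------------------
# the integrated loop
# ---------------------------------------------------------------------------

def run_pio(problem: DecoupledProblem, cfg: PIOConfig | None = None,
            final_sensitivity: bool = True) -> PIOResult:
    """Run the full identification/optimization loop on one sub-problem.

    The per-phase mean sensitivity recorded in the history is measured by a
    dedicated m-MPSA over the full legal ranges with a per-run fixed seed
    (common random numbers across phases), so consecutive phases are
    comparable; the classification that drives the bound assignment uses the
    current search bounds, as the algorithm prescribes.  When
    ``final_sensitivity`` is set, a full-range report around the final best is
    attached regardless of whether identification phases ran.
    """
    cfg = cfg or PIOConfig()
    root = np.random.SeedSequence(cfg.seed)
    s_init, s_loop, s_mpsa, s_history, s_final = root.spawn(5)
    rng = np.random.default_rng(s_loop)
    history_seed = int(s_history.generate_state(1)[0] % (2**31))
    mpsa_rng = np.random.default_rng(s_mpsa)

    bounds = BoundsSet.from_problem(
        problem, velocity_bound_rate=cfg.velocity_bound_rate,
        velocity_bound_order=cfg.velocity_bound_order)
    pop = init_population(cfg.pop_size, bounds, np.random.default_rng(s_init), problem)
    evaluations = cfg.pop_size

    ccr = cfg.sensitivity.ccr
    gbest_history = np.empty(cfg.max_gen)
    phase_generations: list[int] = []
    phase_mean_sensitivity: list[float] = []
    phase_ccr: list[float] = []

    sa_cfg = cfg.sensitivity
    for gen in range(1, cfg.max_gen + 1):
        if cfg.identification_interval and gen % cfg.identification_interval == 0:
            ranges = np.column_stack((bounds.lower, bounds.upper))
            report = mpsa(problem, pop.gbest_position,
                          replace(sa_cfg, ranges=ranges, ccr=ccr),
                          seed=mpsa_rng)
            evaluations += sa_cfg.n_samples * problem.n_params
            if ccr is None:
                ccr = report.ccr_used
            bounds = assign_bounds(report.sensitivity <= ccr,
                                   pop.gbest_position, bounds)
            regenerate_population(pop, bounds, rng, problem)
            evaluations += cfg.pop_size
            # comparable-scale history metric (full ranges, common seed)
            hist = mpsa(problem, pop.gbest_position,
                        replace(sa_cfg, ranges=None, ccr=ccr),
                        seed=history_seed)
            evaluations += sa_cfg.n_samples * problem.n_params
            phase_generations.append(gen)
            phase_mean_sensitivity.append(hist.mean_sensitivity)
            phase_ccr.append(float(ccr))
            ccr = update_ccr(ccr, sa_cfg.epsilon)
        if cfg.exploration_interval and gen % cfg.exploration_interval == 0:
            exploration_phase(pop, bounds, cfg.elite_keep_fraction, rng, problem)
            evaluations += pop.size
        elite, pending = rank_and_split(pop, cfg.randomness_rate)
        pso_step(pop, elite, bounds, cfg, rng, problem)
        ga_step(pop, pending, bounds, cfg, rng, problem)
        evaluations += pop.size
        pop.generation = gen
        gbest_history[gen - 1] = pop.gbest_fitness

    final_report = None
    if final_sensitivity:
        final_report = mpsa(problem, pop.gbest_position,
                            replace(sa_cfg, ranges=None, ccr=ccr),
                            seed=np.random.default_rng(s_final))
        evaluations += sa_cfg.n_samples * problem.n_params

    return PIOResult(
        params=problem.to_params(pop.gbest_position),
        position=pop.gbest_position.copy(),
        fitness=float(pop.gbest_fitness),
        gbest_history=gbest_history,
        phase_generations=phase_generations,
        phase_mean_sensitivity=phase_mean_sensitivity,
        phase_ccr=phase_ccr,
        final_report=final_report,
        evaluations=evaluations,
    )
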