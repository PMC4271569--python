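"""Modified multi-parameter sensitivity analysis (m-MPSA).

For each parameter of a decoupled sub-problem, candidate solutions are formed
by sampling the parameter uniformly within its range (one at a time around an
anchor vector by default; a classic joint-sampling mode is available).  Each
candidate is scored by the sub-problem objective and split into *acceptable* /
*unacceptable* by the threshold ``Cr`` -- a multiple (3 by default) of the
best fitness among the sampled candidates.  The parameter's sensitivity is
the Pearson correlation between the cumulative-frequency curves of the
acceptable and unacceptable sample values, evaluated on the common grid of
all sampled values: curves that coincide (the parameter does not influence
acceptability) give a correlation near 1, strongly diverging curves give low
values.  *Low* sensitivity therefore marks *influential* parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SensitivityConfig",
    "SensitivityReport",
    "sample_parameter",
    "split_acceptable",
    "sensitivity_of_parameter",
    "mpsa",
    "classify_parameters",
    "update_ccr",
]

#: Sensitivity assigned when the PCC is undefined (all samples acceptable,
#: all unacceptable, or a zero-variance CF curve): maximally insensitive.
DEGENERATE_SENSITIVITY = 1.0


@dataclass(frozen=True)
class SensitivityConfig:
    """Settings of one m-MPSA pass.

    ``ranges`` (shape ``(n_params, 2)``) defaults to the sub-problem's legal
    parameter box.  ``ccr`` may be an absolute threshold; when None the
    classification threshold is initialized from the ``ccr_quantile`` of the
    first report's sensitivity distribution.
    """

    n_samples: int = 500
    cr_multiplier: float = 3.0
    ccr: float | None = None
    ccr_quantile: float = 0.25
    epsilon: float = 0.01
    ranges: np.ndarray | None = None
    joint: bool = False

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.cr_multiplier <= 1:
            raise ValueError("cr_multiplier must exceed 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.ranges is not None:
            r = np.asarray(self.ranges, dtype=float)
            if r.ndim != 2 or r.shape[1] != 2 or np.any(r[:, 0] > r[:, 1]):
                raise ValueError("ranges must be (n_params, 2) with lo <= hi")
            object.__setattr__(self, "ranges", r)


@dataclass(frozen=True)
class SensitivityReport:
    """Per-parameter sensitivities, ranking and classification."""

    sensitivity: np.ndarray
    ccr_used: float
    param_names: tuple
    degenerate: np.ndarray

    @property
    def n_params(self) -> int:
        return len(self.sensitivity)

    @property
    def rank(self) -> np.ndarray:
        """Parameter indices ordered by ascending sensitivity (most sensitive
        first); ties broken by parameter index."""
        return np.argsort(self.sensitivity, kind="stable")

    @property
    def sensitive(self) -> np.ndarray:
        """Boolean mask: sensitive iff sensitivity <= ccr_used."""
        return self.sensitivity <= self.ccr_used

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.sensitivity))

    def to_frame(self) -> pd.DataFrame:
        order = np.empty(self.n_params, dtype=int)
        order[self.rank] = np.arange(self.n_params)
        return pd.DataFrame({
            "parameter": list(self.param_names),
            "sensitivity": self.sensitivity,
            "rank": order,
            "class": np.where(self.sensitive, "sensitive", "insensitive"),
            "degenerate": self.degenerate,
        })


def sample_parameter(interval, n: int, rng) -> np.ndarray:
    """n i.i.d. uniform draws in [lo, hi]; a point interval returns n copies."""
    lo, hi = float(interval[0]), float(interval[1])
    if hi < lo:
        raise ValueError("empty interval")
    rng = np.random.default_rng(rng)
    if hi == lo:
        return np.full(n, lo)
    return rng.uniform(lo, hi, n)


def split_acceptable(fitnesses, cr_multiplier: float = 3.0):
    """Mask of acceptable candidates and the threshold Cr.

    ``Cr = cr_multiplier * min(fitnesses)``; a candidate is acceptable iff its
    fitness is <= Cr, so the best candidate is always acceptable.
    """
    fitnesses = np.asarray(fitnesses, dtype=float)
    if fitnesses.size < 1:
        raise ValueError("need at least one fitness value")
    if np.any(~np.isfinite(fitnesses)) or np.any(fitnesses < 0):
        raise ValueError("fitnesses must be finite and non-negative")
    cr = cr_multiplier * fitnesses.min()
    return fitnesses <= cr, float(cr)


def sensitivity_of_parameter(values, mask) -> float:
    """PCC of the acceptable and unacceptable cumulative-frequency curves.

    Both curves are evaluated on the common grid of sorted sampled values:
    ``CF_acc(v)`` is the fraction of acceptable samples <= v, likewise for
    the unacceptable samples.  Degenerate cases (one group empty, or a
    zero-variance curve) return :data:`DEGENERATE_SENSITIVITY`.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape or values.ndim != 1 or len(values) < 2:
        raise ValueError("values and mask must be equal-length vectors, n >= 2")
    n_acc = int(mask.sum())
    n_un = len(values) - n_acc
    if n_acc == 0 or n_un == 0:
        return DEGENERATE_SENSITIVITY
    grid = np.sort(values)
    acc = np.sort(values[mask])
    un = np.sort(values[~mask])
    cf_acc = np.searchsorted(acc, grid, side="right") / n_acc
    cf_un = np.searchsorted(un, grid, side="right") / n_un
    if cf_acc.std() == 0.0 or cf_un.std() == 0.0:
        return DEGENERATE_SENSITIVITY
    return float(np.corrcoef(cf_acc, cf_un)[0, 1])


def mpsa(problem, anchor, cfg: SensitivityConfig | None = None, seed=0) -> SensitivityReport:
    """Run m-MPSA for every parameter of a decoupled sub-problem.

    One at a time (default), each parameter is sampled ``n_samples`` times in
    its range; candidates substitute the sampled value into ``anchor``
    (normally the current population best).  In ``joint`` mode a single batch
    of fully random candidates is shared by all parameters, as in classic
    MPSA.  Candidates whose simulation fails are assigned the worst-case
    fitness by the problem evaluator and land in the unacceptable group.
    """
    cfg = cfg or SensitivityConfig()
    anchor = np.asarray(anchor, dtype=float)
    d = problem.n_params
    if anchor.shape != (d,):
        raise ValueError(f"anchor must have length {d}")
    if cfg.ranges is not None:
        if len(cfg.ranges) != d:
            raise ValueError("ranges length does not match problem")
        ranges = cfg.ranges
    else:
        ranges = np.column_stack((problem.lower, problem.upper))
    rng = np.random.default_rng(seed)
    sens = np.empty(d)
    degenerate = np.zeros(d, dtype=bool)

    if cfg.joint:
        cand = rng.uniform(ranges[:, 0], ranges[:, 1], (cfg.n_samples, d))
        fit = problem.evaluate(cand)
        fit = np.minimum(fit, np.finfo(float).max)
        mask, _ = split_acceptable(fit, cfg.cr_multiplier)
        for i in range(d):
            degenerate[i] = ranges[i, 0] == ranges[i, 1]
            sens[i] = sensitivity_of_parameter(cand[:, i], mask)
    else:
        for i in range(d):
            values = sample_parameter(ranges[i], cfg.n_samples, rng)
            degenerate[i] = ranges[i, 0] == ranges[i, 1]
            cand = np.tile(anchor, (cfg.n_samples, 1))
            cand[:, i] = values
            fit = problem.evaluate(cand)
            mask, _ = split_acceptable(fit, cfg.cr_multiplier)
            sens[i] = sensitivity_of_parameter(values, mask)

    ccr = cfg.ccr if cfg.ccr is not None else float(np.quantile(sens, cfg.ccr_quantile))
    return SensitivityReport(sensitivity=sens, ccr_used=ccr,
                             param_names=tuple(problem.param_names()),
                             degenerate=degenerate)


def classify_parameters(report: SensitivityReport, ccr: float | None = None):
    """Indices of sensitive (sensitivity <= CCR) and insensitive parameters."""
    ccr = report.ccr_used if ccr is None else ccr
    mask = report.sensitivity <= ccr
    idx = np.arange(report.n_params)
    return idx[mask], idx[~mask]


def update_ccr(ccr: float, epsilon: float = 0.01, cap: float = 1.0) -> float:
    """Raise the classification threshold so more parameters become sensitive.

    Capped at 1 (the maximum attainable PCC), at which point every parameter
    is classified sensitive.
    """
    return min(ccr + epsilon, cap)
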