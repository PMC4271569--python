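"""Built-in artificial benchmark networks and profile generation.

Two classic S-system benchmarks are provided verbatim from the network
inference literature: a 5-node system (``dataset1``) and a 10-node system
(``dataset2``).  Both relax toward steady state within roughly 0.1 time units
(rate constants of order 10), so profiles are sampled at 0.01 time units for
thirty simulation steps by default -- dense enough that the transient, which
carries essentially all the information about the kinetic orders, is resolved.

``random_toy_network`` generates small sparse self-degrading systems for
parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ExpressionProfile, GeneParameters, SSystemNetwork, simulate_network

__all__ = [
    "BenchmarkSpec",
    "dataset1_network",
    "dataset2_network",
    "benchmark_network",
    "default_x0",
    "generate_profile",
    "random_toy_network",
]

#: Default initial state of the 5-node benchmark (not part of the published
#: system; chosen once so that trajectories are non-trivial and bounded).
X0_DATASET1 = np.full(5, 0.7)

#: Default initial state of the 10-node benchmark: a fixed vector drawn once
#: from U(0.1, 1.0) and frozen here for reproducibility.
X0_DATASET2 = np.array([0.93, 0.74, 0.34, 0.57, 0.81, 0.99, 0.70, 0.79, 0.70, 0.91])


@dataclass(frozen=True)
class BenchmarkSpec:
    """Profile-generation settings: initial state, sample count and spacing."""

    name: str = "dataset1"
    x0: np.ndarray | None = None
    n_steps: int = 30
    dt: float = 0.01
    substeps: int = 1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.x0 is not None:
            x0 = np.asarray(self.x0, dtype=float)
            if np.any(x0 <= 0):
                raise ValueError("x0 components must be positive")
            object.__setattr__(self, "x0", x0)


def dataset1_network() -> SSystemNetwork:
    """The 5-node benchmark system.

    dX1/dt = 15 X3 X5^-0.1 - 10 X1^2
    dX2/dt = 10 X1^2       - 10 X2^2
    dX3/dt = 10 X2^-0.1    - 10 X2^-0.1 X3^2
    dX4/dt =  8 X1^2 X5^-0.1 - 10 X4^2
    dX5/dt = 10 X4^2       - 10 X5^2
    """
    n = 5
    alpha = np.array([15.0, 10.0, 10.0, 8.0, 10.0])
    beta = np.full(n, 10.0)
    g = np.zeros((n, n))
    h = np.zeros((n, n))
    g[0, 2] = 1.0
    g[0, 4] = -0.1
    g[1, 0] = 2.0
    g[2, 1] = -0.1
    g[3, 0] = 2.0
    g[3, 4] = -0.1
    g[4, 3] = 2.0
    h[0, 0] = 2.0
    h[1, 1] = 2.0
    h[2, 1] = -0.1
    h[2, 2] = 2.0
    h[3, 3] = 2.0
    h[4, 4] = 2.0
    return SSystemNetwork.from_matrices(alpha, beta, g, h)


def dataset2_network() -> SSystemNetwork:
    """The 10-node benchmark system (all degradations are 10 Xi^2).

    dX1/dt  =  5 X4 X6^-2        - 10 X1^2
    dX2/dt  = 10 X3 X8           - 10 X2^2
    dX3/dt  =  8 X1^-1 X4^-1     - 10 X3^2
    dX4/dt  = 10 X5^2 X9         - 10 X4^2
    dX5/dt  = 10 X2^2 X6^-1      - 10 X5^2
    dX6/dt  =  5 X9^2 X10^-2     - 10 X6^2
    dX7/dt  = 10 X6 X10^-1       - 10 X7^2
    dX8/dt  =  5 X1 X2^-2 X7     - 10 X8^2
    dX9/dt  = 10 X3 X8^-2        - 10 X9^2
    dX10/dt =  8 X1^2 X7^-1      - 10 X10^2
    """
    n = 10
    alpha = np.array([5.0, 10.0, 8.0, 10.0, 10.0, 5.0, 10.0, 5.0, 10.0, 8.0])
    beta = np.full(n, 10.0)
    g = np.zeros((n, n))
    h = np.zeros((n, n))
    g[0, 3] = 1.0
    g[0, 5] = -2.0
    g[1, 2] = 1.0
    g[1, 7] = 1.0
    g[2, 0] = -1.0
    g[2, 3] = -1.0
    g[3, 4] = 2.0
    g[3, 8] = 1.0
    g[4, 1] = 2.0
    g[4, 5] = -1.0
    g[5, 8] = 2.0
    g[5, 9] = -2.0
    g[6, 5] = 1.0
    g[6, 9] = -1.0
    g[7, 0] = 1.0
    g[7, 1] = -2.0
    g[7, 6] = 1.0
    g[8, 2] = 1.0
    g[8, 7] = -2.0
    g[9, 0] = 2.0
    g[9, 6] = -1.0
    for i in range(n):
        h[i, i] = 2.0
    return SSystemNetwork.from_matrices(alpha, beta, g, h)


_BUILTIN = {"dataset1": dataset1_network, "dataset2": dataset2_network}


def benchmark_network(name: str) -> SSystemNetwork:
    try:
        return _BUILTIN[name]()
    except KeyError:
        raise ValueError(f"unknown benchmark {name!r}; choose from {sorted(_BUILTIN)}")


def default_x0(name: str) -> np.ndarray:
    if name == "dataset1":
        return X0_DATASET1.copy()
    if name == "dataset2":
        return X0_DATASET2.copy()
    raise ValueError(f"no default initial state for {name!r}")


def generate_profile(spec: BenchmarkSpec, net: SSystemNetwork | None = None) -> ExpressionProfile:
    """Simulate a benchmark profile; deterministic given (spec, net).

    Measurement noise (multiplicative Gaussian, seeded) is available through
    ``spec.noise_sd`` but defaults to off: the benchmark studies use noiseless
    artificial data.
    """
    if net is None:
        net = benchmark_network(spec.name)
    x0 = spec.x0 if spec.x0 is not None else default_x0(spec.name)
    if len(x0) != net.n:
        raise ValueError("spec and network dimensions disagree")
    profile = simulate_network(net, x0, n_steps=spec.n_steps, dt=spec.dt,
                               substeps=spec.substeps)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = profile.values * (1.0 + rng.normal(0.0, spec.noise_sd,
                                                   profile.values.shape))
        profile = ExpressionProfile(np.maximum(noisy, 0.0), profile.times,
                                    profile.names)
    return profile


def random_toy_network(n: int, connectivity: int = 1, seed: int = 0) -> SSystemNetwork:
    """Random sparse S-system for recovery tests; deterministic per seed.

    Every gene self-degrades (h_ii > 0).  ``connectivity`` bounds the number
    of off-diagonal synthesis regulators per gene.  Regulation strengths are
    drawn well away from zero (|order| in [0.5, 2]) so that the zero/non-zero
    structure of the generated system is unambiguous at the conventional 0.1
    reporting threshold.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if connectivity > n:
        raise ValueError("connectivity cannot exceed n")
    rng = np.random.default_rng(seed)
    alpha = rng.uniform(4.0, 10.0, n)
    beta = rng.uniform(4.0, 10.0, n)
    g = np.zeros((n, n))
    h = np.zeros((n, n))
    for i in range(n):
        h[i, i] = rng.uniform(1.0, 2.5)
        k = int(rng.integers(0, connectivity + 1)) if connectivity else 0
        if k:
            others = [j for j in range(n) if j != i]
            regulators = rng.choice(others, size=min(k, len(others)), replace=False)
            for j in regulators:
                g[i, j] = rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])
    return SSystemNetwork.from_matrices(alpha, beta, g, h)
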