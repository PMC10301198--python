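"""Bald Eagle Search (BES) and its chaotic-map modification (MBES).

BES is a three-phase population metaheuristic.  Per iteration each eagle

1. *selects* a search area around the best-known position,
   ``P_new = Pbest + alpha * gamma * (Pmean - P_i)``;
2. *searches* the area along a spiral, mixing its offset from the
   population centroid and from its ring neighbour with coefficients
   derived from polar angles ``theta = a*pi*rand``; and
3. *swoops* onto prey with hyperbolic spiral coefficients,
   ``P_new = rand*Pbest + x1*(P_i - c1*Pmean) + y1*(P_i - c2*Pbest)``.

The modified variant (MBES) replaces the uniform initialization with a
tent-map chaotic one, draws the selection factor ``gamma`` from a Fuch
chaotic stream, and damps both swoop terms by an adaptive cosine weight
``omega`` in [0, 0.9] that grows with iteration progress and with an
eagle's fitness rank — small early weights contract aggressively onto
the best position, late weights near 0.9 restore full spiral motion.

Proposals are accepted greedily (an eagle moves only if its fitness
strictly improves), which makes the best-so-far trace monotone by
construction.  Everything is driven by a single seeded generator, so runs
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chaos import ConfigurationError, FuchState, SearchSpace, chaotic_init, fuch_step

__all__ = [
    "BESConfig",
    "EaglePopulation",
    "OptimizationTrace",
    "select_positions",
    "search_positions",
    "swoop_positions",
    "compute_weight",
    "compute_weights",
    "greedy_update",
    "optimize",
]

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class BESConfig:
    """Control parameters of the eagle search.

    Defaults follow the standard experimental settings: ``alpha=1.5``,
    ``a=10``, ``R=1.5``, ``c1=c2=2``, population 100, 100 iterations.

    ``init_mode``, ``gamma_source`` and ``weight_mode`` are diagnostic
    overrides; left ``None`` they follow the variant (``mbes`` uses
    chaotic init, the Fuch gamma stream and the adaptive weight, ``bes``
    uses uniform draws and no weight).  Forcing ``weight_mode="one"`` and
    ``gamma_source="uniform"`` on ``mbes`` reproduces plain BES exactly.
    """

    alpha: float = 1.5
    angle_param: float = 10.0  # a, spiral angle parameter
    cycle_param: float = 1.5  # R, search-cycle parameter
    c1: float = 2.0
    c2: float = 2.0
    n_agents: int = 100
    max_iter: int = 100
    variant: str = "mbes"
    init_mode: str | None = None  # {"chaotic", "uniform"}
    gamma_source: str | None = None  # {"fuch", "uniform"}
    weight_mode: str | None = None  # {"adaptive", "one"}
    chaos_particles: int | None = None  # N of the tent perturbation; default n_agents

    def __post_init__(self) -> None:
        if self.variant not in ("bes", "mbes"):
            raise ConfigurationError(f"variant must be 'bes' or 'mbes', got {self.variant!r}")
        if not 1.5 <= self.alpha <= 2.0:
            raise ConfigurationError(f"alpha must lie in [1.5, 2], got {self.alpha}")
        if not 5.0 <= self.angle_param <= 10.0:
            raise ConfigurationError(f"angle_param must lie in [5, 10], got {self.angle_param}")
        if not 0.5 <= self.cycle_param <= 2.0:
            raise ConfigurationError(f"cycle_param must lie in [0.5, 2], got {self.cycle_param}")
        if not 1.0 <= self.c1 <= 2.0 or not 1.0 <= self.c2 <= 2.0:
            raise ConfigurationError("c1 and c2 must lie in [1, 2]")
        if self.n_agents < 2:
            raise ConfigurationError("n_agents must be >= 2")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")

    def resolved_init(self) -> str:
        return self.init_mode or ("chaotic" if self.variant == "mbes" else "uniform")

    def resolved_gamma(self) -> str:
        return self.gamma_source or ("fuch" if self.variant == "mbes" else "uniform")

    def resolved_weight(self) -> str:
        return self.weight_mode or ("adaptive" if self.variant == "mbes" else "one")


@dataclass
class EaglePopulation:
    """Population state in the optimizer's internal coordinates."""

    space: SearchSpace
    positions: np.ndarray  # (n_agents, dim), internal coordinates
    fitnesses: np.ndarray | None = None
    p_best: np.ndarray | None = None  # best position ever seen (internal)
    g_best: float = np.inf
    iteration: int = 0
    evaluations: int = 0

    @property
    def p_mean(self) -> np.ndarray:
        """Arithmetic centroid of the current positions."""
        return self.positions.mean(axis=0)

    @property
    def evaluated(self) -> bool:
        return self.fitnesses is not None

    def evaluate_initial(self, objective: Objective) -> None:
        fits = _evaluate(objective, self.space, self.positions)
        self.fitnesses = fits
        self.evaluations += len(fits)
        best = int(np.argmin(fits))
        if fits[best] < self.g_best:
            self.g_best = float(fits[best])
            self.p_best = self.positions[best].copy()


@dataclass
class OptimizationTrace:
    """Best-so-far fitness per iteration plus run bookkeeping."""

    best_per_iter: np.ndarray
    evaluations: int
    best_position: np.ndarray  # native units
    seed: int


def _require_evaluated(pop: EaglePopulation) -> None:
    if not pop.evaluated:
        raise RuntimeError("population must be evaluated before proposing positions")


def _evaluate(objective: Objective, space: SearchSpace, U: np.ndarray) -> np.ndarray:
    """Objective values at internal positions; non-finite results become +inf."""
    fits = np.empty(U.shape[0])
    for i, u in enumerate(U):
        val = objective(space.to_native(u))
        fits[i] = val if np.isfinite(val) else np.inf
    return fits


def select_positions(
    pop: EaglePopulation,
    cfg: BESConfig,
    rng: np.random.Generator,
    fuch: FuchState | None = None,
) -> np.ndarray:
    """Selection phase: move each eagle toward the best area.

    ``P_new[i] = Pbest + alpha * gamma_i * (Pmean - P_i)`` where the
    selection factor ``gamma_i`` is drawn per eagle from ``rng`` for plain
    BES and from the Fuch chaotic stream for MBES.  Proposals are clipped
    to the bounds.  The Fuch state is advanced in place.
    """
    _require_evaluated(pop)
    n = pop.positions.shape[0]
    if cfg.resolved_gamma() == "fuch":
        if fuch is None:
            raise ValueError("MBES selection requires a Fuch state")
        gam = np.empty(n)
        state = fuch
        for i in range(n):
            state = fuch_step(state, rng)
            gam[i] = state.f
        fuch.f, fuch.needs_reseed = state.f, state.needs_reseed
    else:
        gam = rng.uniform(size=n)
    prop = pop.p_best[None, :] + cfg.alpha * gam[:, None] * (pop.p_mean[None, :] - pop.positions)
    return pop.space.clip_internal(prop)


def search_positions(
    pop: EaglePopulation, cfg: BESConfig, rng: np.random.Generator
) -> np.ndarray:
    """Search phase: spiral flight around the centroid and ring neighbour.

    Polar draws ``theta_i = a*pi*rand``, ``r_i = theta_i + R*rand``; the
    Cartesian components ``r sin(theta)``, ``r cos(theta)`` are normalized
    by their population maxima (a degenerate all-zero component yields
    zero coefficients), and the last eagle's neighbour wraps to the first.
    """
    _require_evaluated(pop)
    P = pop.positions
    n = P.shape[0]
    theta = cfg.angle_param * np.pi * rng.uniform(size=n)
    r = theta + cfg.cycle_param * rng.uniform(size=n)
    xr = r * np.sin(theta)
    yr = r * np.cos(theta)
    x = _normalize_by_max_abs(xr)
    y = _normalize_by_max_abs(yr)
    P_next = np.roll(P, -1, axis=0)  # ring neighbour P_{i+1}
    prop = P + x[:, None] * (P - pop.p_mean[None, :]) + y[:, None] * (P - P_next)
    return pop.space.clip_internal(prop)


def swoop_positions(
    pop: EaglePopulation,
    cfg: BESConfig,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Swoop phase: hyperbolic spiral dive onto the best position.

    ``theta_i = a*pi*rand``, ``r_i = theta_i``; coefficients
    ``x1 = r sinh(theta)``, ``y1 = r cosh(theta)`` normalized by their
    population maxima.  Plain BES proposes
    ``rand*Pbest + x1*(P_i - c1*Pmean) + y1*(P_i - c2*Pbest)``; MBES
    multiplies both spiral terms by the per-eagle adaptive weight.
    """
    _require_evaluated(pop)
    if (weights is not None) != (cfg.resolved_weight() == "adaptive"):
        raise ValueError("weights must be supplied iff the adaptive swoop weight is active")
    P = pop.positions
    n = P.shape[0]
    theta = cfg.angle_param * np.pi * rng.uniform(size=n)
    r = theta
    x1 = _normalize_by_max_abs(r * np.sinh(theta))
    y1 = _normalize_by_max_abs(r * np.cosh(theta))
    if weights is not None:
        x1 = weights * x1
        y1 = weights * y1
    rnd = rng.uniform(size=n)
    prop = (
        rnd[:, None] * pop.p_best[None, :]
        + x1[:, None] * (P - cfg.c1 * pop.p_mean[None, :])
        + y1[:, None] * (P - cfg.c2 * pop.p_best[None, :])
    )
    return pop.space.clip_internal(prop)


def _normalize_by_max_abs(v: np.ndarray) -> np.ndarray:
    m = np.max(np.abs(v))
    if m == 0.0 or not np.isfinite(m):
        return np.zeros_like(v)
    return v / m


def compute_weight(fit_i: float, avgfit: float, g_best: float, t: int, T: int) -> float:
    """Adaptive swoop weight ``omega`` in [0, 0.9].

    ``omega = 0.9 * cos((pi/2) * (1 - t/T) * ratio)`` with
    ``ratio = (fit_i - g_best) / (avgfit - g_best)`` for eagles fitter
    than the population average, and ``ratio = 1`` otherwise.  The ratio
    is clipped to [0, 1] (and defined as 0 when ``avgfit == g_best``) so
    the cosine argument stays in [0, pi/2]: the weight is 0.9 at the final
    iteration and for the incumbent best eagle, and decays toward 0 for
    poor eagles early in the run.
    """
    if T < 1:
        raise ValueError(f"iteration budget T must be >= 1, got {T}")
    if not 0 <= t <= T:
        raise ValueError(f"iteration t must lie in [0, T], got t={t}, T={T}")
    denom = avgfit - g_best
    if denom <= 0.0:
        ratio = 0.0
    elif fit_i < avgfit:
        ratio = min(max((fit_i - g_best) / denom, 0.0), 1.0)
    else:
        ratio = 1.0
    return 0.9 * float(np.cos(0.5 * np.pi * (1.0 - t / T) * ratio))


def compute_weights(fitnesses: np.ndarray, g_best: float, t: int, T: int) -> np.ndarray:
    """Vector of adaptive weights for a population (finite fitnesses only count toward the mean)."""
    finite = fitnesses[np.isfinite(fitnesses)]
    avg = float(np.mean(finite)) if finite.size else g_best
    return np.array([compute_weight(float(f), avg, g_best, t, T) for f in fitnesses])


def greedy_update(
    pop: EaglePopulation, proposals: np.ndarray, objective: Objective
) -> EaglePopulation:
    """Evaluate proposals and accept each one only on strict improvement.

    Ties and regressions keep the incumbent position; the global best is
    updated from accepted improvements.  Non-finite objective values are
    treated as ``+inf`` and never accepted.
    """
    _require_evaluated(pop)
    fits = _evaluate(objective, pop.space, proposals)
    pop.evaluations += len(fits)
    better = fits < pop.fitnesses
    pop.positions[better] = proposals[better]
    pop.fitnesses[better] = fits[better]
    if np.any(better):
        best = int(np.argmin(pop.fitnesses))
        if pop.fitnesses[best] < pop.g_best:
            pop.g_best = float(pop.fitnesses[best])
            pop.p_best = pop.positions[best].copy()
    return pop


def optimize(
    objective: Objective,
    space: SearchSpace,
    cfg: BESConfig,
    seed: int,
) -> tuple[np.ndarray, float, OptimizationTrace]:
    """Run the eagle search and return ``(best_position, best_fitness, trace)``.

    One iteration is select -> greedy accept -> search -> greedy accept ->
    swoop -> greedy accept, i.e. ``3 * n_agents`` objective calls, after an
    initial population evaluation.  ``best_position`` is in native units.
    Identical seeds give bit-identical results.
    """
    rng = np.random.default_rng(seed)
    n, T = cfg.n_agents, cfg.max_iter
    if cfg.resolved_init() == "chaotic":
        z0 = float(rng.uniform())
        native = chaotic_init(space, n, z0, rng, n_particles=cfg.chaos_particles or n)
        U = space.from_native(native)
    else:
        lo, up = space.internal_lower, space.internal_upper
        U = lo + rng.uniform(size=(n, space.dim)) * (up - lo)
    fuch = FuchState(f=float(rng.uniform())) if cfg.resolved_gamma() == "fuch" else None
    adaptive = cfg.resolved_weight() == "adaptive"

    pop = EaglePopulation(space=space, positions=U)
    pop.evaluate_initial(objective)

    best_per_iter = np.empty(T)
    for t in range(1, T + 1):
        pop.iteration = t
        greedy_update(pop, select_positions(pop, cfg, rng, fuch), objective)
        greedy_update(pop, search_positions(pop, cfg, rng), objective)
        weights = compute_weights(pop.fitnesses, pop.g_best, t, T) if adaptive else None
        greedy_update(pop, swoop_positions(pop, cfg, rng, weights), objective)
        best_per_iter[t - 1] = pop.g_best

    trace = OptimizationTrace(
        best_per_iter=best_per_iter,
        evaluations=pop.evaluations,
        best_position=space.to_native(pop.p_best),
        seed=seed,
    )
    return space.to_native(pop.p_best), pop.g_best, trace
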