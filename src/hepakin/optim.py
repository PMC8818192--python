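"""Parameter-estimation engines for the dual-input liver model.

Three interchangeable fitters minimise the sum of squared per-frame
residuals over the five-vector (k1, k2, k3, k4, HPI):

* :func:`nlls_fit` — bounded trust-region nonlinear least squares with
  multi-start (local, gradient-based; sensitive to its starting point).
* GSA — the gravitational search algorithm: candidate solutions are
  particles whose fitness-derived masses attract each other with
  Newtonian-style forces under a decaying gravitational constant.
* DCGSA — GSA with a dynamic, randomised gravitational-constant schedule,
  a linearly decaying inertia weight on the velocity, and a per-particle
  chaotic (logistic-map) factor on the position step, which together
  slow premature convergence and improve the global search.

Both population methods run through :func:`minimize`; the single-step
primitives (:func:`update_masses`, :func:`pairwise_force`, ...) are exposed
so each update rule can be tested in isolation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import (
    FrameSchedule,
    InputFunction,
    KineticParams,
    TissueCurve,
    _tissue_response,
)

__all__ = [
    "SearchSpace",
    "GsaConfig",
    "Swarm",
    "FitResult",
    "TacObjective",
    "fitness",
    "update_masses",
    "gravitational_constant",
    "dynamic_gravitational_constant",
    "pairwise_force",
    "resultant_force",
    "kbest_size",
    "gsa_step",
    "dcgsa_step",
    "ChaoticSequence",
    "logistic_step",
    "minimize",
    "nlls_fit",
    "fit_tac",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchSpace:
    """Per-dimension box bounds for candidate parameter vectors."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower and upper bounds must be matching 1-D arrays")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must be strictly below its upper bound")

    @property
    def ndim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    @classmethod
    def default(cls) -> "SearchSpace":
        """Default kinetic bounds: k1, k2 in [0,3]; k3 in [0,1]; k4 in [0,0.5]; HPI in [0,1]."""
        return cls(np.zeros(5), np.array([3.0, 3.0, 1.0, 0.5, 1.0]))


@dataclass(frozen=True)
class GsaConfig:
    """Configuration shared by GSA and DCGSA.

    ``g0`` and ``alpha`` set the gravitational-constant schedule
    ``G(t) = g0 exp(-alpha t / T)``; DCGSA replaces it with the randomised
    ``G'(t) = g0 exp(-alpha_dyn (t / T^1.5) (rand_t + t/T))``.  Because the
    dynamic exponent is bounded by ``alpha_dyn (1 + t/T) / sqrt(T)``, the
    decay constant of the two schedules lives on different scales; when
    ``alpha_dynamic`` is left unset it defaults to ``(2/3) alpha sqrt(T)``,
    which matches the *expected* total decay of the dynamic schedule at
    t = T to the classic one (E[rand_t + 1] = 3/2), so both variants
    explore early and take small steps late.  ``omega_max`` and
    ``omega_min`` bound DCGSA's linearly decaying inertia weight.  Kbest
    shrinks linearly from N at t=0 to ``kbest_final`` at t=T.
    """

    n_particles: int = 50
    n_iters: int = 500
    g0: float = 100.0
    alpha: float = 20.0
    alpha_dynamic: float | None = None
    epsilon: float = 1e-9
    variant: str = "gsa"  # "gsa" | "dcgsa"
    omega_max: float = 0.7
    omega_min: float = 0.1
    kbest_final: int = 1
    rand_per_dimension: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("a swarm needs at least 2 particles")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if self.g0 <= 0:
            raise ValueError("g0 must be positive")
        if not (self.omega_max > self.omega_min > 0):
            raise ValueError("need omega_max > omega_min > 0")
        if self.variant not in ("gsa", "dcgsa"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 1 <= self.kbest_final <= self.n_particles:
            raise ValueError("kbest_final must lie in [1, n_particles]")

    @property
    def effective_alpha_dynamic(self) -> float:
        """Decay constant used in the dynamic schedule (scale-matched default)."""
        if self.alpha_dynamic is not None:
            return self.alpha_dynamic
        return (2.0 / 3.0) * self.alpha * math.sqrt(self.n_iters)


@dataclass
class Swarm:
    """Mutable optimizer state: one row per candidate solution."""

    positions: np.ndarray  # (N, D)
    velocities: np.ndarray  # (N, D)
    fitness: np.ndarray  # (N,)
    masses: np.ndarray  # (N,) normalized to sum 1 after each mass update
    t: int
    n_iters: int
    space: SearchSpace
    chaotic_state: np.ndarray | None = None  # per-particle logistic states (DCGSA)


@dataclass
class FitResult:
    """Outcome of one fit: best candidate, trace and residual diagnostics."""

    x: np.ndarray
    fun: float
    trace: np.ndarray  # best-so-far fitness, one entry per iteration
    method: str
    residuals: np.ndarray | None = None
    n_obs: int | None = None
    n_params: int | None = None
    n_evals: int = 0

    def as_kinetic_params(self) -> KineticParams:
        return KineticParams.from_vector(np.clip(self.x, [0, 0, 0, 0, 0], [np.inf] * 4 + [1]))


# ---------------------------------------------------------------------------
# objective


class TacObjective:
    """Sum-of-squared-frame-residuals objective for one measured tissue curve.

    Precomputes the gridded arterial and portal curves and the frame
    integration weights so a single candidate evaluation costs two O(n)
    exponential convolutions.
    """

    def __init__(
        self,
        observed: TissueCurve,
        arterial: InputFunction,
        portal: InputFunction,
        grid: np.ndarray | None = None,
    ):
        if arterial.span != portal.span or len(arterial) != len(portal):
            raise ValueError(
                "arterial and portal curves must share a time span: "
                f"arterial {arterial.span}, portal {portal.span}"
            )
        if grid is None:
            grid = arterial.times
        self.grid = np.asarray(grid, dtype=float)
        self.dt = float(self.grid[1] - self.grid[0])
        sched = observed.schedule
        if sched.end_times[-1] > self.grid[-1] + 1e-9:
            raise ValueError(
                f"frame schedule (to {sched.end_times[-1]} s) extends past the "
                f"model grid (to {self.grid[-1]} s)"
            )
        self.observed = observed
        self.schedule = sched
        self._a = arterial(self.grid)
        self._p = portal(self.grid)
        # frame averages via the cumulative trapezoid integral
        self._lo = sched.starts
        self._hi = sched.end_times
        self.n_evals = 0

    def _frame_average(self, y: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0.0], np.cumsum((y[1:] + y[:-1]) / 2.0 * self.dt)])
        lo = np.interp(self._lo, self.grid, cum)
        hi = np.interp(self._hi, self.grid, cum)
        return (hi - lo) / self.schedule.durations

    def model_frames(self, x: Sequence[float]) -> np.ndarray:
        params = KineticParams.from_vector(x)
        cb = params.hpi * self._a + (1.0 - params.hpi) * self._p
        y = _tissue_response(params, cb, self.grid, self.dt)
        self.n_evals += 1
        return self._frame_average(y)

    def residuals(self, x: Sequence[float]) -> np.ndarray:
        return self.observed.values - self.model_frames(x)

    def __call__(self, x: Sequence[float]) -> float:
        r = self.residuals(x)
        return float(r @ r)


def fitness(
    candidate: KineticParams,
    observed: TissueCurve,
    arterial: InputFunction,
    portal: InputFunction,
) -> float:
    """Sum over frames of (observed - model frame value)^2."""
    return TacObjective(observed, arterial, portal)(candidate.to_vector())


# ---------------------------------------------------------------------------
# GSA primitives


def update_masses(fit_values: np.ndarray) -> np.ndarray:
    """Fitness-derived inertial masses, normalized to sum 1 (minimization).

    The best (lowest-fitness) particle gets raw mass 1, the worst 0; when
    all fitness values coincide the map is 0/0 and masses fall back to the
    uniform 1/N.
    """
    f = np.asarray(fit_values, dtype=float)
    best = np.min(f)
    worst = np.max(f)
    if worst == best:
        return np.full(f.size, 1.0 / f.size)
    if not np.isfinite(worst):
        # failed (infinite-fitness) evaluations get zero raw mass; the rest
        # are ranked against the worst finite value
        finite = np.isfinite(f)
        worst = f[finite].max()
        if worst == best:
            return finite / finite.sum()
        m = np.where(finite, (np.where(finite, f, worst) - worst) / (best - worst), 0.0)
    else:
        m = (f - worst) / (best - worst)
    return m / m.sum() if m.sum() > 0 else np.full(f.size, 1.0 / f.size)


def gravitational_constant(t: int, cfg: GsaConfig) -> float:
    """Classic exponentially decaying schedule ``G(t) = G0 e^{-alpha t/T}``."""
    return cfg.g0 * math.exp(-cfg.alpha * t / cfg.n_iters)


def dynamic_gravitational_constant(t: int, cfg: GsaConfig, rng: np.random.Generator) -> float:
    """Randomised schedule ``G'(t) = G0 e^{-alpha_dyn (t/T^1.5)(rand_t + t/T)}``.

    ``rand_t`` is drawn uniform(0, 1) once per iteration; the random factor
    perturbs the decay so particles can jump out of local optima early
    while still shrinking the step late in the run.  ``alpha_dyn`` is
    ``cfg.effective_alpha_dynamic`` (see :class:`GsaConfig`).
    """
    rand_t = float(rng.uniform())
    T = cfg.n_iters
    return cfg.g0 * math.exp(
        -cfg.effective_alpha_dynamic * (t / T**1.5) * (rand_t + t / T)
    )


def pairwise_force(
    i: int,
    j: int,
    positions: np.ndarray,
    masses: np.ndarray,
    g: float,
    epsilon: float,
) -> np.ndarray:
    """Gravitational pull of particle j on particle i (attractive).

    ``F_ij^d = G M_i M_j / (R_ij + eps) (x_j^d - x_i^d)`` with R_ij the
    Euclidean distance; epsilon guards the coincident-position case.
    """
    if i == j:
        raise ValueError("pairwise force requires i != j")
    diff = positions[j] - positions[i]
    r = float(np.linalg.norm(diff))
    return g * masses[i] * masses[j] / (r + epsilon) * diff


def kbest_size(t: int, cfg: GsaConfig) -> int:
    """Linearly shrinking elite count: N at t=0 down to kbest_final at t=T."""
    n, k_end = cfg.n_particles, cfg.kbest_final
    return int(math.ceil(n - (n - k_end) * t / cfg.n_iters))


def resultant_force(
    i: int,
    swarm: Swarm,
    g: float,
    kbest: int,
    rng: np.random.Generator,
    epsilon: float = 1e-9,
    rand_per_dimension: bool = False,
) -> np.ndarray:
    """Randomly weighted sum of pulls from the ``kbest`` fittest particles.

    One uniform(0,1) weight is drawn per attracting particle (optionally per
    dimension), iterating elite members in ascending particle index.
    """
    n = swarm.positions.shape[0]
    if not 1 <= kbest <= n:
        raise ValueError(f"kbest must lie in [1, {n}], got {kbest}")
    elite = np.sort(np.argsort(swarm.fitness, kind="stable")[:kbest])
    total = np.zeros(swarm.positions.shape[1])
    for j in elite:
        if j == i:
            continue
        w = rng.uniform(size=swarm.positions.shape[1]) if rand_per_dimension else rng.uniform()
        total += w * pairwise_force(i, j, swarm.positions, swarm.masses, g, epsilon)
    return total


def _accelerations(swarm: Swarm, g: float, kbest: int, rng: np.random.Generator,
                   cfg: GsaConfig) -> np.ndarray:
    """Forces and accelerations for the whole swarm (vectorised).

    Equivalent to calling :func:`resultant_force` per particle with an
    independent weight per (i, j) pair, then dividing by M_i.  The factor
    M_i in the force cancels analytically against the division, so it is
    dropped here; this is also the epsilon-substitution limit for the
    zero-mass (worst) particle, which must still move.
    """
    x, m = swarm.positions, swarm.masses
    n, d = x.shape
    elite = np.sort(np.argsort(swarm.fitness, kind="stable")[:kbest])
    diff = x[None, elite, :] - x[:, None, :]  # (n, k, d): x_j - x_i
    r = np.linalg.norm(diff, axis=2)  # (n, k)
    if cfg.rand_per_dimension:
        w = rng.uniform(size=(n, elite.size, d))
    else:
        w = rng.uniform(size=(n, elite.size))[:, :, None]
    coef = (g * m[elite][None, :] / (r + cfg.epsilon))[:, :, None] * w
    # zero out the self term for elite particles
    self_mask = elite[None, :] == np.arange(n)[:, None]
    coef = np.where(self_mask[:, :, None], 0.0, coef)
    return (coef * diff).sum(axis=1)  # (n, d)


def _apply_bounds(swarm: Swarm) -> None:
    """Clip positions to bounds, zeroing each velocity component that violated."""
    lo, hi = swarm.space.lower, swarm.space.upper
    out = (swarm.positions < lo) | (swarm.positions > hi)
    swarm.velocities[out] = 0.0
    np.clip(swarm.positions, lo, hi, out=swarm.positions)


def gsa_step(swarm: Swarm, cfg: GsaConfig, rng: np.random.Generator) -> Swarm:
    """One classic-GSA update: masses, forces, then v <- rand_i v + a, x <- x + v."""
    swarm.masses = update_masses(swarm.fitness)
    g = gravitational_constant(swarm.t, cfg)
    acc = _accelerations(swarm, g, kbest_size(swarm.t, cfg), rng, cfg)
    rand_i = rng.uniform(size=swarm.positions.shape[0])[:, None]
    swarm.velocities = rand_i * swarm.velocities + acc
    swarm.positions = swarm.positions + swarm.velocities
    _apply_bounds(swarm)
    swarm.t += 1
    return swarm


def inertia_weight(t: int, cfg: GsaConfig) -> float:
    """Linearly decaying inertia weight ``W(t) = w_max - (w_max - w_min) t / T``."""
    return cfg.omega_max - (cfg.omega_max - cfg.omega_min) * t / cfg.n_iters


def dcgsa_step(
    swarm: Swarm,
    cfg: GsaConfig,
    rng: np.random.Generator,
    chaotic_state: np.ndarray | None = None,
) -> Swarm:
    """One DCGSA update: dynamic G, inertia-weighted velocity, chaotic step.

    ``v <- W(t) v + a`` and ``x <- x + v c(i)`` where c(i) is the next
    logistic-map value of particle i's chaotic stream, advanced once per
    particle per iteration.
    """
    if chaotic_state is None:
        chaotic_state = swarm.chaotic_state
    if chaotic_state is None:
        raise ValueError("dcgsa_step requires per-particle chaotic state")
    swarm.masses = update_masses(swarm.fitness)
    g = dynamic_gravitational_constant(swarm.t, cfg, rng)
    acc = _accelerations(swarm, g, kbest_size(swarm.t, cfg), rng, cfg)
    w = inertia_weight(swarm.t, cfg)
    swarm.velocities = w * swarm.velocities + acc
    chaotic_state[:] = logistic_step(chaotic_state)
    swarm.positions = swarm.positions + swarm.velocities * chaotic_state[:, None]
    swarm.chaotic_state = chaotic_state
    _apply_bounds(swarm)
    swarm.t += 1
    return swarm


# ---------------------------------------------------------------------------
# chaotic sequence


def logistic_step(x):
    """One iterate of the fully chaotic logistic map ``x <- 4 x (1 - x)``."""
    return 4.0 * x * (1.0 - x)


# logistic fixed/periodic seeds whose orbits collapse
_DEGENERATE_SEEDS = (0.0, 0.25, 0.5, 0.75, 1.0)


class ChaoticSequence:
    """Deterministic aperiodic values in (0, 1) from the logistic map.

    Seeds at the map's fixed or periodic points (0, 0.25, 0.5, 0.75, 1)
    are rejected: their orbits collapse (e.g. 0.5 -> 1 -> 0 -> 0 ...).
    """

    def __init__(self, seed: float):
        if not 0.0 < seed < 1.0 or any(
            abs(seed - s) < 1e-12 for s in _DEGENERATE_SEEDS
        ):
            raise ValueError(
                f"chaotic seed must lie in (0,1) away from {{0.25, 0.5, 0.75}}, got {seed}"
            )
        self.state = float(seed)

    def next(self) -> float:
        self.state = logistic_step(self.state)
        return self.state

    def __iter__(self):
        return self

    def __next__(self) -> float:
        return self.next()


def _draw_chaotic_seeds(n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-particle logistic seeds, resampled away from degenerate orbits."""
    seeds = rng.uniform(0.01, 0.99, size=n)
    for s in _DEGENERATE_SEEDS:
        bad = np.abs(seeds - s) < 1e-6
        while bad.any():
            seeds[bad] = rng.uniform(0.01, 0.99, size=int(bad.sum()))
            bad = np.abs(seeds - s) < 1e-6
    return seeds


# ---------------------------------------------------------------------------
# drivers


def _safe_eval(objective: Callable, x: np.ndarray) -> float:
    v = objective(x)
    if not np.isfinite(v):
        logger.warning("non-finite objective value at %s; assigning +inf", x)
        return np.inf
    return float(v)


def minimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    cfg: GsaConfig,
) -> FitResult:
    """Run GSA or DCGSA (per ``cfg.variant``) and return the best-so-far result.

    The trace records the best fitness seen after initialization and after
    each of the T iterations (length T + 1, non-increasing); the run is
    fully reproducible under a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_particles, space.ndim
    positions = rng.uniform(space.lower, space.upper, size=(n, d))
    swarm = Swarm(
        positions=positions,
        velocities=np.zeros((n, d)),
        fitness=np.array([_safe_eval(objective, x) for x in positions]),
        masses=np.full(n, 1.0 / n),
        t=0,
        n_iters=cfg.n_iters,
        space=space,
        chaotic_state=_draw_chaotic_seeds(n, rng) if cfg.variant == "dcgsa" else None,
    )
    ibest = int(np.argmin(swarm.fitness))
    best_x = swarm.positions[ibest].copy()
    best_f = float(swarm.fitness[ibest])
    trace = [best_f]
    step = dcgsa_step if cfg.variant == "dcgsa" else gsa_step
    for _ in range(cfg.n_iters):
        step(swarm, cfg, rng)
        swarm.fitness = np.array([_safe_eval(objective, x) for x in swarm.positions])
        ibest = int(np.argmin(swarm.fitness))
        if swarm.fitness[ibest] < best_f:
            best_f = float(swarm.fitness[ibest])
            best_x = swarm.positions[ibest].copy()
        trace.append(best_f)
    return FitResult(
        x=best_x,
        fun=best_f,
        trace=np.array(trace),
        method=cfg.variant,
        n_evals=n * (cfg.n_iters + 1),
    )


def nlls_fit(
    observed: TissueCurve,
    arterial: InputFunction,
    portal: InputFunction,
    space: SearchSpace | None = None,
    starts: np.ndarray | None = None,
    n_starts: int = 10,
    seed: int | None = None,
) -> FitResult:
    """Bounded trust-region least squares with uniform-random multi-start.

    A single deliberately chosen start reproduces the classic local-minimum
    sensitivity of NLLS; the default 10 uniform draws make recovery robust
    on clean data.  Returns the best of all starts under the same result
    contract as :func:`minimize`.
    """
    space = space or SearchSpace.default()
    obj = TacObjective(observed, arterial, portal)
    if starts is None:
        rng = np.random.default_rng(seed)
        starts = rng.uniform(space.lower, space.upper, size=(n_starts, space.ndim))
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    best = None
    trace: list[float] = []
    failures: list[str] = []
    for x0 in starts:
        try:
            sol = least_squares(
                obj.residuals, x0, bounds=(space.lower, space.upper), method="trf"
            )
        except Exception as exc:  # pragma: no cover - solver hard failure
            failures.append(f"start {x0}: {exc}")
            continue
        cost = float(2.0 * sol.cost)  # least_squares cost = 0.5 * SSE
        if best is None or cost < best[0]:
            best = (cost, sol.x.copy(), sol.fun.copy())
        trace.append(best[0])
    if best is None:
        raise RuntimeError("all NLLS starts failed to converge: " + "; ".join(failures))
    cost, x, res = best
    return FitResult(
        x=x,
        fun=cost,
        trace=np.array(trace),
        method="nlls",
        residuals=res,  # observed - model, as produced by TacObjective
        n_obs=len(observed.values),
        n_params=space.ndim,
        n_evals=obj.n_evals,
    )


def fit_tac(
    observed: TissueCurve,
    arterial: InputFunction,
    portal: InputFunction,
    method: str,
    space: SearchSpace | None = None,
    cfg: GsaConfig | None = None,
    seed: int | None = None,
    n_starts: int = 10,
) -> FitResult:
    """Fit one tissue curve with ``method`` in {"nlls", "gsa", "dcgsa"}."""
    space = space or SearchSpace.default()
    if method == "nlls":
        result = nlls_fit(observed, arterial, portal, space, n_starts=n_starts, seed=seed)
    elif method in ("gsa", "dcgsa"):
        cfg = cfg or GsaConfig()
        cfg = replace(cfg, variant=method, seed=seed if seed is not None else cfg.seed)
        obj = TacObjective(observed, arterial, portal)
        result = minimize(obj, space, cfg)
        result.residuals = obj.residuals(result.x)
    else:
        raise ValueError(f"unknown method {method!r}; expected nlls, gsa or dcgsa")
    result.n_obs = len(observed.values)
    result.n_params = space.ndim
    return result
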