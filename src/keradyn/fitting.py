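"""Least-squares estimation of turnover parameters per scenario.

The objective is the sum of squared differences between a scenario's
insoluble profile at 48 h and the measured 48-h profile at the ``N_x``
grid points,

    Psi(p) = sum_i [ I(x_i, 48 h, p) - f_final(x_i) ]^2   (uM^2),

minimized over the scenario's free turnover parameters (2 for linear
kinetics, 4 for Michaelis-Menten).  The global search is a real-coded
genetic algorithm — tournament selection, simulated-binary crossover,
bounded polynomial-style mutation, elitism — working in log-space for the
rate and half-saturation parameters, optionally followed by a
derivative-free simplex polish of the best individual.  During the search
the forward solves may run at a coarse solver tolerance; the returned
residual is always re-evaluated at the tight default tolerance.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import minimize

from .profiles import FixedParameters, SpatialGrid, eval_ffinal
from .scenarios import ScenarioSpec, TurnoverParameters, n_estimated_parameters
from .solver import ATOL_DEFAULT, RTOL_DEFAULT, IntegrationError, integrate

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterBound",
    "SearchSpace",
    "GAConfig",
    "FitResult",
    "objective",
    "fit_scenario",
    "fit_all",
    "minimize_ga",
]


# ----------------------------------------------------------------------
# Search space
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterBound:
    """Bounds for one free parameter; ``log=True`` searches in log10
    space (appropriate for rates and half-saturations spanning decades)."""

    name: str
    lower: float
    upper: float
    log: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError(
                f"bounds for {self.name} must satisfy 0 < lower < upper")

    def to_internal(self, value: float) -> float:
        return math.log10(value) if self.log else value

    def from_internal(self, z: float) -> float:
        return 10.0 ** z if self.log else z

    @property
    def internal_interval(self) -> tuple[float, float]:
        return (self.to_internal(self.lower), self.to_internal(self.upper))


@dataclass(frozen=True)
class SearchSpace:
    """Ordered bounds for every free parameter of a scenario."""

    bounds: tuple[ParameterBound, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bounds)

    @property
    def dim(self) -> int:
        return len(self.bounds)

    def decode(self, z: ArrayLike) -> dict[str, float]:
        z = np.asarray(z, dtype=float)
        return {b.name: b.from_internal(float(v))
                for b, v in zip(self.bounds, z)}

    def validate_for(self, spec: ScenarioSpec) -> None:
        if self.names != spec.free_parameter_names:
            raise ValueError(
                f"search space covers {self.names}, scenario {spec.index} "
                f"needs {spec.free_parameter_names}")

    @classmethod
    def default_for(cls, spec: ScenarioSpec) -> "SearchSpace":
        """Default bounds: rate levels in [1e-6, 1e2] (scenario units),
        half-saturations in [1e-1, 1e4] uM, all log-scaled."""
        rate = dict(lower=1e-6, upper=1e2, log=True)
        sat = dict(lower=1e-1, upper=1e4, log=True)
        if spec.turnover == "linear":
            bounds = (ParameterBound("k_ass", **rate),
                      ParameterBound("k_dis", **rate))
        else:
            bounds = (ParameterBound("k_ass", **rate),
                      ParameterBound("k_S", **sat),
                      ParameterBound("k_dis", **rate),
                      ParameterBound("k_I", **sat))
        return cls(bounds=bounds)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters (config-overridable).

    Defaults target robust global search on 2-4 dimensional problems:
    population 60 over 120 generations, tournament selection of size 3,
    simulated-binary crossover with probability 0.9, per-gene mutation
    probability 0.15, two elites carried over unchanged, log-uniform
    initialization over the bounds.
    """

    population: int = 60
    generations: int = 120
    tournament: int = 3
    crossover_prob: float = 0.9
    crossover_eta: float = 12.0
    mutation_prob: float = 0.15
    mutation_scale: float = 0.12  # st.dev. as fraction of the bound range
    elitism: int = 2
    polish: bool = True
    polish_maxfev: int = 120
    search_rtol: float = 1e-4    # coarse solve during the search
    search_atol: float = 1e-4
    final_rtol: float = RTOL_DEFAULT  # tight re-evaluation of the optimum
    final_atol: float = ATOL_DEFAULT

    def __post_init__(self) -> None:
        if self.population < max(2, self.elitism + 1):
            raise ValueError("population too small for the elite count")
        if self.generations < 1 or self.tournament < 1:
            raise ValueError("generations and tournament size must be >= 1")

    def digest(self) -> str:
        import hashlib

        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class FitResult:
    """Best parameters found for one scenario and their residual."""

    scenario_index: int
    best_params: TurnoverParameters
    psi: float
    K: int
    evaluations: int
    seed: int
    ga_digest: str = ""

    def __post_init__(self) -> None:
        if self.psi < 0:
            raise ValueError("residual psi must be nonnegative")
        if self.K not in (3, 5):
            raise ValueError("K must be 3 (linear) or 5 (nonlinear)")

    def to_json(self) -> str:
        return json.dumps({
            "scenario_index": self.scenario_index,
            "params": self.best_params.as_dict(),
            "psi": self.psi,
            "K": self.K,
            "evaluations": self.evaluations,
            "seed": self.seed,
            "ga_digest": self.ga_digest,
        }, indent=2)


# ----------------------------------------------------------------------
# Objective
# ----------------------------------------------------------------------

def objective(spec: ScenarioSpec, params: TurnoverParameters,
              grid: SpatialGrid | None = None,
              fixed: FixedParameters | None = None,
              target: ArrayLike | None = None,
              rtol: float = RTOL_DEFAULT,
              atol: float = ATOL_DEFAULT) -> float:
    """Residual sum of squares Psi (uM^2) of the scenario at ``params``.

    ``target`` defaults to the measured 48-h profile evaluated on the
    grid; a synthetic target of matching length may be supplied instead.
    Integration failures return ``+inf`` (and are logged) so an optimizer
    can treat the candidate as infeasible rather than aborting.
    """
    grid = grid or SpatialGrid()
    target = (eval_ffinal(grid.x) if target is None
              else np.asarray(target, dtype=float))
    if target.shape != grid.x.shape:
        raise ValueError("target length does not match the grid")
    try:
        traj = integrate(spec, params, grid=grid, fixed=fixed,
                         rtol=rtol, atol=atol)
    except IntegrationError as exc:
        logger.warning("objective: %s", exc)
        return float("inf")
    return float(np.sum((traj.final.I - target) ** 2))


# ----------------------------------------------------------------------
# Genetic algorithm (generic, bounded, seeded)
# ----------------------------------------------------------------------

def _sbx_crossover(rng, a, b, lo, hi, eta):
    """Simulated-binary crossover of two parents within bounds."""
    u = rng.random(a.shape)
    beta = np.where(u <= 0.5,
                    (2 * u) ** (1.0 / (eta + 1)),
                    (0.5 / (1 - u)) ** (1.0 / (eta + 1)))
    c1 = 0.5 * ((1 + beta) * a + (1 - beta) * b)
    c2 = 0.5 * ((1 - beta) * a + (1 + beta) * b)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def minimize_ga(func, bounds: list[tuple[float, float]], seed: int,
                config: GAConfig | None = None,
                callback=None) -> tuple[NDArray[np.float64], float, int]:
    """Minimize ``func(z)`` over a box with the package's GA.

    Returns ``(z_best, f_best, n_evaluations)``.  With a fixed seed the
    whole run — initialization, selection, variation — is reproducible.
    Elitism makes the best-so-far objective non-increasing across
    generations.
    """
    config = config or GAConfig()
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    n_pop, dim = config.population, len(bounds)

    pop = rng.uniform(lo, hi, size=(n_pop, dim))
    fitness = np.array([func(z) for z in pop])
    n_eval = n_pop

    def tournament_pick():
        idx = rng.integers(0, n_pop, size=config.tournament)
        return pop[idx[np.argmin(fitness[idx])]]

    for gen in range(config.generations):
        order = np.argsort(fitness)
        elites = pop[order[:config.elitism]].copy()
        children = list(elites)
        while len(children) < n_pop:
            p1, p2 = tournament_pick(), tournament_pick()
            if rng.random() < config.crossover_prob:
                c1, c2 = _sbx_crossover(rng, p1, p2, lo, hi,
                                        config.crossover_eta)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                mutate = rng.random(dim) < config.mutation_prob
                if mutate.any():
                    step = rng.normal(0.0, config.mutation_scale * (hi - lo))
                    child[mutate] = np.clip(child + step, lo, hi)[mutate]
                if len(children) < n_pop:
                    children.append(child)
        pop = np.asarray(children)
        # elites keep their known fitness; only new individuals are scored
        new_fitness = np.empty(n_pop)
        new_fitness[:config.elitism] = fitness[order[:config.elitism]]
        for i in range(config.elitism, n_pop):
            new_fitness[i] = func(pop[i])
        n_eval += n_pop - config.elitism
        fitness = new_fitness
        if callback is not None:
            best = int(np.argmin(fitness))
            callback(gen, pop[best], float(fitness[best]))

    best = int(np.argmin(fitness))
    return pop[best].copy(), float(fitness[best]), n_eval


# ----------------------------------------------------------------------
# Per-scenario and batch fitting
# ----------------------------------------------------------------------

def fit_scenario(spec: ScenarioSpec, space: SearchSpace | None = None,
                 ga_config: GAConfig | None = None, seed: int = 0,
                 grid: SpatialGrid | None = None,
                 fixed: FixedParameters | None = None,
                 target: ArrayLike | None = None) -> FitResult:
    """Estimate the scenario's turnover parameters by GA least squares.

    The GA searches at the (possibly coarse) ``search_rtol``; the best
    candidate is optionally polished with a Nelder-Mead simplex and the
    final residual is re-evaluated at the tight ``final_rtol``.
    """
    space = space or SearchSpace.default_for(spec)
    space.validate_for(spec)
    config = ga_config or GAConfig()
    grid = grid or SpatialGrid()
    n_eval_extra = 0

    def make_params(z) -> TurnoverParameters:
        return TurnoverParameters(**space.decode(z))

    def search_func(z) -> float:
        return objective(spec, make_params(z), grid=grid, fixed=fixed,
                         target=target, rtol=config.search_rtol,
                         atol=config.search_atol)

    def log_progress(gen, _z, best):
        logger.info("scenario %d gen %d best psi %.6g",
                    spec.index, gen, best)

    z_best, f_best, n_eval = minimize_ga(
        search_func, [b.internal_interval for b in space.bounds],
        seed=seed, config=config, callback=log_progress)
    if not np.isfinite(f_best):
        raise IntegrationError(
            f"scenario {spec.index}: every GA candidate failed to integrate")

    if config.polish:
        res = minimize(search_func, z_best, method="Nelder-Mead",
                       options=dict(maxfev=config.polish_maxfev,
                                    xatol=1e-4, fatol=1e-8 * max(f_best, 1)))
        n_eval_extra += res.nfev
        lo = np.array([b.internal_interval[0] for b in space.bounds])
        hi = np.array([b.internal_interval[1] for b in space.bounds])
        z_cand = np.clip(res.x, lo, hi)
        if search_func(z_cand) <= f_best:
            z_best = z_cand
        n_eval_extra += 1

    params = make_params(z_best)
    psi = objective(spec, params, grid=grid, fixed=fixed, target=target,
                    rtol=config.final_rtol, atol=config.final_atol)
    return FitResult(
        scenario_index=spec.index,
        best_params=params,
        psi=psi,
        K=n_estimated_parameters(spec),
        evaluations=n_eval + n_eval_extra + 1,
        seed=seed,
        ga_digest=config.digest(),
    )


def fit_all(specs, spaces: dict[str, SearchSpace] | None = None,
            ga_config: GAConfig | None = None,
            seeds: dict[int, int] | int = 0,
            grid: SpatialGrid | None = None,
            fixed: FixedParameters | None = None,
            target: ArrayLike | None = None,
            strict: bool = False) -> dict[int, FitResult]:
    """Fit every scenario independently; results keyed by index.

    ``spaces`` maps turnover kind (``'linear'``/``'nonlinear'``) to a
    search space; ``seeds`` is either one base seed (each scenario gets
    ``base + index``) or an explicit index->seed mapping.  Per-scenario
    failures are logged and omitted from the result unless ``strict``.
    """
    results: dict[int, FitResult] = {}
    for spec in specs:
        if isinstance(seeds, dict):
            seed = seeds[spec.index]
        else:
            seed = int(seeds) + spec.index
        space = (spaces or {}).get(spec.turnover) or SearchSpace.default_for(spec)
        try:
            results[spec.index] = fit_scenario(
                spec, space=space, ga_config=ga_config, seed=seed,
                grid=grid, fixed=fixed, target=target)
        except (IntegrationError, ValueError) as exc:
            logger.error("scenario %d fit failed: %s", spec.index, exc)
            if strict:
                raise
    return results
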