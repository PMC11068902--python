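"""Profile-style min/max uncertainty of parameters and predictions.

Any scalar model property p̂ — a parameter value, or a simulated
observable at one time point — is profiled by solving

    minimize  ± p̂(θ)   subject to   V(θ) < T,

where T is the χ² rejection threshold.  The constraint is relaxed into
the objective as an L1 penalty with an offset,

    penalty = |p̂| + |p̂₀| · (1 + (V(θ) − T))   when V(θ) > T, else 0,

scaled by the property's value p̂₀ at the starting point.  The sign
flip of p̂ turns the maximization into the same minimization problem.
Solutions are accepted only if they are actually feasible (within a
small relative tolerance on T), so a returned bound always comes with
an achieving parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import (
    DEFAULT_CONSTANTS,
    PARAMETER_BOUNDS,
    PARAMETER_NAMES,
    ModelConstants,
    ModelParameters,
)
from .scenario import Scenario
from .simulator import SolverConfig, simulate
from .estimation import ObservationTable, cost

__all__ = [
    "PropertySpec",
    "ProfileConfig",
    "ProfileResult",
    "UncertaintyBand",
    "profile_scalar",
    "profile",
    "prediction_band",
]

#: Relative feasibility tolerance on the χ² threshold when accepting
#: an achieving point.
FEASIBILITY_RTOL = 1e-6


@dataclass(frozen=True)
class PropertySpec:
    """What to profile: a parameter, or a prediction at a time point."""

    kind: str  # "parameter" | "prediction"
    #: parameter name, or (scenario, observable, time) for predictions
    target: object
    direction: str = "min"  # "min" | "max"

    def __post_init__(self) -> None:
        if self.kind not in ("parameter", "prediction"):
            raise ValueError(f"kind must be 'parameter' or 'prediction', got {self.kind!r}")
        if self.direction not in ("min", "max"):
            raise ValueError(f"direction must be 'min' or 'max', got {self.direction!r}")
        if self.kind == "parameter" and self.target not in PARAMETER_NAMES:
            raise ValueError(f"unknown parameter {self.target!r}")


@dataclass(frozen=True)
class ProfileConfig:
    """Settings of the penalized profiling search (seeded)."""

    n_starts: int = 6
    seed: int = 0
    jitter: float = 0.3  # std of the start perturbations (log-units for rates)
    max_iterations: int = 300
    max_evaluations: int = 2000  # hard cap on objective evaluations per start
    xtol: float = 1e-8


@dataclass
class ProfileResult:
    value: float  # the admissible bound found
    theta: np.ndarray  # achieving point (same space as the search)
    cost: float
    threshold: float
    feasible: bool
    direction: str


def _penalized(
    prop: float, prop0: float, cost_value: float, threshold: float, sign: float
) -> float:
    if cost_value > threshold:
        penalty = abs(prop) + abs(prop0) * (1.0 + (cost_value - threshold))
    else:
        penalty = 0.0
    return sign * prop + penalty


def profile_scalar(
    cost_fn: Callable[[np.ndarray], float],
    prop_fn: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    threshold: float,
    direction: str = "min",
    config: ProfileConfig = ProfileConfig(),
    log_space: bool = False,
) -> ProfileResult:
    """Generic penalized min/max of ``prop_fn`` subject to ``cost_fn < T``.

    Works on a plain parameter vector, so it can be exercised on toy
    problems with closed-form sublevel sets.  ``log_space`` perturbs the
    multi-starts multiplicatively (appropriate for positive rate
    constants spanning decades).
    """
    if direction not in ("min", "max"):
        raise ValueError(f"direction must be 'min' or 'max', got {direction!r}")
    sign = 1.0 if direction == "min" else -1.0
    x0 = np.asarray(x0, dtype=float)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    prop0 = prop_fn(x0)
    cost0 = cost_fn(x0)

    def objective(x: np.ndarray) -> float:
        x = np.clip(x, lo, hi)
        c = cost_fn(x)
        if not np.isfinite(c):
            return np.inf
        return _penalized(prop_fn(x), prop0, c, threshold, sign)

    rng = np.random.default_rng(config.seed)
    starts = [x0]
    for _ in range(config.n_starts - 1):
        if log_space:
            pert = x0 * np.exp(rng.normal(scale=config.jitter, size=len(x0)))
        else:
            pert = x0 + rng.normal(scale=config.jitter * (1.0 + np.abs(x0)), size=len(x0))
        starts.append(np.clip(pert, lo, hi))

    feas_tol = threshold * (1.0 + FEASIBILITY_RTOL)
    best_val = prop0 if cost0 <= feas_tol else None
    best_x = x0
    best_cost = cost0
    for s in starts:
        res = minimize(
            objective,
            s,
            method="Powell",
            bounds=list(zip(lo, hi)),
            options={"maxiter": config.max_iterations,
                     "maxfev": config.max_evaluations,
                     "xtol": config.xtol, "ftol": config.xtol},
        )
        x = np.clip(res.x, lo, hi)
        c = cost_fn(x)
        if c <= feas_tol:
            v = prop_fn(x)
            if best_val is None or sign * v < sign * best_val:
                best_val, best_x, best_cost = v, x, c

    if best_val is None:
        return ProfileResult(
            value=np.nan, theta=x0, cost=cost0, threshold=threshold,
            feasible=False, direction=direction,
        )
    # the bound can never be tighter than the (feasible) starting value
    if cost0 <= feas_tol and sign * prop0 < sign * best_val:
        best_val, best_x, best_cost = prop0, x0, cost0
    return ProfileResult(
        value=float(best_val), theta=best_x, cost=float(best_cost),
        threshold=threshold, feasible=True, direction=direction,
    )


def _model_cost_fn(
    free: list[str],
    base: ModelParameters,
    table: ObservationTable,
    scenarios: Mapping[object, Scenario],
    solver_config: SolverConfig,
    constants: ModelConstants,
) -> Callable[[np.ndarray], float]:
    def fn(x: np.ndarray) -> float:
        p = base.replace(**{n: float(v) for n, v in zip(free, x)})
        return cost(p, table, scenarios, solver_config, constants)

    return fn


def profile(
    spec: PropertySpec,
    table: ObservationTable,
    scenarios: Mapping[object, Scenario],
    p0: ModelParameters,
    threshold: float,
    free: Sequence[str] | None = None,
    config: ProfileConfig = ProfileConfig(),
    solver_config: SolverConfig = SolverConfig(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> ProfileResult:
    """Profile one model property against the data in ``table``.

    ``p0`` should be (close to) the best fit; if it is infeasible the
    profiling effectively runs a feasibility phase first, since the
    penalty dominates until the cost drops below the threshold.
    ``free`` restricts which parameters the search may move (default:
    all 17).
    """
    free = list(free) if free is not None else list(PARAMETER_NAMES)
    # search over log-parameters: the rate constants span many decades,
    # and line searches behave far better on the log scale
    x0 = np.log(np.array([getattr(p0, n) for n in free], dtype=float))
    bounds = [tuple(np.log(PARAMETER_BOUNDS[n])) for n in free]
    lin_cost = _model_cost_fn(free, p0, table, scenarios, solver_config, constants)
    cost_fn = lambda x: lin_cost(np.exp(x))  # noqa: E731

    if spec.kind == "parameter":
        if spec.target not in free:
            raise ValueError(f"profiled parameter {spec.target!r} must be free")
        idx = free.index(spec.target)
        prop_fn = lambda x: float(np.exp(x[idx]))  # noqa: E731
    else:
        scn, observable, t_point = spec.target
        grid = np.unique([0.0, float(t_point)])
        i_pt = int(np.searchsorted(grid, float(t_point)))

        def prop_fn(x: np.ndarray) -> float:
            p = p0.replace(**{n: float(v) for n, v in zip(free, np.exp(x))})
            traj = simulate(
                scn.schedule(), scn.anthropometrics, p, basal_peth=scn.basal_peth,
                grid=grid, config=solver_config, constants=constants,
                v_blood=scn.v_blood,
            )
            return float(traj.observables[observable][i_pt])

    res = profile_scalar(
        cost_fn, prop_fn, x0, bounds, threshold,
        direction=spec.direction, config=config, log_space=False,
    )
    res.theta = np.exp(res.theta)  # report achieving parameters on the linear scale
    return res


@dataclass
class UncertaintyBand:
    """Per-time lower/upper admissible prediction values."""

    frame: pd.DataFrame  # columns: time_min, lower, best, upper
    threshold: float
    achieving_lower: list[np.ndarray]
    achieving_upper: list[np.ndarray]

    def contains(self, times: np.ndarray, values: np.ndarray, rtol: float = 1e-9) -> bool:
        f = self.frame.set_index("time_min")
        lower = f.loc[times, "lower"].to_numpy()
        upper = f.loc[times, "upper"].to_numpy()
        slack = rtol * np.maximum(1.0, np.abs(values))
        return bool(np.all(values >= lower - slack) and np.all(values <= upper + slack))


def prediction_band(
    scenario: Scenario,
    observable: str,
    time_grid: Sequence[float],
    table: ObservationTable,
    scenarios: Mapping[object, Scenario],
    p0: ModelParameters,
    threshold: float,
    free: Sequence[str] | None = None,
    config: ProfileConfig = ProfileConfig(),
    solver_config: SolverConfig = SolverConfig(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> UncertaintyBand:
    """Min/max profile of one observable over a grid of time points.

    Applies :func:`profile` per grid point, warm-starting each direction
    from the previous point's achieving parameters.  The band always
    contains the best-fit trajectory (p0 is a feasible candidate at
    every point whenever its cost is below the threshold).  The result
    is independent of the order of the grid points.
    """
    free = list(free) if free is not None else list(PARAMETER_NAMES)
    order = np.argsort(np.asarray(time_grid, dtype=float))
    times_sorted = np.asarray(time_grid, dtype=float)[order]

    rows = {}
    ach_lo, ach_hi = {}, {}
    warm = {"min": p0, "max": p0}
    for t in times_sorted:
        spec_row = {}
        for direction in ("min", "max"):
            spec = PropertySpec("prediction", (scenario, observable, float(t)), direction)
            res = profile(
                spec, table, scenarios, warm[direction], threshold,
                free=free, config=config, solver_config=solver_config,
                constants=constants,
            )
            spec_row[direction] = res
            if res.feasible:
                warm[direction] = warm[direction].replace(
                    **{n: float(v) for n, v in zip(free, res.theta)}
                )
        rows[float(t)] = (spec_row["min"].value, spec_row["max"].value)
        ach_lo[float(t)] = spec_row["min"].theta
        ach_hi[float(t)] = spec_row["max"].theta

    # best-fit trajectory on the same grid
    traj = simulate(
        scenario.schedule(), scenario.anthropometrics, p0,
        basal_peth=scenario.basal_peth,
        grid=np.unique(np.concatenate([[0.0], times_sorted])),
        config=solver_config, constants=constants, v_blood=scenario.v_blood,
    )
    best_lookup = dict(zip(traj.times, traj.observables[observable]))

    frame = pd.DataFrame(
        {
            "time_min": times_sorted,
            "lower": [rows[float(t)][0] for t in times_sorted],
            "best": [best_lookup[float(t)] for t in times_sorted],
            "upper": [rows[float(t)][1] for t in times_sorted],
        }
    )
    return UncertaintyBand(
        frame=frame,
        threshold=threshold,
        achieving_lower=[ach_lo[float(t)] for t in times_sorted],
        achieving_upper=[ach_hi[float(t)] for t in times_sorted],
    )
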