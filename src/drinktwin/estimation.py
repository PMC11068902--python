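"""Weighted least-squares fitting and χ² model evaluation.

The cost is the classical SEM-weighted sum of squared residuals over
every study, observable kind and time point,

    V(θ) = Σ_i Σ_k Σ_j ((y_ikj − ŷ_ikj(θ)) / SEM_ikj)²,

which under additive Gaussian noise is χ²-distributed with one degree
of freedom per data point.  The model is rejected at level α when
V(θ) exceeds the 1−α quantile of χ²(dof), with dof equal to the number
of data points (no parameter-count correction).

``fit`` is a seeded multi-start global search: log-uniform starts in
the estimation box, bound-constrained local refinement of each start,
and a scatter-style geometric recombination of the elite survivors.
Identical seeds give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .model import (
    DEFAULT_CONSTANTS,
    PARAMETER_BOUNDS,
    PARAMETER_NAMES,
    Anthropometrics,
    ModelConstants,
    ModelParameters,
)
from .scenario import Scenario
from .simulator import SolverConfig, simulate

__all__ = [
    "ObservationTable",
    "FitConfig",
    "FitResult",
    "ChiSquareTest",
    "cost",
    "predictions",
    "chi2_threshold",
    "chi2_test",
    "fit",
]

_OBSERVABLE_KINDS = frozenset(
    {"yEtOH", "yBrAC", "yAcetate", "yPEth", "yGastricVolume", "yPEth_delta"}
)

_COLUMNS = ["study_id", "observable", "time_min", "mean", "sem", "n"]


@dataclass(frozen=True)
class ObservationTable:
    """Tidy multi-study observation table (one row per data point)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"observation table is missing columns {missing}")
        bad = set(df["observable"]) - _OBSERVABLE_KINDS
        if bad:
            raise ValueError(f"unrecognized observable kinds {sorted(bad)}")
        if not (df["sem"] > 0).all():
            raise ValueError("every SEM must be > 0")
        if not (df["n"] >= 1).all():
            raise ValueError("every n must be >= 1")
        if not (df["time_min"] >= 0).all():
            raise ValueError("every time must be >= 0")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dof(self) -> int:
        """Degrees of freedom of the χ² test: the number of data points."""
        return len(self.frame)

    @property
    def study_ids(self) -> list:
        return list(dict.fromkeys(self.frame["study_id"]))

    @classmethod
    def read_csv(cls, path: str | Path) -> "ObservationTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame[_COLUMNS].to_csv(path, index=False)

    def concat(self, other: "ObservationTable") -> "ObservationTable":
        return ObservationTable(
            pd.concat([self.frame, other.frame], ignore_index=True)
        )


def predictions(
    params: ModelParameters,
    table: ObservationTable,
    scenarios: Mapping[object, Scenario],
    config: SolverConfig = SolverConfig(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Simulated counterpart ŷ of every record in ``table``.

    Each study is simulated once on the union of its observation times.
    ``yPEth_delta`` records compare against the change from the
    simulated baseline (the study's basal PEth at t = 0).
    """
    out = table.frame.copy()
    out["predicted"] = np.nan
    for study_id, sub in table.frame.groupby("study_id", sort=False):
        if study_id not in scenarios:
            raise KeyError(f"no scenario registered for study {study_id!r}")
        scn = scenarios[study_id]
        if scn.anthropometrics is None and scn.v_blood is None:
            raise ValueError(f"scenario for study {study_id!r} lacks anthropometrics")
        times = np.unique(np.concatenate([[0.0], sub["time_min"].to_numpy(float)]))
        traj = simulate(
            scn.schedule(),
            scn.anthropometrics,
            params,
            basal_peth=scn.basal_peth,
            grid=times,
            config=config,
            constants=constants,
            v_blood=scn.v_blood,
        )
        obs = traj.observables
        lookup = {t: i for i, t in enumerate(times)}
        for idx, row in sub.iterrows():
            i = lookup[row["time_min"]]
            kind = row["observable"]
            if kind == "yPEth_delta":
                out.at[idx, "predicted"] = obs["yPEth"][i] - obs["yPEth"][0]
            else:
                out.at[idx, "predicted"] = obs[kind][i]
    return out


def cost(
    params: ModelParameters,
    table: ObservationTable,
    scenarios: Mapping[object, Scenario],
    config: SolverConfig = SolverConfig(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """SEM-weighted least-squares cost V(θ); +inf on simulation failure."""
    try:
        pred = predictions(params, table, scenarios, config, constants)
    except (RuntimeError, FloatingPointError):
        return np.inf
    res = (pred["mean"] - pred["predicted"]) / pred["sem"]
    return float(np.sum(res.to_numpy() ** 2))


def chi2_threshold(alpha: float, dof: int) -> float:
    """Rejection threshold: the 1−α quantile of the χ² distribution."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if int(dof) != dof or dof < 1:
        raise ValueError(f"dof must be a positive integer, got {dof}")
    return float(stats.chi2.ppf(1.0 - alpha, int(dof)))


@dataclass(frozen=True)
class ChiSquareTest:
    cost: float
    dof: int
    alpha: float
    threshold: float
    passed: bool


def chi2_test(cost_value: float, dof: int, alpha: float = 0.05) -> ChiSquareTest:
    """Accept/reject decision: the model passes iff V(θ) < threshold."""
    if cost_value < 0:
        raise ValueError(f"cost must be >= 0, got {cost_value}")
    threshold = chi2_threshold(alpha, dof)
    return ChiSquareTest(
        cost=float(cost_value),
        dof=int(dof),
        alpha=alpha,
        threshold=threshold,
        passed=bool(cost_value < threshold),
    )


@dataclass(frozen=True)
class FitConfig:
    """Multi-start search settings (everything seeded)."""

    n_starts: int = 20
    seed: int = 0
    n_elites: int = 4
    n_recombinations: int = 6
    local_tol: float = 1e-8
    max_evaluations: int = 400  # per local refinement
    alpha: float = 0.05


@dataclass
class FitResult:
    estimate: ModelParameters
    cost: float
    dof: int
    threshold: float
    passed: bool
    #: one row per local search: start index, start cost, refined cost
    trace: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "estimate": {n: getattr(self.estimate, n) for n in PARAMETER_NAMES},
            "cost": self.cost,
            "dof": self.dof,
            "threshold": self.threshold,
            "passed": self.passed,
        }


def fit(
    table: ObservationTable,
    scenarios: Mapping[object, Scenario],
    free: Sequence[str] | None = None,
    fixed: ModelParameters | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    config: FitConfig = FitConfig(),
    solver_config: SolverConfig = SolverConfig(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> FitResult:
    """Bounded global estimation of (a subset of) the model parameters.

    ``free`` names the parameters to estimate (default: all 17); the
    rest stay at ``fixed`` (default: the published estimate).  Starts
    are sampled log-uniformly inside the estimation box, refined with a
    bound-constrained quasi-Newton search over log-parameters, and the
    elite survivors are recombined geometrically (scatter-search style)
    and refined again.
    """
    free = list(free) if free is not None else list(PARAMETER_NAMES)
    unknown = set(free) - set(PARAMETER_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names {sorted(unknown)}")
    base = fixed if fixed is not None else ModelParameters()
    box = {**{n: PARAMETER_BOUNDS[n] for n in free}, **(dict(bounds) if bounds else {})}
    lo = np.log(np.array([box[n][0] for n in free]))
    hi = np.log(np.array([box[n][1] for n in free]))
    if not np.all(np.isfinite(lo) & np.isfinite(hi)):
        raise ValueError("all bounds must be finite and positive")

    def to_params(logx: np.ndarray) -> ModelParameters:
        return base.replace(**{n: float(np.exp(v)) for n, v in zip(free, logx)})

    n_evals = 0

    def objective(logx: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        return cost(to_params(np.clip(logx, lo, hi)), table, scenarios,
                    solver_config, constants)

    rng = np.random.default_rng(config.seed)
    starts = [lo + rng.random(len(free)) * (hi - lo) for _ in range(config.n_starts)]
    # always include the incumbent defaults when they sit inside the box
    incumbent = np.log([getattr(base, n) for n in free])
    if np.all((incumbent >= lo) & (incumbent <= hi)):
        starts.insert(0, incumbent)

    records = []
    pool: list[tuple[float, np.ndarray]] = []

    def refine(x0: np.ndarray, label: str) -> None:
        nonlocal n_evals
        n_evals = 0
        f0 = objective(x0)
        if not np.isfinite(f0):
            records.append({"start": label, "start_cost": f0, "refined_cost": f0})
            return
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={
                "maxfun": config.max_evaluations,
                "ftol": config.local_tol,
                "gtol": 1e-10,
            },
        )
        records.append({"start": label, "start_cost": f0, "refined_cost": float(res.fun)})
        if np.isfinite(res.fun):
            pool.append((float(res.fun), np.clip(res.x, lo, hi)))

    for i, x0 in enumerate(starts):
        refine(x0, f"start_{i}")

    if not pool:
        raise RuntimeError(
            "fit failure: no start produced a finite cost "
            f"(all {len(starts)} starts hit simulation failures)"
        )

    pool.sort(key=lambda fx: fx[0])
    elites = pool[: config.n_elites]
    for j in range(config.n_recombinations):
        if len(elites) < 2:
            break
        a, b = rng.choice(len(elites), size=2, replace=False)
        w = rng.random()
        child = w * elites[a][1] + (1 - w) * elites[b][1]  # geometric mean in log-space
        child += rng.normal(scale=0.05, size=len(free))
        refine(np.clip(child, lo, hi), f"recomb_{j}")

    pool.sort(key=lambda fx: fx[0])
    best_cost, best_x = pool[0]
    dof = table.dof
    test = chi2_test(best_cost, dof, config.alpha)
    return FitResult(
        estimate=to_params(best_x),
        cost=best_cost,
        dof=dof,
        threshold=test.threshold,
        passed=test.passed,
        trace=pd.DataFrame(records),
    )
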