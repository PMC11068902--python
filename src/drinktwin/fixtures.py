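"""Synthetic observation data and a library of reference scenarios.

The generator emulates the structure of the multi-study estimation
datasets the model is calibrated against: per study, a scenario, a set
of observable kinds, sampling times, and per-point replicate noise.
Measurements are drawn as ``n`` i.i.d. Gaussian replicates around the
noise-free simulation; the table stores their sample mean and
SEM = s/√n, exactly the weighting unit of the fitting cost.  Everything
is seeded, so a fixed seed gives byte-identical tables.

The scenario library packages the beverage/meal interventions of the
source gastric-emptying, plasma-ethanol and PEth studies (plus the
daily-wine long-term schedules) in machine-readable form, so tests and
examples run with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_CONSTANTS,
    Anthropometrics,
    ModelConstants,
    ModelParameters,
)
from .scenario import DrinkEvent, MealEvent, Scenario
from .simulator import SolverConfig, simulate

__all__ = ["SyntheticStudySpec", "generate", "scenario_library", "load_external_tables"]

#: Reference heights (m) for BMI-parameterized individuals.
REFERENCE_HEIGHT_FEMALE = 1.66
REFERENCE_HEIGHT_MALE = 1.80

_REFERENCE_FEMALE = Anthropometrics(sex=0, height=1.66, weight=60.0)
_REFERENCE_MALE = Anthropometrics(sex=1, height=1.80, weight=80.0)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Recipe for one synthetic study."""

    study_id: str
    scenario: Scenario
    #: observable kind -> sampling times (min)
    sampling: Mapping[str, Sequence[float]]
    #: per-observable replicate standard deviation σ; by default 10% of
    #: the observable's peak over the simulated trajectory
    sigma: Mapping[str, float] = field(default_factory=dict)
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates to form a SEM")
        for k, s in self.sigma.items():
            if s <= 0:
                raise ValueError(f"sigma[{k!r}] must be > 0, got {s}")


def generate(
    spec: SyntheticStudySpec,
    params: ModelParameters | None = None,
    config: SolverConfig = SolverConfig(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Simulate the study and draw noisy replicate summaries.

    Returns a tidy frame with the observation-table schema
    (study_id, observable, time_min, mean, sem, n); wrap it in
    :class:`~drinktwin.estimation.ObservationTable` (possibly after
    concatenating several studies) for fitting.
    """
    params = params if params is not None else ModelParameters()
    scn = spec.scenario
    times_all = np.unique(
        np.concatenate([[0.0]] + [np.asarray(list(v), float) for v in spec.sampling.values()])
    )
    if times_all[-1] > scn.horizon:
        raise ValueError("sampling times extend beyond the scenario horizon")
    traj = simulate(
        scn.schedule(), scn.anthropometrics, params, basal_peth=scn.basal_peth,
        grid=times_all, config=config, constants=constants, v_blood=scn.v_blood,
    )
    obs = traj.observables
    lookup = {t: i for i, t in enumerate(times_all)}

    rng = np.random.default_rng(spec.seed)
    rows = []
    for kind in spec.sampling:
        base_kind = "yPEth" if kind == "yPEth_delta" else kind
        clean = obs[base_kind]
        sigma = spec.sigma.get(kind, 0.1 * float(np.max(np.abs(clean))))
        if sigma <= 0:
            raise ValueError(
                f"observable {kind!r} is identically zero in this scenario; "
                "provide an explicit sigma"
            )
        for t in spec.sampling[kind]:
            truth = clean[lookup[float(t)]]
            if kind == "yPEth_delta":
                truth = truth - clean[lookup[0.0]]
            reps = rng.normal(truth, sigma, size=spec.n_replicates)
            sem = float(np.std(reps, ddof=1) / np.sqrt(spec.n_replicates))
            rows.append(
                {
                    "study_id": spec.study_id,
                    "observable": kind,
                    "time_min": float(t),
                    "mean": float(np.mean(reps)),
                    "sem": sem,
                    "n": spec.n_replicates,
                }
            )
    return pd.DataFrame(rows)


def _bmi_person(sex: int, bmi: float) -> Anthropometrics:
    h = REFERENCE_HEIGHT_MALE if sex == 1 else REFERENCE_HEIGHT_FEMALE
    return Anthropometrics.from_bmi(sex, h, bmi)


def scenario_library() -> dict[str, Scenario]:
    """Named, machine-readable reference scenarios.

    Gastric-emptying interventions (isovolumetric beverages of varying
    caloric content, and isocaloric beverages of varying volume),
    plasma-ethanol drinking challenges with and without meals, and the
    daily-wine schedules used for the 90-day PEth predictions.
    """
    lib: dict[str, Scenario] = {}

    def add(name, drinks, meals=(), horizon=360.0, anthro=None, desc=""):
        lib[name] = Scenario(
            drinks=tuple(drinks), meals=tuple(meals), horizon=horizon,
            anthropometrics=anthro, description=desc,
        )

    # gastric emptying: 500 mL over 3 min, caloric content 0 / 220 / 329 kcal
    add("water_500ml", [DrinkEvent(0, 3, 0.5, 0.0, 0.0)], horizon=240,
        anthro=_REFERENCE_MALE, desc="500 mL non-caloric liquid over 3 min")
    add("glucose_500ml_220kcal", [DrinkEvent(0, 3, 0.5, 0.0, 220.0)], horizon=240,
        anthro=_REFERENCE_MALE, desc="500 mL liquid, 220 kcal, over 3 min")
    add("glucose_500ml_329kcal", [DrinkEvent(0, 3, 0.5, 0.0, 329.0)], horizon=240,
        anthro=_REFERENCE_MALE, desc="500 mL liquid, 329 kcal, over 3 min")
    # isocaloric, different volumes
    add("beverage_200ml_200kcal", [DrinkEvent(0, 3, 0.2, 0.0, 200.0)], horizon=240,
        anthro=_REFERENCE_MALE, desc="200 mL liquid, 200 kcal, over 3 min")
    add("beverage_600ml_200kcal", [DrinkEvent(0, 3, 0.6, 0.0, 200.0)], horizon=240,
        anthro=_REFERENCE_MALE, desc="600 mL liquid, 200 kcal, over 3 min")
    add("whisky_150ml", [DrinkEvent(0, 3, 0.15, 8.0, 0.0)], horizon=240,
        anthro=_REFERENCE_MALE, desc="150 mL 8 v/v% drink, no non-ethanol kcal")

    # plasma ethanol: same dose, different beverages
    add("beer_1l", [DrinkEvent(0, 20, 1.0, 5.1, 133.0)], horizon=480,
        anthro=_REFERENCE_MALE, desc="1 L beer, 5.1 v/v%, 133 kcal, over 20 min")
    add("wine_420ml", [DrinkEvent(0, 20, 0.42, 12.5, 56.0)], horizon=480,
        anthro=_REFERENCE_MALE, desc="0.42 L wine, 12.5 v/v%, 56 kcal, over 20 min")
    add("spirit_260ml", [DrinkEvent(0, 20, 0.26, 20.0, 43.0)], horizon=480,
        anthro=_REFERENCE_MALE, desc="0.26 L spirit, 20 v/v%, 43 kcal, over 20 min")
    # fasting vs fed drinking challenges
    add("spirit_140ml_fasted", [DrinkEvent(0, 15, 0.14, 20.0, 51.0)], horizon=480,
        anthro=_REFERENCE_MALE, desc="0.14 L 20 v/v% spirit over 15 min, fasted")
    add("spirit_140ml_meal700", [DrinkEvent(0, 15, 0.14, 20.0, 51.0)],
        meals=[MealEvent(0.0, 700.0)], horizon=480, anthro=_REFERENCE_MALE,
        desc="0.14 L 20 v/v% spirit over 15 min after a 700 kcal meal")
    add("spirit_150ml_meal760", [DrinkEvent(0, 5, 0.15, 20.0, 53.0)],
        meals=[MealEvent(0.0, 760.0)], horizon=480, anthro=_REFERENCE_MALE,
        desc="0.15 L 20 v/v% spirit over 5 min after a 760 kcal meal")
    # acetate / PEth challenges
    add("spirit_280ml_acetate", [DrinkEvent(0, 15, 0.28, 12.4, 85.0)], horizon=480,
        anthro=_REFERENCE_MALE, desc="0.28 L 12.4 v/v% spirit over 15 min")
    add("spirit_710ml_peth", [DrinkEvent(0, 15, 0.71, 6.5, 247.0)], horizon=480,
        anthro=_REFERENCE_MALE, desc="0.71 L 6.5 v/v% spirit over 15 min")

    # daily wine-with-dinner patterns (24 h horizon, chained for months)
    add("daily_wine_female",
        [DrinkEvent(0, 20, 0.15, 13.5, 0.0)], meals=[MealEvent(0.0, 920.0)],
        horizon=1440, anthro=_bmi_person(0, 22.5),
        desc="one 15 cL glass of 13.5 v/v% wine with a 920 kcal dinner")
    add("daily_wine_male",
        [DrinkEvent(0, 20, 0.30, 13.5, 0.0)], meals=[MealEvent(0.0, 1120.0)],
        horizon=1440, anthro=_bmi_person(1, 22.5),
        desc="two 15 cL glasses (30 cL) of 13.5 v/v% wine with a 1120 kcal dinner")
    return lib


def load_external_tables(directory) -> dict[str, pd.DataFrame]:
    """Load externally deposited observation tables, if present.

    Expects tidy CSV files with the observation-table schema
    (study_id, observable, time_min, mean, sem, n), e.g.
    ``estimation.csv`` and ``validation.csv`` exported from the public
    data deposit.  Purely optional — nothing in the package or the test
    suite requires these files.
    """
    from pathlib import Path

    directory = Path(directory)
    out = {}
    for f in sorted(directory.glob("*.csv")):
        out[f.stem] = pd.read_csv(f)
    return out
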