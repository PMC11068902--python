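"""Drinking/meal schedules compiled to piecewise-constant model inputs.

A scenario is a list of timed drink events (finite-rate liquid inputs)
and meal events (instantaneous state jumps).  ``compile_schedule`` turns
these into an :class:`InputSchedule`: an exact piecewise-constant input
evaluator plus the sorted list of discontinuity times at which the
integrator must be restarted.

Meals add their calories to both the remaining (``kcal_solid``) and the
reference (``max_kcal_solid``) solid load and reset the since-last-meal
clock.  When the solid load has been digested down to the 1-kcal floor,
the leftover encapsulated ethanol and the meal bookkeeping states are
zeroed (``pool_reset``); the simulator locates that crossing by
root-finding and logs the discarded ethanol mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .model import (
    Anthropometrics,
    I_ETOH_POOL,
    I_KCAL_SOLID,
    I_MAX_KCAL_SOLID,
    I_TIME_ELAPSED,
    ModelInputs,
    ModelState,
)

__all__ = [
    "DrinkEvent",
    "MealEvent",
    "InputSchedule",
    "Scenario",
    "compile_schedule",
    "apply_meal",
    "pool_reset",
    "load_scenario",
]

#: Solid-calorie floor below which the meal counts as fully digested.
#: Chosen to coincide with the gate that switches the food-pool fluxes
#: off, so the reset never discards an actively exchanging pool.
POOL_RESET_KCAL = 1.0

#: Two event times closer than this (min) are treated as one.
_TIME_TOL = 1e-9


@dataclass(frozen=True)
class DrinkEvent:
    """One beverage consumed at a constant rate over a finite interval."""

    start: float  # min
    duration: float  # min
    volume: float  # L
    ethanol_vv: float  # v/v%
    kcal: float = 0.0  # non-ethanol kcal in the whole beverage

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"drink duration must be > 0 min, got {self.duration}")
        if self.volume <= 0:
            raise ValueError(f"drink volume must be > 0 L, got {self.volume}")
        if not 0 <= self.ethanol_vv <= 100:
            raise ValueError(f"ethanol_vv must be in [0, 100] v/v%, got {self.ethanol_vv}")
        if self.kcal < 0:
            raise ValueError(f"drink kcal must be >= 0, got {self.kcal}")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def rate(self) -> float:
        """Drinking rate in L/min."""
        return self.volume / self.duration

    @property
    def ethanol_grams(self) -> float:
        """Total ethanol mass in grams (density 0.7891 g/mL)."""
        return self.volume * 1000.0 * self.ethanol_vv / 100.0 * 0.7891


@dataclass(frozen=True)
class MealEvent:
    """A solid meal, applied instantaneously to the gastric states."""

    time: float  # min
    kcal: float

    def __post_init__(self) -> None:
        if self.kcal <= 0:
            raise ValueError(f"meal kcal must be > 0, got {self.kcal}")


@dataclass(frozen=True)
class InputSchedule:
    """Compiled schedule: exact piecewise-constant inputs + event times."""

    drinks: tuple[DrinkEvent, ...]
    meals: tuple[MealEvent, ...]
    horizon: float
    event_times: np.ndarray = field(repr=False)

    def inputs_at(self, t: float) -> ModelInputs:
        """Exact input vector at time ``t`` (no interpolation).

        Overlapping drinks add their volume rates; the ethanol
        concentration and caloric density of the blend are the
        volume-rate-weighted means of the contributing beverages.
        """
        rate = 0.0
        conc_flux = 0.0  # Σ rate_i · vv_i
        kcal_flux = 0.0  # Σ rate_i · (kcal_i / volume_i)
        for d in self.drinks:
            if d.start - _TIME_TOL <= t < d.end - _TIME_TOL:
                rate += d.rate
                conc_flux += d.rate * d.ethanol_vv
                kcal_flux += d.rate * d.kcal / d.volume
        if rate == 0.0:
            return ModelInputs()
        return ModelInputs(
            vol_drink_per_time=rate,
            kcal_liquid_per_vol=kcal_flux / rate,
            etoh_conc=conc_flux / rate,
        )

    def meals_at(self, t: float) -> float:
        """Total meal kcal scheduled at time ``t`` (0 if none)."""
        return sum(m.kcal for m in self.meals if abs(m.time - t) <= _TIME_TOL)

    def segments(self) -> list[tuple[float, float, ModelInputs]]:
        """Consecutive (t0, t1, constant inputs) intervals covering the horizon."""
        times = self.event_times
        out = []
        for t0, t1 in zip(times[:-1], times[1:]):
            out.append((float(t0), float(t1), self.inputs_at(0.5 * (t0 + t1))))
        return out

    @property
    def total_drink_volume(self) -> float:
        return sum(d.volume for d in self.drinks)

    @property
    def total_ethanol_mg(self) -> float:
        return sum(d.ethanol_grams for d in self.drinks) * 1000.0

    def shifted(self, delta: float) -> "InputSchedule":
        """The same schedule with every event delayed by ``delta`` minutes."""
        return compile_schedule(
            [DrinkEvent(d.start + delta, d.duration, d.volume, d.ethanol_vv, d.kcal)
             for d in self.drinks],
            [MealEvent(m.time + delta, m.kcal) for m in self.meals],
            self.horizon + delta,
        )


def compile_schedule(
    drinks: Sequence[DrinkEvent],
    meals: Sequence[MealEvent],
    horizon: float,
) -> InputSchedule:
    """Validate events against the horizon and build the schedule."""
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0 min, got {horizon}")
    for i, d in enumerate(drinks):
        if d.start < 0 or d.end > horizon + _TIME_TOL:
            raise ValueError(
                f"drinks[{i}]: interval [{d.start}, {d.end}] outside [0, {horizon}]"
            )
    for i, m in enumerate(meals):
        if not 0 <= m.time <= horizon:
            raise ValueError(f"meals[{i}]: time {m.time} outside [0, {horizon}]")

    times = [0.0, float(horizon)]
    times += [d.start for d in drinks] + [d.end for d in drinks]
    times += [m.time for m in meals]
    uniq: list[float] = []
    for t in sorted(times):
        if not uniq or t - uniq[-1] > _TIME_TOL:
            uniq.append(t)
    return InputSchedule(
        drinks=tuple(drinks),
        meals=tuple(meals),
        horizon=float(horizon),
        event_times=np.asarray(uniq),
    )


def apply_meal(state: ModelState | np.ndarray, kcal: float):
    """Add a meal's calories to the solid states and reset the meal clock.

    Returns the same container kind as was passed in.  Every non-gastric
    state is left untouched.
    """
    if kcal <= 0:
        raise ValueError(f"meal kcal must be > 0, got {kcal}")
    if isinstance(state, ModelState):
        return state.replace(
            kcal_solid=state.kcal_solid + kcal,
            max_kcal_solid=state.max_kcal_solid + kcal,
            time_elapsed=0.0,
        )
    y = np.array(state, dtype=float)
    y[I_KCAL_SOLID] += kcal
    y[I_MAX_KCAL_SOLID] += kcal
    y[I_TIME_ELAPSED] = 0.0
    return y


def pool_reset(state: ModelState | np.ndarray):
    """Zero the meal bookkeeping and encapsulated ethanol after digestion.

    Triggered when ``kcal_solid`` falls to the 1-kcal digestion floor;
    idempotent.  The zeroed ``etoh_pool`` mass is discarded from the
    system (the simulator logs it).
    """
    if isinstance(state, ModelState):
        return state.replace(kcal_solid=0.0, max_kcal_solid=0.0, etoh_pool=0.0)
    y = np.array(state, dtype=float)
    y[I_KCAL_SOLID] = 0.0
    y[I_MAX_KCAL_SOLID] = 0.0
    y[I_ETOH_POOL] = 0.0
    return y


@dataclass(frozen=True)
class Scenario:
    """A named, self-contained simulation setup."""

    drinks: tuple[DrinkEvent, ...]
    meals: tuple[MealEvent, ...]
    horizon: float
    anthropometrics: Anthropometrics | None = None
    basal_peth: float = 0.0
    description: str = ""
    #: mixed-cohort override (sex-fraction-weighted mean blood volume, dL)
    v_blood: float | None = None

    def schedule(self) -> InputSchedule:
        return compile_schedule(self.drinks, self.meals, self.horizon)


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ValueError(f"{where}: missing required key '{key}'")
    return mapping[key]


def load_scenario(path: str | Path) -> Scenario:
    """Read a scenario config file (YAML or JSON).

    Schema::

        person: {sex: 0|1, height: m, weight: kg, basal_peth: ng/mL}
        drinks: [{start, duration, volume, ethanol_vv, kcal}, ...]
        meals:  [{time, kcal}, ...]
        horizon: min

    ``person`` and ``meals`` are optional.  Validation errors name the
    offending entry.
    """
    path = Path(path)
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"{path}: could not parse scenario file: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario file must contain a mapping at top level")

    horizon = float(_require(raw, "horizon", str(path)))
    drinks = []
    for i, d in enumerate(raw.get("drinks", [])):
        where = f"{path}: drinks[{i}]"
        try:
            drinks.append(
                DrinkEvent(
                    start=float(_require(d, "start", where)),
                    duration=float(_require(d, "duration", where)),
                    volume=float(_require(d, "volume", where)),
                    ethanol_vv=float(_require(d, "ethanol_vv", where)),
                    kcal=float(d.get("kcal", 0.0)),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from exc
    meals = []
    for i, m in enumerate(raw.get("meals", [])):
        where = f"{path}: meals[{i}]"
        try:
            meals.append(
                MealEvent(time=float(_require(m, "time", where)),
                          kcal=float(_require(m, "kcal", where)))
            )
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from exc

    anthro = None
    basal = 0.0
    if "person" in raw:
        person = raw["person"]
        where = f"{path}: person"
        try:
            anthro = Anthropometrics(
                sex=int(_require(person, "sex", where)),
                height=float(_require(person, "height", where)),
                weight=float(_require(person, "weight", where)),
            )
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from exc
        basal = float(person.get("basal_peth", 0.0))

    # compile once to surface horizon violations with entry context
    compile_schedule(drinks, meals, horizon)
    return Scenario(
        drinks=tuple(drinks),
        meals=tuple(meals),
        horizon=horizon,
        anthropometrics=anthro,
        basal_peth=basal,
        description=str(raw.get("description", "")),
    )
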