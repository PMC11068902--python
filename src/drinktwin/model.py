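"""Core physiology: ODE right-hand side, observables, and defaults.

This module contains only pure functions and typed containers — no solver
and no I/O.  The model couples four sub-systems sharing one stomach:

* **Gastric emptying** — liquid volume leaves the stomach through a
  Michaelis–Menten valve that is inhibited exponentially by the liquid
  caloric load; solid (meal) calories empty along a Tougas-type
  power-exponential retention curve.
* **Ethanol absorption** — ethanol enters the stomach with the drink,
  can be reversibly encapsulated into solid food (the "food pool"),
  passes to the intestines with the emptied liquid, and is absorbed
  into blood or eliminated first-pass.
* **Hepatic metabolism** — two saturable pathways, ADH and CYP2E1,
  clear blood ethanol and produce plasma acetate.
* **PEth** — phosphatidylethanol is formed from blood ethanol, cleared
  from plasma, and exchanges with a slowly equilibrating lipid-bound
  pool, which is what makes it a weeks-scale consumption biomarker.

Internal units: time min, volume dL, ethanol concentration mg/dL,
ethanol mass mg, energy kcal, PEth ng/mL.  Drink volume inputs are in L
(the explicit ·10 factors are the L→dL conversion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from types import MappingProxyType
from typing import Mapping

import numpy as np

__all__ = [
    "Anthropometrics",
    "ModelConstants",
    "ModelParameters",
    "ModelState",
    "ModelInputs",
    "PARAMETER_NAMES",
    "PARAMETER_BOUNDS",
    "STATE_NAMES",
    "OBSERVABLE_NAMES",
    "DEFAULT_CONSTANTS",
    "blood_volume",
    "gastric_retention",
    "reaction_rates",
    "rhs",
    "observables",
    "initial_state",
]


@dataclass(frozen=True)
class Anthropometrics:
    """Sex, height and weight of the simulated person.

    ``sex`` is a binary flag (1 = male, 0 = female) and is the only
    covariate beside body size: it selects the blood-volume regression.
    Height is in meters, weight in kilograms.
    """

    sex: int
    height: float
    weight: float

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 (female) or 1 (male), got {self.sex!r}")
        if not 0.5 < self.height < 2.5:
            raise ValueError(f"height must be in (0.5, 2.5) m, got {self.height}")
        if not 20 < self.weight < 300:
            raise ValueError(f"weight must be in (20, 300) kg, got {self.weight}")

    @classmethod
    def from_bmi(cls, sex: int, height: float, bmi: float) -> "Anthropometrics":
        """Build from a BMI value with weight = BMI·height²."""
        return cls(sex=sex, height=height, weight=bmi * height**2)

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2


@dataclass(frozen=True)
class ModelConstants:
    """Fixed physico-chemical constants; not subject to estimation."""

    ss_vol: float = 0.001  # dL, minimal (residual) stomach volume
    ethanol_density_factor: float = 789.1  # mg/dL of ethanol per v/v%
    kcal_per_gram: float = 4.0  # average caloric density of food
    v_liver: float = 15.0  # dL
    acetate_scale: float = 10.2  # mg/dL per mM, acetate unit conversion
    brac_slope: float = 0.840  # BrAC–BAC linear regression
    brac_intercept: float = 0.00367
    tougas_rate: float = 0.010  # min⁻¹, solid-emptying rate constant
    tougas_shape: float = 1.86  # retention-curve shape exponent
    # Coefficient and exponent of the solid-emptying flux as printed in
    # the source rate law.  Note 1.88 is not the analytic derivative of
    # the retention curve (which would reuse the shape 1.86); it is kept
    # as its own switch so either convention can be selected.
    tougas_deriv_coeff: float = 1.88
    tougas_deriv_exp: float = 0.86


DEFAULT_CONSTANTS = ModelConstants()

#: Canonical parameter ordering used by every array interface.
PARAMETER_NAMES: tuple[str, ...] = (
    "kPEth",
    "kPEth_out",
    "kPEth_bind",
    "kPEth_release",
    "kPool_In",
    "kPool_Out",
    "Vmax",
    "km",
    "kKcal",
    "k3",
    "k4",
    "k6",
    "Vmax_ADH",
    "Vmax_CYP2E1",
    "km_ADH",
    "km_CYP2E1",
    "kKcal_clearance",
)

#: Estimation box constraints per parameter.  Most parameters share a
#: wide generic box; the two Michaelis constants of the hepatic enzymes
#: are restricted to literature ranges.
PARAMETER_BOUNDS: Mapping[str, tuple[float, float]] = MappingProxyType(
    {
        **{name: (1e-5, 1e5) for name in PARAMETER_NAMES},
        "km_ADH": (9.22e-1, 9.22e0),
        "km_CYP2E1": (3.688e1, 4.61e1),
    }
)


@dataclass(frozen=True)
class ModelParameters:
    """The 17 estimated rate/affinity constants.

    The default constructor returns the published best-fit estimate.
    All values are strictly positive; units follow from the rate laws
    (min⁻¹, dL/min, mg/dL, kcal as appropriate).
    """

    kPEth: float = 1.4599e4
    kPEth_out: float = 1.5695e2
    kPEth_bind: float = 1.7416e4
    kPEth_release: float = 5.8081e-3
    kPool_In: float = 1.0155e1
    kPool_Out: float = 4.0227e-1
    Vmax: float = 2.1545e3
    km: float = 1.7793e4
    kKcal: float = 1.5843e2
    k3: float = 8.4172e1
    k4: float = 8.3001e2
    k6: float = 1.3079e-1
    Vmax_ADH: float = 9.6381e-1
    Vmax_CYP2E1: float = 1.7148e-1
    km_ADH: float = 9.2200e0
    km_CYP2E1: float = 3.6880e1
    kKcal_clearance: float = 6.1804e-3

    bounds = PARAMETER_BOUNDS

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ModelParameters":
        return cls(**dict(zip(PARAMETER_NAMES, map(float, values))))

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def within_bounds(self) -> bool:
        return all(
            PARAMETER_BOUNDS[n][0] <= getattr(self, n) <= PARAMETER_BOUNDS[n][1]
            for n in PARAMETER_NAMES
        )


#: Canonical state ordering used by every array interface.
STATE_NAMES: tuple[str, ...] = (
    "vol_stomach",
    "kcal_liquid",
    "max_kcal_solid",
    "kcal_solid",
    "time_elapsed",
    "etoh_pool",
    "conc_etoh_stomach",
    "mass_etoh_intestines",
    "blood_conc",
    "plasma_acetate",
    "peth",
    "peth_bound",
)

# Index constants for fast array access.
(
    I_VOL_STOMACH,
    I_KCAL_LIQUID,
    I_MAX_KCAL_SOLID,
    I_KCAL_SOLID,
    I_TIME_ELAPSED,
    I_ETOH_POOL,
    I_CONC_ETOH_STOMACH,
    I_MASS_ETOH_INTESTINES,
    I_BLOOD_CONC,
    I_PLASMA_ACETATE,
    I_PETH,
    I_PETH_BOUND,
) = range(12)


@dataclass(frozen=True)
class ModelState:
    """The 12 dynamical states.

    ``vol_stomach`` dL, caloric states kcal, ``time_elapsed`` min since
    the last meal, ethanol pool/intestinal masses mg, stomach/blood
    ethanol concentrations mg/dL, acetate in internal units (scaled to
    mM on output), PEth states ng/mL.
    """

    vol_stomach: float = 1.0e-3
    kcal_liquid: float = 0.0
    max_kcal_solid: float = 0.0
    kcal_solid: float = 0.0
    time_elapsed: float = 0.0
    etoh_pool: float = 0.0
    conc_etoh_stomach: float = 0.0
    mass_etoh_intestines: float = 0.0
    blood_conc: float = 0.0
    plasma_acetate: float = 0.0
    peth: float = 0.0
    peth_bound: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ModelState":
        return cls(**dict(zip(STATE_NAMES, map(float, values))))

    def replace(self, **changes: float) -> "ModelState":
        return replace(self, **changes)


@dataclass(frozen=True)
class ModelInputs:
    """Piecewise-constant external inputs (zero outside drink intervals)."""

    vol_drink_per_time: float = 0.0  # L/min
    kcal_liquid_per_vol: float = 0.0  # kcal per L of beverage
    etoh_conc: float = 0.0  # v/v%

    def __post_init__(self) -> None:
        if self.vol_drink_per_time < 0 or self.kcal_liquid_per_vol < 0 or self.etoh_conc < 0:
            raise ValueError("model inputs must be non-negative")


OBSERVABLE_NAMES: tuple[str, ...] = (
    "yEtOH",
    "yAcetate",
    "yBrAC",
    "yPEth",
    "yGastricVolume",
)


def blood_volume(a: Anthropometrics, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Total blood volume in dL from sex-specific Nadler-type regressions.

    Height in meters, weight in kg; the regression yields liters and is
    multiplied by 10 to express the result in dL.
    """
    if a.sex == 0:
        liters = 0.3561 * a.height**3 + 0.03308 * a.weight + 0.1833
    elif a.sex == 1:
        liters = 0.3669 * a.height**3 + 0.03219 * a.weight + 0.6041
    else:  # pragma: no cover - Anthropometrics already validates
        raise ValueError(f"sex must be 0 or 1, got {a.sex!r}")
    return liters * 10.0


def cohort_blood_volume(
    members: "list[tuple[Anthropometrics, float]]",
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Weighted mean blood volume for a mixed cohort.

    ``members`` is a list of (anthropometrics, fraction) pairs, e.g. a
    study population given only as a sex distribution with mean height
    and weight per sex.  Fractions must sum to 1.
    """
    fractions = [f for _, f in members]
    if not math.isclose(sum(fractions), 1.0, rel_tol=1e-9):
        raise ValueError(f"cohort fractions must sum to 1, got {sum(fractions)}")
    return sum(f * blood_volume(a, constants) for a, f in members)


def gastric_retention(t: float, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Fraction of a solid meal retained in the stomach ``t`` minutes after it.

    Power-exponential Tougas curve ``exp(-(rate·t)^shape)``; negative
    times are clamped to zero, so the value is 1 at (and before) the meal
    and non-increasing afterwards.
    """
    x = constants.tougas_rate * max(0.0, t)
    return math.exp(-(x**constants.tougas_shape))


def _rates(
    t: float,
    y: np.ndarray,
    u: ModelInputs,
    p: ModelParameters,
    v_blood: float,
    c: ModelConstants,
) -> dict[str, float]:
    """All reaction rates at one state point, keyed by their model names."""
    vol = y[I_VOL_STOMACH]
    if vol <= 0:
        raise FloatingPointError(
            f"gastric volume {vol} <= 0 at t={t}; the integration left the model domain"
        )
    kcal_liquid = y[I_KCAL_LIQUID]
    kcal_solid = y[I_KCAL_SOLID]

    vol_change = vol - c.ss_vol
    r2 = (
        p.Vmax
        * (vol_change / (vol_change + p.km))
        * math.exp(-max(0.0, kcal_liquid) / p.kKcal)
    )
    x = c.tougas_rate * max(0.0, y[I_TIME_ELAPSED])
    r_kcal_solid = (
        y[I_MAX_KCAL_SOLID]
        * c.tougas_deriv_coeff
        * c.tougas_rate
        * x**c.tougas_deriv_exp
        * math.exp(-(x**c.tougas_shape))
        if x > 0.0
        else 0.0
    )
    r_kcal_clearance = kcal_liquid * p.kKcal_clearance
    kcal_solid_vol = max(1.0, kcal_solid) / (c.kcal_per_gram * 100.0)

    # Ethanol can only diffuse into/out of the food pool while there is
    # actual food and a non-degenerate stomach volume.
    if kcal_solid <= 1.0 or vol < 2.0 * c.ss_vol:
        r_pool_in = 0.0
        r_pool_out = 0.0
    else:
        r_pool_in = (
            max(0.0, y[I_CONC_ETOH_STOMACH] - y[I_ETOH_POOL] / kcal_solid_vol) * p.kPool_In
        )
        r_pool_out = y[I_ETOH_POOL] * p.kPool_Out

    conc_drink = u.etoh_conc * c.ethanol_density_factor
    r_drink_etoh = (conc_drink - y[I_CONC_ETOH_STOMACH]) * u.vol_drink_per_time / vol * 10.0

    blood = y[I_BLOOD_CONC]
    r3 = y[I_MASS_ETOH_INTESTINES] * p.k3
    r4 = y[I_MASS_ETOH_INTESTINES] * p.k4
    v_adh = p.Vmax_ADH * blood / (p.km_ADH + blood)
    v_cyp2e1 = p.Vmax_CYP2E1 * blood / (p.km_CYP2E1 + blood)
    r5 = v_adh + v_cyp2e1
    r6 = y[I_PLASMA_ACETATE] * p.k6

    peth = y[I_PETH]
    r_peth = p.kPEth * blood
    r_peth_clearance = p.kPEth_out * peth
    r_peth_bound = p.kPEth_bind * peth
    r_peth_release = max(0.0, p.kPEth_release * (y[I_PETH_BOUND] - peth))

    return {
        "r2": r2,
        "rKcal_Solid": r_kcal_solid,
        "rKcal_clearance": r_kcal_clearance,
        "kcalSolidVol": kcal_solid_vol,
        "rPool_In": r_pool_in,
        "rPool_Out": r_pool_out,
        "rDrink_EtOH": r_drink_etoh,
        "concDrink": conc_drink,
        "r3": r3,
        "r4": r4,
        "vADH": v_adh,
        "vCYP2E1": v_cyp2e1,
        "r5": r5,
        "r6": r6,
        "rPEth": r_peth,
        "rPEth_clearance": r_peth_clearance,
        "rPEth_bound": r_peth_bound,
        "rPEth_release": r_peth_release,
    }


def reaction_rates(
    t: float,
    state: ModelState | np.ndarray,
    inputs: ModelInputs,
    params: ModelParameters,
    anthro: Anthropometrics,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> dict[str, float]:
    """Evaluate every reaction rate by name (diagnostic/companion to :func:`rhs`)."""
    y = state.to_array() if isinstance(state, ModelState) else np.asarray(state, dtype=float)
    return _rates(t, y, inputs, params, blood_volume(anthro, constants), constants)


def _rhs_array(
    t: float,
    y: np.ndarray,
    u: ModelInputs,
    p: ModelParameters,
    v_blood: float,
    c: ModelConstants,
) -> np.ndarray:
    r = _rates(t, y, u, p, v_blood, c)
    dy = np.empty(12)
    dy[I_VOL_STOMACH] = u.vol_drink_per_time * 10.0 - r["r2"]
    dy[I_KCAL_LIQUID] = u.vol_drink_per_time * u.kcal_liquid_per_vol - r["rKcal_clearance"]
    dy[I_MAX_KCAL_SOLID] = 0.0  # changes only through meal/reset events
    dy[I_KCAL_SOLID] = -r["rKcal_Solid"]
    dy[I_TIME_ELAPSED] = 1.0
    dy[I_ETOH_POOL] = r["rPool_In"] * y[I_VOL_STOMACH] - r["rPool_Out"]
    dy[I_CONC_ETOH_STOMACH] = (
        r["rDrink_EtOH"] - r["rPool_In"] + r["rPool_Out"] / y[I_VOL_STOMACH]
    )
    dy[I_MASS_ETOH_INTESTINES] = r["r2"] * y[I_CONC_ETOH_STOMACH] - r["r3"] - r["r4"]
    dy[I_BLOOD_CONC] = r["r3"] / v_blood - r["r5"] * c.v_liver / v_blood
    dy[I_PLASMA_ACETATE] = r["r5"] - r["r6"]
    dy[I_PETH] = (
        r["rPEth"] - r["rPEth_bound"] + r["rPEth_release"] - r["rPEth_clearance"]
    )
    dy[I_PETH_BOUND] = r["rPEth_bound"] - r["rPEth_release"]
    return dy


def rhs(
    t: float,
    state: ModelState | np.ndarray,
    inputs: ModelInputs,
    params: ModelParameters,
    anthro: Anthropometrics,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Time derivative of the full state vector (canonical state order)."""
    y = state.to_array() if isinstance(state, ModelState) else np.asarray(state, dtype=float)
    return _rhs_array(t, y, inputs, params, blood_volume(anthro, constants), constants)


def observables(
    state: ModelState | np.ndarray,
    params: ModelParameters | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> dict[str, float]:
    """Map a state to the measured quantities.

    yEtOH: blood ethanol, mg/dL.  yAcetate: plasma acetate in mM.
    yBrAC: breath alcohol in g/210 L breath-equivalent via the linear
    BrAC–BAC regression (the /1000 converts mg to g).  yPEth: free
    plasma PEth, ng/mL.  yGastricVolume: dL.
    """
    y = state.to_array() if isinstance(state, ModelState) else np.asarray(state, dtype=float)
    blood = y[..., I_BLOOD_CONC]
    return {
        "yEtOH": blood,
        "yAcetate": y[..., I_PLASMA_ACETATE] / constants.acetate_scale,
        "yBrAC": constants.brac_slope * blood / 1000.0 + constants.brac_intercept,
        "yPEth": y[..., I_PETH],
        "yGastricVolume": y[..., I_VOL_STOMACH],
    }


def initial_state(
    basal_peth: float = 0.0,
    params: ModelParameters | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> ModelState:
    """Fasted rest state with an optional non-zero basal PEth level.

    All states are zero except the residual gastric volume (ss_vol).
    When ``basal_peth > 0`` the bound pool is initialized at the
    binding/release quasi-equilibrium, ``PEth_Bound = basal·(1 +
    kPEth_bind/kPEth_release)``, which makes the bind and release fluxes
    cancel exactly at t = 0 so that the basal level is a steady state of
    the drink-free PEth subsystem.
    """
    if basal_peth < 0:
        raise ValueError(f"basal PEth must be non-negative, got {basal_peth}")
    p = params if params is not None else ModelParameters()
    peth_bound = basal_peth * (1.0 + p.kPEth_bind / p.kPEth_release)
    return ModelState(vol_stomach=constants.ss_vol, peth=basal_peth, peth_bound=peth_bound)
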