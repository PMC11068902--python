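import numpy as np
import pytest

from drinktwin import (
    Anthropometrics,
    DrinkEvent,
    MealEvent,
    ModelParameters,
    ObservationTable,
    Scenario,
    SyntheticStudySpec,
    compile_schedule,
    generate,
    scenario_library,
)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def male():
    return Anthropometrics(sex=1, height=1.80, weight=80.0)


@pytest.fixture(scope="session")
def female():
    return Anthropometrics(sex=0, height=1.66, weight=60.0)


@pytest.fixture(scope="session")
def library():
    return scenario_library()


@pytest.fixture(scope="session")
def beer_schedule(library):
    return library["beer_1l"].schedule()


def make_synthetic_dataset(seed=0, n_replicates=10):
    """Two-study synthetic dataset (gastric volume + blood ethanol)."""
    lib = scenario_library()
    specs = [
        SyntheticStudySpec(
            study_id="gastric",
            scenario=lib["glucose_500ml_220kcal"],
            sampling={"yGastricVolume": [10.0, 30.0, 60.0, 120.0, 180.0]},
            seed=seed,
            n_replicates=n_replicates,
        ),
        SyntheticStudySpec(
            study_id="ethanol",
            scenario=lib["beer_1l"],
            sampling={"yEtOH": [20.0, 40.0, 60.0, 120.0, 240.0, 360.0]},
            seed=seed + 1,
            n_replicates=n_replicates,
        ),
    ]
    import pandas as pd

    frames = [generate(s) for s in specs]
    table = ObservationTable(pd.concat(frames, ignore_index=True))
    scenarios = {s.study_id: s.scenario for s in specs}
    return table, scenarios


@pytest.fixture(scope="session")
def synthetic_dataset():
    return make_synthetic_dataset(seed=42)
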