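import numpy as np
import pytest

from relsev import (
    Cohort,
    AnimalSeries,
    VariableSpec,
    build_reference,
    default_variable_specs,
    simulate_reference_cohort,
)


@pytest.fixture(scope="session")
def specs():
    return default_variable_specs()


@pytest.fixture
def toy_specs():
    """Two-variable spec set: one percent, one ordinal."""
    return {
        "bw": VariableSpec("bw", "down", "percent_of_baseline", (0.0, 200.0)),
        "ds": VariableSpec("ds", "up", "native_ordinal", (0.0, 10.0), max_score=10),
    }


def make_animal(animal_id="a1", model="M", subgroup="g", days=(-1, 0, 1), **values):
    days = np.asarray(days, dtype=int)
    vals = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    return AnimalSeries(animal_id, model, subgroup, days, vals)


@pytest.fixture
def toy_cohort(toy_specs):
    animals = [
        make_animal("a1", days=(-1, 0, 1), bw=(100, 90, 95), ds=(0, 3, 1)),
        make_animal("a2", days=(-1, 0, 1), bw=(100, 85, 92), ds=(0, 4, 2)),
    ]
    return Cohort(animals, toy_specs, provenance="toy")


@pytest.fixture(scope="session")
def reference_lab_a(specs):
    cohort, _ = simulate_reference_cohort(10, seed=7, provenance="laboratory A")
    return build_reference(cohort)


@pytest.fixture(scope="session")
def reference_lab_b(specs):
    cohort, _ = simulate_reference_cohort(
        10, variables=("body_weight", "burrowing"), seed=8, provenance="laboratory B"
    )
    return build_reference(cohort)
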