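import math

import pytest

from tgrkit.model import AnimalSeries, Measurement, Study, Unit


def make_series(animal_id, group, days, values, **kw):
    return AnimalSeries(
        animal_id=animal_id,
        group=group,
        measurements=[Measurement(day=d, value=v) for d, v in zip(days, values)],
        **kw,
    )


def exponential_series(animal_id, group, days, n0, r):
    return make_series(
        animal_id, group, days, [n0 * math.exp(r * d) for d in days]
    )


@pytest.fixture
def clean_two_group_study():
    """Noiseless exponential cohort: control r=0.30, treated r=0.10."""
    days = [0, 3, 5, 7, 10, 14]
    animals = [
        exponential_series(f"c{i}", "control", days, 100 * (1 + 0.1 * i), 0.30)
        for i in range(5)
    ] + [
        exponential_series(f"t{i}", "treated", days, 100 * (1 + 0.1 * i), 0.10)
        for i in range(5)
    ]
    return Study(animals=animals, unit=Unit.volume_mm3)


@pytest.fixture
def noisy_cohort():
    from tgrkit.simulate import daskalakis_preset, simulate_cohort

    return simulate_cohort(daskalakis_preset(seed=42))
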