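import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from covgrad.effect_sizes import PopulationObservation


def make_experiment(
    means: dict[tuple[str, float], float],
    positions: dict[str, float],
    homes: dict[str, float],
    sd: float = 1.0,
    n: int = 20,
    **meta,
) -> list[PopulationObservation]:
    """Build an observation list from a (population, treatment) -> mean map."""
    defaults = dict(study_id="s1", experiment_id="e1", trait="growth",
                    species="sp1")
    defaults.update(meta)
    return [
        PopulationObservation(
            population_id=pid,
            gradient_position=positions[pid],
            treatment_level=t,
            mean=m,
            sd=sd,
            n=n,
            is_home=(homes.get(pid) == t),
            **defaults,
        )
        for (pid, t), m in means.items()
    ]


@pytest.fixture
def counter_experiment():
    """Countergradient: north (high position) genetically larger, homes at
    the trait-lowering treatment."""
    return make_experiment(
        means={("lo", 0.0): 0.0, ("lo", 1.0): 1.0,
               ("hi", 0.0): 2.0, ("hi", 1.0): 3.0},
        positions={"lo": 10.0, "hi": 50.0},
        homes={"lo": 1.0, "hi": 0.0},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
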