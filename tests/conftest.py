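import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small two-species simulated dataset written to disk once per session."""
    from retrofam.simulate import (
        AgeComponent,
        AgeMixture,
        ChromosomePlan,
        FamilyPlan,
        GenePlan,
        SimulationConfig,
        SpeciesPlan,
        simulate,
    )

    old = AgeMixture(components=(AgeComponent(1.0, 28.0, 6.0),))
    cfg = SimulationConfig(
        seed=42,
        species=[
            SpeciesPlan(
                "dip1",
                [ChromosomePlan("c1", 800_000), ChromosomePlan("c2", 800_000)],
            ),
            SpeciesPlan(
                "tet1",
                [
                    ChromosomePlan("A01", 800_000, "A"),
                    ChromosomePlan("D01", 800_000, "D"),
                ],
            ),
        ],
        families=[
            FamilyPlan(
                "RLGy_0001", 2500, {"dip1": 40, "tet1": 80},
                subgenome_bias=0.9, min_remnant_fraction=0.15, age=old,
            ),
            FamilyPlan(
                "RLCo_0002", 2000, {"dip1": 20, "tet1": 20},
                superfamily="Copia", min_remnant_fraction=0.15, age=old,
            ),
            FamilyPlan(
                "RLGy_0003", 2000, {"dip1": 15},
                min_remnant_fraction=0.15, age=old,
            ),
        ],
        genes=GenePlan(per_chromosome=15),
    )
    dataset = simulate(cfg)
    outdir = tmp_path_factory.mktemp("small_dataset")
    dataset.write(outdir)
    return cfg, dataset, outdir
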