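import pytest

from ahlkit import masslib, simulate


@pytest.fixture(scope="session")
def library():
    return masslib.build_library()


@pytest.fixture(scope="session")
def ms_result():
    """A small, noiseless sample/control pair with three planted AHLs."""
    spec = simulate.MsRunSpec(
        planted=(
            simulate.PlantedAHL("C8-HSL", rt=10.0),
            simulate.PlantedAHL("C10-HSL", rt=14.0),
            simulate.PlantedAHL("Oxo-C12-HSL", rt=18.0),
        ),
        background=(
            simulate.BackgroundIon(279.2, rt=8.0),
            simulate.BackgroundIon(391.3, rt=12.0),
        ),
        rt_min=0.0,
        rt_max=20.0,
        seed=42,
    )
    return simulate.make_ms_run(spec)


@pytest.fixture(scope="session")
def cohort():
    """A small genome-mining cohort with duplicated species."""
    return simulate.make_cohort(
        simulate.CohortSpec(n_species=40, duplicate_fraction=0.25, seed=42)
    )
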