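import pytest
from hypothesis import HealthCheck, settings

from protopep import (
    PlantedEffect,
    SimConfig,
    apply_fusion,
    build_screen_dataset,
    enumerate_library,
    layout_array,
    load_protocodes,
    simulate_screen,
)
from protopep.codes import SGCTable

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocodes():
    return load_protocodes()


@pytest.fixture(scope="session")
def sgc():
    return SGCTable.standard()


@pytest.fixture(scope="session")
def fusion(protocodes, sgc):
    return apply_fusion(protocodes, sgc)


@pytest.fixture(scope="session")
def small_gc_screen():
    """Small synthetic GC-like screen: full 4-letter 4-mer library, 2 copies,
    a planted per-presence PP effect in the C channel, mild lognormal noise."""
    lib = enumerate_library(("G", "P", "A", "R"), 4, "GC-dominant", copies=2)
    design = layout_array([lib], seed=11)
    config = SimConfig(
        design=design,
        baselines={"C12": 100.0, "G12": 50.0},
        effects=[PlantedEffect("PP", "C12", 2.0, mode="per_presence")],
        sigma=0.2,
        seed=11,
    )
    table = simulate_screen(config)
    return build_screen_dataset(design, table)
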