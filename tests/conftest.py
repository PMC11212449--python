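import numpy as np
import pytest

from dronemap.pipeline import PipelineResult, run_pipeline
from dronemap.simulate import SimConfig


@pytest.fixture(scope="session")
def default_result() -> PipelineResult:
    """Full pipeline run at the default study conditions (seed 42)."""
    return run_pipeline(SimConfig(seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_628)


def tiny_config(**overrides) -> SimConfig:
    """Small, fast simulation config for unit tests."""
    defaults = dict(
        seed=7,
        chromosome_lengths=(2_000_000,),
        snp_density=0.0005,
        colonies=((8, 2),),
        nco_rate=0.5,
        n_371_total=4,
        n_371_selected=4,
        n_91_total=0,
        n_91_selected=0,
        boundary_arrays_per_chromosome=2,
        withhold_assignment_fraction=0.0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
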