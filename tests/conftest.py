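import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def toy_bipartite():
    """Small compound-target network with a hub gene and a private gene."""
    from netpharm.model_io import BipartiteNetwork

    return BipartiteNetwork(
        [
            ("c1", "G1"), ("c2", "G1"), ("c3", "G1"),
            ("c1", "G2"), ("c2", "G3"), ("c4", "G4"),
        ]
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One fully generated synthetic dataset (seed 1), shared read-only."""
    from netpharm.synthetic import SimulationConfig, simulate_all

    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the seed-1 synthetic dataset."""
    from netpharm.pipeline import PipelineConfig, run_screen

    return run_screen(PipelineConfig(simulate=True, seed=1), write=False)
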