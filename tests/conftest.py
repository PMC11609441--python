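import pytest
from hypothesis import HealthCheck, settings

from isprm import panel as panel_mod
from isprm import pipeline

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel9():
    """The default 9-protein / 18-pair panel."""
    return panel_mod.default_panel()


@pytest.fixture(scope="session")
def one_run(panel9):
    """One triggered run under default study conditions, scans kept."""
    return pipeline.simulate_experiment(
        n_samples=1, seed=0, panel=panel9, keep_runs=True
    )


@pytest.fixture(scope="session")
def cohort42(panel9):
    """The 42-sample default-noise cohort used for end-to-end checks."""
    return pipeline.simulate_experiment(n_samples=42, seed=0, panel=panel9)
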