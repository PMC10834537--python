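import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_bundle():
    from adrscreen.simulate import generate_demo

    return generate_demo(0)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demo pipeline run shared across tests."""
    from adrscreen.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("demo_run")
    return run_pipeline({"seed": 0}, out)
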