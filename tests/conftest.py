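import pytest
from hypothesis import HealthCheck, settings

from lhseg.benchmark import suite_benchmark
from lhseg.pipeline import default_model
from lhseg.synthetic import SceneSpec, generate_benchmark_suite, generate_scene

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scene3():
    """One default scene with its ground truth."""
    return generate_scene(SceneSpec(seed=3))


@pytest.fixture(scope="session")
def touching_scene():
    """Scene containing a cell placed face-adjacent to an osteoblast."""
    return generate_scene(SceneSpec(seed=7, touching_pair=True))


@pytest.fixture(scope="session")
def suite():
    """The 10-scene acquisition-variability benchmark suite."""
    return generate_benchmark_suite(seed=1)


@pytest.fixture(scope="session")
def suite_results(suite):
    """(segmentation Jaccard table, distance match table) for the suite,
    sharing one segmentation pass."""
    return suite_benchmark(suite)


@pytest.fixture(scope="session")
def model():
    return default_model(0)
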