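import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from fishnet import (  # noqa: E402
    FixtureSpec,
    GeneScoreTable,
    PermutationConfig,
    SignalModel,
    generate,
)


@pytest.fixture
def tiny_scores() -> GeneScoreTable:
    return GeneScoreTable(
        entries={"g1": 0.01, "g2": 0.5, "g3": 0.9, "g4": 0.2, "g5": 0.7}
    )


@pytest.fixture
def planted_fixture():
    """One 1000-gene fixture with a planted low-P module and aligned term."""
    spec = FixtureSpec(
        planted_modules=((0, SignalModel("beta", 0.1, 1.0)),), seed=7
    )
    scores, modules, annotations, truth = generate(spec)
    return scores, modules, annotations, truth


@pytest.fixture
def planted_config() -> PermutationConfig:
    return PermutationConfig(seed=7)


def planted_spec(seed: int, module_size: int | None = None) -> FixtureSpec:
    return FixtureSpec(
        planted_modules=((0, SignalModel("beta", 0.1, 1.0)),), seed=seed
    )
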