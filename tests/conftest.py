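import numpy as np
import pytest

from movecomp import synthdata


def single_group_config(group: str = "obesity I", **kwargs) -> synthdata.GeneratorConfig:
    """Config drawing every participant from one weight-status group."""
    props = [1.0 if g == group else 0.0 for g in synthdata.GROUPS]
    kwargs.setdefault("group_proportions", props)
    return synthdata.GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def cohort_df():
    """Default 93-participant cohort as a participant table."""
    cfg = synthdata.GeneratorConfig(n_participants=93, seed=11)
    return synthdata.cohort_to_frame(synthdata.generate_cohort(cfg))


@pytest.fixture(scope="session")
def big_cohort_df():
    """Large cohort for distributional checks."""
    cfg = synthdata.GeneratorConfig(n_participants=1000, seed=12)
    return synthdata.cohort_to_frame(synthdata.generate_cohort(cfg))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
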