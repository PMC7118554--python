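import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small deterministic cohort with one planted transient edge."""
    from dfcpipe.simulate import CohortSpec, EffectEdge, generate_cohort

    spec = CohortSpec(
        n_patients=12, n_controls=12, n_regions=10, seed=7,
        effect_edges=[EffectEdge(1, 4, 60, 140, 0.6)],
    )
    subjects, truth = generate_cohort(spec)
    return spec, subjects, truth
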