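import numpy as np
import pytest

from multifc.measures import BoldMatrix
from multifc.synthetic import CohortSpec, SyntheticSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_bold(rng):
    """Random 64 x 6 BOLD-like matrix at TR = 2.6 s."""
    return BoldMatrix(
        values=rng.standard_normal((64, 6)),
        sampling_interval=2.6,
        region_ids=tuple(f"r{i}" for i in range(6)),
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Miniature planted cohort shared across pipeline tests:
    6 + 6 subjects, 12 regions in 3 networks, t = 96."""
    spec = SyntheticSpec(
        network_sizes=(4, 4, 4), within_strength=0.6, t=96, seed=42
    )
    cohort_spec = CohortSpec(
        n_group_a=6,
        n_group_b=6,
        effect_networks=("net01",),
        effect_delta=0.3,
        behavior_network="net02",
        behavior_noise_sd=0.0,
        seed=42,
    )
    return generate_cohort(spec, cohort_spec)
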