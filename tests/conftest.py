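import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from idiseg.core import DEFAULT_BRACKETS, TractTable

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(counts, city_id="c1", region="se", brackets=None):
    counts = np.asarray(counts, dtype=np.int64)
    brackets = brackets or DEFAULT_BRACKETS[: counts.shape[1]]
    # Close the last bracket's upper bound only if the default set was trimmed.
    return TractTable(
        city_id=city_id,
        region=region,
        tract_ids=tuple(f"t{i}" for i in range(counts.shape[0])),
        brackets=tuple(brackets),
        counts=counts,
    )


@pytest.fixture
def two_tract_table():
    """Brackets 0-1, 1-2, 2-3 with the worked counts used across tests."""
    return make_table(
        [[5, 3, 2], [5, 3, 2]],
        brackets=((0.0, 1.0), (1.0, 2.0), (2.0, 3.0)),
    )
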