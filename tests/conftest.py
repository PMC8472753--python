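import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def random_kernel_factory(rng):
    from actifilt.types import ScoringKernel

    def make(n_future=None, n_past=None, scale=None, bias=0.0):
        nf = int(rng.integers(0, 5)) if n_future is None else n_future
        npp = int(rng.integers(0, 6)) if n_past is None else n_past
        coeffs = rng.normal(size=nf + npp + 1)
        if not np.any(coeffs != 0):
            coeffs[0] = 1.0
        return ScoringKernel(
            coefficients=coeffs,
            future_span=nf,
            past_span=npp,
            scale=float(rng.uniform(0.5, 2.0)) if scale is None else scale,
            bias=bias,
            threshold=0.0,
            algorithm_name="random",
        )

    return make
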