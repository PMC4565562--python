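import numpy as np
import pytest

from grnfit import (
    GRNModelParameters,
    RateLaw,
    builtin_topology,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_params(rng, n=4, rate_law=RateLaw.HILL, omega_scale=2.0, topology=None):
    """Random valid parameter set for either rate law."""
    if topology is not None:
        omega = topology.sign * rng.uniform(0.2, omega_scale, (n, n))
    else:
        omega = rng.uniform(-omega_scale, omega_scale, (n, n))
        omega[rng.random((n, n)) < 0.3] = 0.0
    kw = dict(
        alpha=rng.uniform(0.5, 2.0, n),
        beta=rng.uniform(0.5, 2.0, n),
        omega=omega,
    )
    if RateLaw.coerce(rate_law) is RateLaw.HILL:
        return GRNModelParameters(
            rate_law=RateLaw.HILL,
            gamma=rng.uniform(0.3, 1.5, n),
            hill_n=rng.uniform(0.5, 4.0, (n, n)),
            **kw,
        )
    return GRNModelParameters(rate_law=RateLaw.ANN, gamma=rng.uniform(-1, 1, n), **kw)


@pytest.fixture
def topology_a():
    return builtin_topology("A")
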