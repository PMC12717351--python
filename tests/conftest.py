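"""Shared fixtures: the hand-derived math fixture, the packaged baseline,
and seeded random parameter sets."""

import pytest

from soceeo import io
from soceeo.params import ToyModelParams


@pytest.fixture(scope="session")
def fix_params() -> ToyModelParams:
    """Hand-evaluable parameter set.

    Every quantity at this fixture can be computed on paper:
    steady-state SOC is 1 at m_e = 4, the instantaneous optimum at
    x_s = 1 is 4 with mu = 8, the resident uptake is G = 16 and the
    emergent mortality 8, and with c0 = 0.5 the singular strategy sits
    exactly at 4 with invasion-fitness curvature -1/4.
    """
    return ToyModelParams(
        alpha=1.0, beta=0.5, eps_e=2.0, d_e=1.0, input_rate=17.0,
        k_u=1.0, ell_s=1.0, v_u=32.0, y=0.5, c0=0.5, d_fixed=8.0,
    )


@pytest.fixture(scope="session")
def baseline() -> ToyModelParams:
    return io.baseline_params()


@pytest.fixture(scope="session")
def random_fixtures() -> list[ToyModelParams]:
    """30 seeded feasible parameter sets for unit-level property checks."""
    return io.generate_fixtures(io.FixtureConfig(seed=1234, n_sets=30))
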