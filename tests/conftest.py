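"""Shared fixtures: schemes, canonical parameters, liver-realistic draws."""

import numpy as np
import pytest

from ivimyi import (
    BiexParams,
    DecaySignal,
    NoiseModel,
    TriexParams,
    biex_signal,
    generate_decay,
    table1_scheme,
    triex_signal,
)

#: canonical healthy-liver two-compartment parameters used throughout
CANONICAL_BIEX = BiexParams(pf=0.2, d_slow=1e-3, d_fast=50e-3)

#: canonical three-compartment truth (fractions from the healthy-liver means;
#: the very fast pool decays essentially completely by b = 2 s/mm^2)
CANONICAL_TRIEX = TriexParams(
    f_slow=0.71, f_fast=0.15, f_vfast=0.14,
    d_slow=1e-3, d_fast=50e-3, d_vfast=2.0,
)


def draw_biex_params(rng) -> BiexParams:
    """One draw from a healthy-liver two-compartment distribution.

    Centred on the cohort means (pf ~ total perfusion fraction 0.286,
    d_slow 1.0e-3, d_fast 55e-3 mm^2/s) with 15% relative spread, truncated
    to physically sensible ranges.
    """
    pf = float(np.clip(rng.normal(0.286, 0.043), 0.10, 0.45))
    d_slow = float(np.clip(rng.normal(1.0e-3, 0.15e-3), 5e-4, 2e-3))
    d_fast = float(np.clip(rng.normal(55e-3, 8.25e-3), 25e-3, 0.12))
    return BiexParams(pf=pf, d_slow=d_slow, d_fast=d_fast)


@pytest.fixture(scope="session")
def scheme():
    return table1_scheme()


@pytest.fixture(scope="session")
def biex_params():
    return CANONICAL_BIEX


@pytest.fixture(scope="session")
def triex_params():
    return CANONICAL_TRIEX


@pytest.fixture(scope="session")
def biex_noiseless(scheme):
    """Exact two-compartment decay on the 16-b scheme."""
    return DecaySignal(scheme, biex_signal(CANONICAL_BIEX, 1.0, scheme.b_values))


@pytest.fixture(scope="session")
def triex_noiseless(scheme):
    """Exact three-compartment decay on the 16-b scheme."""
    return DecaySignal(scheme, triex_signal(CANONICAL_TRIEX, 1.0, scheme.b_values))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
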