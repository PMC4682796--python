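"""Shared fixtures: small grids, toy networks, and one grown tumor state.

The grown day-18 state at 64x64 resolution is expensive (~5 s) and is shared
session-wide by the treatment/efficacy/acceptance tests; each test that
mutates it must work on ``state.copy()``.
"""

from __future__ import annotations

import numpy as np
import pytest

import nanovasc as nv
from nanovasc.efficacy import grow, initialize_state


@pytest.fixture(scope="session")
def grid64() -> nv.GridSpec:
    return nv.GridSpec(domain_size_mm=2.0, n_cells=64, length_scale_mm=0.2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def scenario64(grid64) -> nv.TreatmentScenario:
    return nv.TreatmentScenario(grid=grid64)


@pytest.fixture(scope="session")
def grown_state(scenario64):
    """Day-18 vascularized tumor at test resolution (shared, copy before use)."""
    st = initialize_state(scenario64)
    grow(st)
    return st


@pytest.fixture(scope="session")
def injected_state_100nm_hi(grown_state):
    """Grown state injected with the reference 100-nm, alpha=1e12 formulation."""
    from nanovasc.efficacy import inject

    st = grown_state.copy()
    st.scenario.formulation = nv.NPFormulation(diameter_m=100e-9, alpha_neo=1e12)
    inject(st)
    return st
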