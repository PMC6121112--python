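"""Shared fixtures: parameter sets, small grids, and one real rotor episode.

The stable-rotor episode is session-scoped because it takes tens of seconds;
several analysis tests interrogate the same record.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from rotoremu.fk import FKParams

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")
from rotoremu.protocol import EpisodeConfig, run_s1s2_episode
from rotoremu.solver import GridSpec, smoke_grid


@pytest.fixture(scope="session")
def base_params() -> FKParams:
    return FKParams()


@pytest.fixture(scope="session")
def tiny_grid() -> GridSpec:
    """Very small 2D domain for plumbing tests (dx just under 0.06 cm)."""
    return GridSpec(Lx=1.875, Ly=1.875, nx=32, ny=32)


@pytest.fixture(scope="session")
def stable_rotor_record(base_params):
    """One episode that sustains a rotor for the whole simulated window.

    Repolarization is strengthened (g_so +20%) so the excitation wavelength
    fits the 7.5 cm domain and the induced rotor persists.
    """
    p = base_params.replace(g_so=base_params.g_so * 1.2)
    grid = GridSpec(Lx=7.5, Ly=7.5, nx=128, ny=128)
    cfg = EpisodeConfig(post_induction_T=2000.0)
    rec = run_s1s2_episode(p, grid, cfg)
    return rec, grid, cfg


@pytest.fixture(scope="session")
def smoke_episode_record(base_params):
    """Quick base-parameter episode on the small domain (rotor dies early)."""
    grid = smoke_grid()
    cfg = EpisodeConfig(post_induction_T=1000.0)
    rec = run_s1s2_episode(base_params, grid, cfg)
    return rec, grid, cfg


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
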