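"""Shared fixtures: small synthetic worlds exercised by many tests.

Worlds are generated once per session; tests must not mutate them.
"""

from __future__ import annotations

import pytest

from cropgrid.pipeline import run_annual_pipeline, run_monthly_pipeline
from cropgrid.synthetic_data import WorldConfig, generate_world


@pytest.fixture(scope="session")
def world():
    """Full-featured world without cap stress: every special-case
    structure present, no cell near the 99% budget."""
    cfg = WorldConfig(
        seed=7,
        n_countries=4,
        sudan_split=True,
        no_data_island=True,
        disputed_area=True,
        multi_subcrop=True,
        wrap_season=False,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def annual(world):
    result, _ = run_annual_pipeline(world)
    return result


@pytest.fixture(scope="session")
def monthly(world, annual):
    result, _ = run_monthly_pipeline(world, annual)
    return result


@pytest.fixture(scope="session")
def cap_world():
    """World with one deliberately overfilled cell."""
    return generate_world(WorldConfig(seed=11, cap_stress=True))


@pytest.fixture(scope="session")
def cap_annual(cap_world):
    result, _ = run_annual_pipeline(cap_world)
    return result
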