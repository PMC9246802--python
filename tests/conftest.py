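"""Shared fixtures: physiologies and memoised steady-state runs.

The steady-state simulations are the expensive part of the suite, so a
session-scoped cache hands the same profile to every test that needs it.
"""

from __future__ import annotations

import pytest

from cnspk.drugs import load_drug
from cnspk.physiology import default_physiology
from cnspk.workflow import population_physiologies, steady_state_run


@pytest.fixture(scope="session")
def chy():
    return default_physiology()


@pytest.fixture(scope="session")
def pops():
    return population_physiologies()


@pytest.fixture(scope="session")
def ss_profile(pops):
    """Memoised steady-state interdose profiles: ss_profile(drug, pop)."""
    cache: dict[tuple[str, str], object] = {}

    def get(drug: str, population: str = "AD"):
        key = (drug, population.upper())
        if key not in cache:
            cache[key] = steady_state_run(
                load_drug(drug), population, populations=pops
            )
        return cache[key]

    return get


@pytest.fixture(scope="session")
def semagacestat_ad(ss_profile):
    """The chronic 140 mg daily semagacestat simulation in mild AD."""
    return ss_profile("semagacestat", "AD")
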