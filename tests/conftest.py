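"""Shared fixtures.

Scenario results are session-scoped: each published-figure experiment is
simulated once and shared between the scenario, intervention and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from pkclife import build_default_network, default_parameterization
from pkclife.scenarios import (
    run_block_dephosphorylation,
    run_dose_response,
    run_duration_sweep,
    run_hsp70_sweep,
    run_phlpp_block_sweep,
    run_second_synthesis_pulse,
    run_sequential_pulses,
)
from pkclife.sensitivity import sensitivity_map


@pytest.fixture(scope="session")
def params():
    return default_parameterization()


@pytest.fixture(scope="session")
def network():
    return build_default_network()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230414)


@pytest.fixture(scope="session")
def fig2_result(params):
    return run_dose_response(params)


@pytest.fixture(scope="session")
def fig3_result(params):
    return run_duration_sweep(params)


@pytest.fixture(scope="session")
def fig4_result(params):
    return run_block_dephosphorylation(params)


@pytest.fixture(scope="session")
def fig5_result(params):
    return run_sequential_pulses(params)


@pytest.fixture(scope="session")
def fig6_result(params):
    return run_hsp70_sweep(params)


@pytest.fixture(scope="session")
def fig7_result(params):
    return run_phlpp_block_sweep(params)


@pytest.fixture(scope="session")
def s7_result(params):
    return run_second_synthesis_pulse(params)


@pytest.fixture(scope="session")
def sensitivity_table(params):
    return sensitivity_map(params)
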