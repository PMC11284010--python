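"""Shared fixtures: simulated fields reused across test modules.

Simulations run once per session at the budget (coarse) resolution; tests
that need a field at periodic steady state use the three-cycle variants
(the slow LOW flows have not fully washed out after two 1 s cycles).
"""

from dataclasses import replace

import pytest
from hypothesis import settings

import coromix as cm
from coromix.grid import COARSE

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def _med15(catheter, bench=False):
    return [
        p
        for p in cm.cfd_combinations(catheter, bench=bench)
        if p.coronary_flow_mean == 150
    ][0]


@pytest.fixture(scope="session")
def side_med15_field():
    return cm.simulate(_med15(cm.CatheterType.SIDE_HOLE), resolution=COARSE)


@pytest.fixture(scope="session")
def end_med15_field():
    return cm.simulate(_med15(cm.CatheterType.END_HOLE), resolution=COARSE)


@pytest.fixture(scope="session")
def side_med15_bench_field():
    return cm.simulate(_med15(cm.CatheterType.SIDE_HOLE, bench=True), resolution=COARSE)


@pytest.fixture(scope="session")
def end_med15_bench_field():
    return cm.simulate(_med15(cm.CatheterType.END_HOLE, bench=True), resolution=COARSE)


@pytest.fixture(scope="session")
def steady_cfd_fields():
    """All 8 simulated combinations, run to periodic steady state."""
    res = replace(COARSE, n_cycles=3)
    return {p.label: cm.simulate(p, resolution=res) for p in cm.cfd_combinations()}
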