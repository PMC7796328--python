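"""Shared fixtures: simulated recordings reused across the suite.

Simulations run at the default acquisition conditions (700 events/s,
protocol-length recordings), so the expensive ones are session-scoped
and shared rather than regenerated per test.
"""

import numpy as np
import pytest

from tlfc.fcs_io import EventTable
from tlfc.synthetic_data import (
    SimConfig,
    simulate_ca_run,
    simulate_em_run,
    simulate_ph_run,
)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def em_run_65(sim_config):
    """One Em recording with true resting potential −65 mV."""
    events, truth = simulate_em_run(sim_config, -65.0, seed=42)
    return events, truth


@pytest.fixture(scope="session")
def em_pair(sim_config):
    """NC/CAP Em pair with a −11 mV capacitation hyperpolarization."""
    nc, _ = simulate_em_run(sim_config, -60.0, seed=1001)
    cap, _ = simulate_em_run(sim_config, -71.0, seed=1002)
    return nc, cap


@pytest.fixture(scope="session")
def ph_run_676(sim_config):
    """One pHi determination (HTF + calibration aliquot) at true pHi 6.76."""
    htf, cal, truth = simulate_ph_run(sim_config, 6.76, seed=7)
    return htf, cal, truth


@pytest.fixture(scope="session")
def ph_pair(sim_config):
    """NC/CAP pHi recordings with a +0.36 unit alkalinization."""
    nc_htf, nc_cal, _ = simulate_ph_run(sim_config, 6.58, seed=2001)
    cap_htf, cap_cal, _ = simulate_ph_run(sim_config, 6.94, seed=2002)
    return nc_htf, nc_cal, cap_htf, cap_cal


@pytest.fixture(scope="session")
def ca_pair(sim_config):
    """NC/CAP progesterone-response pair with peaks 0.88 and 1.90."""
    nc, cap, truth = simulate_ca_run(sim_config, 0.88, 1.90, seed=5)
    return nc, cap, truth


def make_events(time_s, **channels) -> EventTable:
    """Small hand-built tables for gate/trace mechanics tests."""
    n = len(time_s)
    defaults = dict(
        fsc_a=np.full(n, 1e5),
        fsc_h=np.full(n, 9e4),
        ssc_a=np.full(n, 5e4),
        fl1_a=np.full(n, 1e4),
        fl4_a=np.full(n, 1e5),
    )
    defaults.update(channels)
    return EventTable.from_arrays(np.asarray(time_s, dtype=float), **defaults)
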