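import numpy as np
import pytest

from nosco import core
from nosco.simulate import (
    make_scenario,
    simulate_nosco_dataset,
    simulate_reference_fid,
)


@pytest.fixture(scope="session")
def weak_noiseless():
    """Noiseless 'weak' scenario with its pseudo-3D dataset and reference."""
    scen = make_scenario("weak", seed=7, snr=np.inf)
    data = simulate_nosco_dataset(
        scen.peaks, scen.acq, scen.scheme, scen.schedule_set, scen.binding
    )
    ref = simulate_reference_fid(scen.peaks, scen.acq)
    return scen, data, ref


@pytest.fixture(scope="session")
def single_peak_problem():
    """Noiseless single-peak refocusing problem from the weak scenario."""
    scen = make_scenario("weak", seed=7, snr=np.inf)
    peak = scen.peaks[0]
    data = simulate_nosco_dataset(
        [peak], scen.acq, scen.scheme, scen.schedule_set, scen.binding
    )
    ref = simulate_reference_fid([peak], scen.acq)
    problem = core.make_problem(
        data, ref, *scen.windows[peak.label], scen.bounds, window=None
    )
    return scen, peak, problem
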