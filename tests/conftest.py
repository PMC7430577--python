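"""Shared fixtures: expensive steady-state runs are session-scoped."""

import pytest

from splitvent import (LungRC, Network, PatientProfile, ResistorSpec,
                       VentilatorSettings, predict_pair, two_patient_topology)
from splitvent.metrics import tidal_volume_per_cycle


BENCH_SETTINGS = dict(pip=20.0, peep=5.0, ie_ratio=(1.0, 2.0))


@pytest.fixture(scope="session")
def fig4_recommendation():
    """Benchtop validation pairing: compliances 18 vs 35 ml/cmH2O, PIP 20,
    PEEP 5, RR 20, I:E 1:2, ETT 7.5 mm, resistor candidates 3.0-5.0 mm."""
    settings = VentilatorSettings(mode="PC", respiratory_rate=20.0,
                                  **BENCH_SETTINGS)
    return predict_pair(PatientProfile(compliance=18.0),
                        PatientProfile(compliance=35.0),
                        settings, resistor_options=[3.0, 3.5, 4.0, 4.5, 5.0])


@pytest.fixture(scope="session")
def rr_series_tvs():
    """Steady-state tidal volumes of the 18/35 pairing (no resistor) at
    RR 15, 20, 25, 30 with fixed I:E 1:2; {rr: (tv_A, tv_B)}."""
    out = {}
    topo = two_patient_topology(LungRC(18.0), LungRC(35.0))
    for rr in (15.0, 20.0, 25.0, 30.0):
        net = Network(topo, VentilatorSettings(mode="PC", respiratory_rate=rr,
                                               **BENCH_SETTINGS))
        wf, _ = net.run_to_steady_state()
        out[rr] = (tidal_volume_per_cycle(wf, "A")[-1],
                   tidal_volume_per_cycle(wf, "B")[-1])
    return out


@pytest.fixture(scope="session")
def fig5_run():
    """Compliances 30 vs 75 ml/cmH2O with a 4 mm resistor on limb B."""
    topo = two_patient_topology(LungRC(30.0), LungRC(75.0),
                                resistor=ResistorSpec(4.0), resistor_limb="B")
    net = Network(topo, VentilatorSettings(mode="PC", respiratory_rate=20.0,
                                           **BENCH_SETTINGS))
    wf, used = net.run_to_steady_state()
    return wf, used


@pytest.fixture(scope="session")
def symmetric_run():
    """Identical limbs and lungs, no resistor."""
    topo = two_patient_topology(LungRC(30.0), LungRC(30.0))
    net = Network(topo, VentilatorSettings(mode="PC", respiratory_rate=20.0,
                                           **BENCH_SETTINGS))
    wf, used = net.run_to_steady_state()
    return wf, used


def steady_tvs(topology, settings, **kwargs):
    net = Network(topology, settings)
    wf, _ = net.run_to_steady_state(**kwargs)
    tv = {p: tidal_volume_per_cycle(wf, p)[-1] for p in wf.patients}
    return tv, wf
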