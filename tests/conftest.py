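import numpy as np
import pytest

from hergvar.synthetic import (PhaseSpec, SweepSimConfig, default_study_design,
                               simulate_cell_recording, simulate_study)


@pytest.fixture(scope="session")
def study_records():
    """One realisation of the default 145-experiment five-lab study."""
    records, truth = simulate_study(default_study_design(seed=7))
    return records, truth


@pytest.fixture(scope="session")
def coarse_protocol():
    # 1 ms sampling keeps per-test sweep simulation light
    from hergvar.protocol import StepRampProtocol
    return StepRampProtocol(sampling_interval_s=1e-3)


def make_cell(protocol, *, herg=1000.0, leak=0.0, rundown=0.0, noise=0.0,
              conc=1e-8, ic50=1e-8, nH=1.0, n_vehicle=6, n_drug=6, n_e4031=4,
              seed=11):
    phases = [PhaseSpec("vehicle", float("nan"), n_vehicle)]
    if n_drug:
        phases.append(PhaseSpec("drug", conc, n_drug))
    if n_e4031:
        phases.append(PhaseSpec("e4031", float("nan"), n_e4031))
    cfg = SweepSimConfig(phases=tuple(phases), protocol=protocol,
                         herg_amplitude_pA=herg, leak_conductance_nS=leak,
                         rundown_per_sweep=rundown, noise_sd_pA=noise,
                         drug_ic50_molar=ic50, drug_nH=nH)
    return simulate_cell_recording(cfg, seed=seed)


@pytest.fixture(scope="session")
def noise_free_cell(coarse_protocol):
    return make_cell(coarse_protocol, leak=2.0)
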