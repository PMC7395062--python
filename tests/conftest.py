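import numpy as np
import pytest
from hypothesis import settings

from mitoscreen.panel import CompoundRecord, ladder_preset, load_panel
from mitoscreen.simulate import KineticWellTrace

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def intact_series():
    return ladder_preset("intact_default")


@pytest.fixture(scope="session")
def extended_series():
    return ladder_preset("permeabilized_extended")


def make_trace(phase_arrays, ecar_arrays=None, compound="test", conc=1e-6,
               well="A1", plate_id="p1"):
    """Build a trace from {phase: [ocr values]} in listed order."""
    labels, ocr = [], []
    for phase, values in phase_arrays.items():
        labels.extend([phase] * len(values))
        ocr.extend(values)
    if ecar_arrays is None:
        ecar = [1.0] * len(ocr)
    else:
        ecar = [v for phase in phase_arrays for v in ecar_arrays[phase]]
    times = np.arange(1.0, len(ocr) + 1)
    return KineticWellTrace(
        plate_id=plate_id, well=well, compound=compound, conc=conc,
        phase_labels=tuple(labels), times=times,
        ocr=np.asarray(ocr, dtype=float), ecar=np.asarray(ecar, dtype=float),
    )


def make_compound(name="probe", target="CI", mechanism="inhibitor",
                  potency=-6.0, slope=2.0):
    return CompoundRecord(
        name=name, target_complex=target, cas="0-00-0", mol_weight=300.0,
        clogp=3.0, subset_flag=False, sim_mechanism=mechanism,
        sim_potency_log10M=potency, sim_hill_slope=slope,
    )


@pytest.fixture(scope="session")
def pipeline_result():
    """Full simulated-panel pipeline, shared across integration tests."""
    from mitoscreen.integrate import run_pipeline

    return run_pipeline(seed=0, cv=0.03)
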