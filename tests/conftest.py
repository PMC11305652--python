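import pytest

from sidexp import (
    AcidKind,
    BloodGas,
    ElectrolytePanel,
    Group,
    ProteinPanel,
    TonometrySeries,
    TonometryStep,
)
from sidexp.datasets import load_table1, load_table2, load_table3
from sidexp.params import BufferParams
from sidexp.simulate import NoiseModel, SimulationScenario, simulate_series

EXP3_LOADS = ((AcidKind.none, 0.0), (AcidKind.lactic, 7.5),
              (AcidKind.hcl, 7.5), (AcidKind.lactic, 15.0),
              (AcidKind.hcl, 15.0))


@pytest.fixture(scope="session")
def params() -> BufferParams:
    return BufferParams()


@pytest.fixture(scope="session")
def table1():
    return {s.subject_id: s for s in load_table1()}


@pytest.fixture(scope="session")
def table2():
    return {s.subject_id: s for s in load_table2()}


@pytest.fixture(scope="session")
def table3():
    return load_table3()


@pytest.fixture(scope="session")
def exp3_noiseless():
    """Acid-loading scenario with noise switched off: exact round trips."""
    scenario = SimulationScenario(group=Group.experiment3, n_subjects=4,
                                  seed=11, acid_loads=EXP3_LOADS,
                                  noise=NoiseModel.silent())
    return simulate_series(scenario)


@pytest.fixture(scope="session")
def exp3_noisy():
    """Acid-loading scenario at analyzer-grade noise, 10 subjects."""
    scenario = SimulationScenario(group=Group.experiment3, n_subjects=10,
                                  seed=23, acid_loads=EXP3_LOADS)
    return simulate_series(scenario)


def make_series(ph_hco3, subject="X", group=Group.healthy, albumin=4.8,
                hemoglobin=14.2, fco2_start=0.02, pco2=40.0,
                panel=None) -> TonometrySeries:
    """Minimal whole-blood series from (pH, HCO3) pairs, for unit tests.

    ``pco2`` may be a single value or one per step.
    """
    panel = panel or ElectrolytePanel(140, 4.0, 1.2, 2.0, 105, 1.5)
    pco2s = ([pco2] * len(ph_hco3) if isinstance(pco2, (int, float))
             else list(pco2))
    steps = [
        TonometryStep(fco2=fco2_start + 0.02 * i,
                      gas=BloodGas(ph=ph, pco2=pco2s[i], hco3=hco3),
                      electrolytes=panel)
        for i, (ph, hco3) in enumerate(ph_hco3)
    ]
    return TonometrySeries(subject_id=subject, group=group,
                           proteins=ProteinPanel(albumin, hemoglobin),
                           steps=tuple(steps))
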