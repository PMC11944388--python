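import numpy as np
import pytest

from pbbm import (
    DissolutionCondition,
    FormulationSpec,
    apixaban,
    apixaban_disposition,
    default_physiology,
    simulate_oral,
)


@pytest.fixture(scope="session")
def drug():
    return apixaban()


@pytest.fixture(scope="session")
def physiology():
    return default_physiology()


@pytest.fixture(scope="session")
def disposition():
    return apixaban_disposition()


@pytest.fixture(scope="session")
def qc_condition():
    return DissolutionCondition(medium="hcl_01n", volume_ml=900.0)


def _tablet(dose, d90, granulation="dry"):
    return FormulationSpec(
        dose_mg=dose, form="ir_tablet", granulation=granulation, d90_um=d90
    )


@pytest.fixture(scope="session")
def tablet_factory():
    return _tablet


@pytest.fixture(scope="session")
def oral_solution_2p5(drug, physiology, disposition):
    return simulate_oral(
        drug, FormulationSpec(dose_mg=2.5, form="solution"), physiology, disposition
    )


@pytest.fixture(scope="session")
def oral_tablet_2p5(drug, physiology, disposition):
    return simulate_oral(drug, _tablet(2.5, 83.0), physiology, disposition, z=31.0)


@pytest.fixture(scope="session")
def oral_tablet_20(drug, physiology, disposition):
    return simulate_oral(drug, _tablet(20.0, 83.0), physiology, disposition, z=31.0)


@pytest.fixture(scope="session")
def oral_tablet_25(drug, physiology, disposition):
    return simulate_oral(drug, _tablet(25.0, 83.0), physiology, disposition, z=31.0)


@pytest.fixture(scope="session")
def sweep_table(drug, physiology, disposition):
    """Full particle-size safe-space sweep, shared across BE/acceptance tests."""
    from pbbm import safe_space_sweep

    sizes = np.array([10.0, 25.0, 50.0, 83.0, 120.0, 160.0, 210.0])
    return safe_space_sweep(
        sizes, drug, physiology, disposition, dose_mg=5.0, granulation="dry", z=31.0
    )
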