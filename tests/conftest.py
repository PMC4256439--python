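import numpy as np
import pytest

from qpcrvar.quantify import StandardCurve
from qpcrvar.simulate import (
    IntraSDModel,
    SimulationDesign,
    simulate_copynumber_plate_pairs,
    simulate_deletion_measurements,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20140412)


@pytest.fixture
def curves():
    """Standard curves with realistic, deliberately unequal efficiencies."""
    return {
        "MT-ND1": StandardCurve("MT-ND1", slope=-3.32, intercept=34.0),
        "MT-ND4": StandardCurve("MT-ND4", slope=-3.45, intercept=35.2),
        "B2M": StandardCurve("B2M", slope=-3.38, intercept=36.1),
    }


@pytest.fixture
def noiseless_deletion_design():
    return SimulationDesign(
        samples={"A": 20.0, "D": 70.0},
        n_plates=3,
        k=24,
        sigma_inter=0.0,
        intra_model=IntraSDModel(a=0.0, b=0.0),
        seed=7,
    )


@pytest.fixture
def interplate_deletion_wells():
    """Noisy 6-sample, 3-plate, 24-well deletion dataset."""
    design = SimulationDesign(
        samples={"A": 20.0, "B": 22.5, "C": 25.0, "D": 70.0, "E": 75.0, "F": 80.0},
        n_plates=3,
        k=24,
        sigma_inter=0.485,
        seed=11,
    )
    return simulate_deletion_measurements(design)


@pytest.fixture
def copynumber_wells():
    """Noisy 5-sample, 4-pair, 12-well copy-number dataset."""
    design = SimulationDesign(
        samples={"S1": 1.0, "S2": 1.10, "S3": 1.25, "S4": 1.50, "S5": 1.9},
        n_plates=4,
        k=12,
        intra_model=IntraSDModel(mode="copynumber"),
        sigma_inter=0.0305,
        seed=13,
    )
    return simulate_copynumber_plate_pairs(design)
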