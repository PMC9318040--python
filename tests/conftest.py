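import numpy as np
import pytest

from melif.image import Geometry, T1Map
from melif.phantom import PhantomSpec, make_ground_truth, make_patient
from melif.scoring import PatientRecord


@pytest.fixture(scope="session")
def mean_patient() -> PatientRecord:
    """Patient at the published cohort means (1.7 m, 83 kg, 1513 mL)."""
    return PatientRecord(
        id="mean",
        sex="M",
        age_years=62.0,
        height_m=1.7,
        weight_kg=83.0,
        bilirubin_mg_dl=0.8,
        inr=1.0,
        creatinine_mg_dl=0.9,
        dialysis=False,
        liver_volume_ml=1513.0,
    )


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Fast 46^3 grid, 5 mm isotropic, no deformation."""
    return PhantomSpec(
        grid_shape=(46, 46, 46),
        voxel_spacing_mm=(5.0, 5.0, 5.0),
        uptake_mean=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec, mean_patient):
    return make_ground_truth(small_spec, mean_patient)


@pytest.fixture(scope="session")
def deformed_truth(mean_patient):
    """64^3 phantom with a 5 mm inter-phase deformation."""
    spec = PhantomSpec(uptake_mean=0.5, deformation_amplitude_mm=5.0, seed=7)
    return make_ground_truth(spec, mean_patient)


@pytest.fixture()
def unit_geometry():
    return Geometry.isotropic((8, 8, 8), 1.0)


@pytest.fixture()
def constant_t1(unit_geometry):
    return T1Map(np.full(unit_geometry.shape, 700.0), unit_geometry)
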