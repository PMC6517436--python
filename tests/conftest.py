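import numpy as np
import pytest

from imiomics.cohort import POPULATION_STATS, RESIDUAL_MASS_KG, SubjectRecord
from imiomics.grids import ImageGrid3D
from imiomics.phantom import build_reference_phantom


@pytest.fixture(scope="session")
def grid_small():
    return ImageGrid3D((32, 24, 64), (2.07, 2.07, 8.0))


@pytest.fixture(scope="session")
def grid_paperlike():
    return ImageGrid3D((48, 32, 96), (2.07, 2.07, 8.0))


@pytest.fixture(scope="session")
def phantom_small(grid_small):
    return build_reference_phantom(grid_small)


@pytest.fixture(scope="session")
def phantom_paperlike(grid_paperlike):
    return build_reference_phantom(grid_paperlike)


@pytest.fixture(scope="session")
def make_record():
    """Factory for subject records at controlled covariate z-scores."""

    def _make(sex="female", z_fat=0.0, z_lean=0.0, z_whr=0.0, rec_id="t0"):
        s = POPULATION_STATS[sex]
        fat = s["fat_mass"][0] + z_fat * s["fat_mass"][1]
        lean = s["lean_mass"][0] + z_lean * s["lean_mass"][1]
        whr = s["whr"][0] + z_whr * s["whr"][1]
        height = s["height"][0]
        weight = fat + lean + RESIDUAL_MASS_KG[sex]
        hip = 102.0
        return SubjectRecord(
            id=rec_id,
            sex=sex,
            height=height,
            weight=weight,
            bmi=weight / (height / 100.0) ** 2,
            fat_mass=fat,
            lean_mass=lean,
            waist=whr * hip,
            hip=hip,
            whr=whr,
        )

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
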