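from importlib import resources

import numpy as np
import pytest

from psoct import ScanGeometry, TEST_GEOMETRY
from psoct.dopu import RpeMask
from psoct.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    """Tiny raster for unit tests (1 x 1 mm, 32 A-scans x 8 B-scans)."""
    return ScanGeometry(
        width_mm=1.0, height_mm=1.0, n_ascans=32, n_bscans=8,
        n_depth=40, axial_step_um=10.0,
    )


@pytest.fixture(scope="session")
def downscaled_config() -> PipelineConfig:
    """Analysis profile for the down-sampled phantom geometry.

    The DOPU window scales with the sampling so its physical footprint
    roughly matches the full-resolution 9x9 default.
    """
    return PipelineConfig(dopu_window_z_px=3, dopu_window_x_px=3, seed=42)


def make_band_mask(geometry, top=20, thickness=5, extra=None) -> RpeMask:
    """Synthetic depolarizing mask: a flat band plus optional extra voxels."""
    mask = np.zeros(geometry.shape, dtype=bool)
    mask[:, :, top:top + thickness] = True
    if extra is not None:
        for b, a, z in extra:
            mask[b, a, z] = True
    return RpeMask(mask=mask, dopu_threshold=0.8, window=(3, 3), geometry=geometry)


@pytest.fixture(scope="session")
def month24_summary(downscaled_config):
    """Full pipeline run over the packaged 31-eye month-24 cohort."""
    path = resources.files("psoct.fixtures") / "cohort_month24.yaml"
    return run_pipeline(str(path), downscaled_config)


@pytest.fixture(scope="session")
def fixture_cohort_path():
    return str(resources.files("psoct.fixtures") / "cohort_month24.yaml")
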