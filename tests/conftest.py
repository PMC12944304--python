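import numpy as np
import pytest
from hypothesis import settings

import nasofilm as nf
from nasofilm.scenario import _rotate_about_y
from nasofilm.spray import SprayConfig, sample_droplets

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def surrogate_45():
    """Unilateral nasal surrogate at 45 degree back tilt, coarse mesh."""
    return nf.build_nasal_surrogate(
        orientation=nf.Orientation(45.0), resolution=1.8
    )


@pytest.fixture(scope="session")
def deposition_45(surrogate_45):
    """Reference 0.25 mL deposition from the standard delivery protocol
    (2 mm insertion, 45 degree nozzle angle, 8.5 m/s)."""
    mesh = surrogate_45
    ic = np.asarray(mesh.metadata["inlet_center"])
    ia = np.asarray(mesh.metadata["inlet_axis"])
    cfg = SprayConfig(
        dose_volume_mL=0.25,
        nozzle_position_mm=tuple(ic + 2.0 * ia),
        nozzle_axis=tuple(_rotate_about_y(ia, 45.0)),
        seed=11,
    )
    return nf.track_droplets(sample_droplets(cfg, 3000), mesh)
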