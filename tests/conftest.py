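import numpy as np
import pytest

from beamsel import AngularGrid, PhantomSpec, generate_phantom, hu_to_rsp
from beamsel.metrics import CaseData, MetricsConfig, compute_metric_maps
from beamsel.volumes import average_intensity_projection, itv_from_gtvs


def build_case(amplitude_mm: float, noise_sd_hu: float = 0.0, seed: int = 0):
    """Default phantom -> CaseData (AIP/phase RSP volumes, ITV, OAR masks)."""
    spec = PhantomSpec(motion_amplitude_mm=amplitude_mm, noise_sd_hu=noise_sd_hu, seed=seed)
    ph = generate_phantom(spec)
    _, itv = itv_from_gtvs(ph.gtv_masks, margin_mm=5.0)
    aip = average_intensity_projection(ph.phases)
    case = CaseData(
        hu_to_rsp(aip), [hu_to_rsp(p) for p in ph.phases], itv, ph.oar_masks
    )
    return ph, case


@pytest.fixture(scope="session")
def default_grid():
    return AngularGrid.default()


@pytest.fixture(scope="session")
def static_case():
    """Motionless, noiseless default phantom."""
    return build_case(amplitude_mm=0.0)


@pytest.fixture(scope="session")
def moving_case():
    """Default phantom with 10 mm peak-to-peak superior-inferior tumour motion."""
    return build_case(amplitude_mm=10.0)


@pytest.fixture(scope="session")
def static_maps(static_case, default_grid):
    _, case = static_case
    return compute_metric_maps(case, default_grid, MetricsConfig(log_every=0))


@pytest.fixture(scope="session")
def moving_maps(moving_case, default_grid):
    _, case = moving_case
    return compute_metric_maps(case, default_grid, MetricsConfig(log_every=0))


def map_by_voi(maps, voi):
    return next(m for m in maps if m.voi == voi)


def grid_index(grid, gantry, couch):
    ig = int(np.flatnonzero(np.isclose(grid.gantry_deg, gantry))[0])
    ic = int(np.flatnonzero(np.isclose(grid.couch_deg, couch))[0])
    return ic, ig
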