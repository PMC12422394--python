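import numpy as np
import pytest

from choroid3d import (BinarizationParams, ChoroidBoundaries, analyze_eye)
from choroid3d.phantom import (PhantomSpec, Vessel, apply_speckle, five_sector_spec,
                               generate_phantom)


def gt_boundaries(gt, spacing, n_axial):
    """ChoroidBoundaries built directly from ground-truth surfaces."""
    nb = gt.inner_um.shape[0]
    return ChoroidBoundaries(inner=gt.inner_um / spacing.axial,
                             outer=gt.outer_um / spacing.axial,
                             corrected=np.zeros(nb, dtype=bool),
                             n_axial=n_axial)


def fine_spec(vessels, seed=1, **kwargs):
    """48 x 120 x 96 phantom at 10 µm isotropic with flat surfaces."""
    defaults = dict(n_bscans=48, n_ascans=96, n_axial=120,
                    inner_depth_mean=300.0, choroid_thickness_mean=500.0,
                    vessels=vessels, seed=seed)
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


def tube_along_bscan(x_um, z_um=550.0, radius=50.0, y0=-100.0, y1=580.0):
    """A straight tube perpendicular to the B-scans (circular cross-section)."""
    return Vessel(points_um=[[y0, z_um, x_um], [y1, z_um, x_um]], radius_um=radius)


@pytest.fixture(scope="session")
def two_tube_phantom():
    spec = fine_spec([tube_along_bscan(480.0, radius=80.0),
                      tube_along_bscan(180.0, radius=50.0)])
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def two_tube_speckled(two_tube_phantom):
    vol, gt = two_tube_phantom
    return apply_speckle(vol, 4.0, seed=7), gt


@pytest.fixture(scope="session")
def coarse_phantom():
    """Full-field 12 x 12 mm phantom with 3 tubes in each of the 5 sectors."""
    return generate_phantom(five_sector_spec(seed=2))


@pytest.fixture(scope="session")
def coarse_analysis(coarse_phantom):
    """Full default pipeline run on the five-sector phantom."""
    vol, _ = coarse_phantom
    return analyze_eye(vol, seed=11)


@pytest.fixture(scope="session")
def coarse_analysis_clean(coarse_phantom):
    """Pipeline run with the noise-cleanup stages disabled (noise-free input)."""
    vol, _ = coarse_phantom
    return analyze_eye(vol, seed=11,
                       bin_params=BinarizationParams(median_size=1, opening_size=1))
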