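import numpy as np
import pytest

from mucheck.beam_model import (
    ToyModelConfig,
    generate_case,
    generate_factor_set,
    node_case_specs,
    shaped_case_specs,
)
from mucheck.factors import FactorSet, FactorTable1D, FactorTable2D
from mucheck.geometry import DensityGrid, VoxelMask
from mucheck.mu_calc import check_case

SEED = 1


@pytest.fixture(scope="session")
def cfg():
    return ToyModelConfig()


@pytest.fixture(scope="session")
def factor_set(cfg):
    return generate_factor_set(cfg)


@pytest.fixture(scope="session")
def unit_factor_set():
    """All-ones factor tables: MU equals prescribed dose numerically."""
    ones2 = FactorTable2D(
        area_axis=[1.0, 1000.0], width_axis=[0.2, 20.0], values=np.ones((2, 2))
    )
    return FactorSet(
        of_open=ones2,
        of_shifted=ones2,
        df=FactorTable1D([4.0, 32.0], [1.0, 1.0]),
        agf=FactorTable1D([0.0, 10.0], [1.0, 1.0]),
    )


@pytest.fixture(scope="session")
def node_results(cfg, factor_set):
    """All cuboid node cases run end-to-end against the toy engine."""
    return [
        check_case(generate_case(s, cfg, SEED), factor_set)
        for s in node_case_specs(cfg)
    ]


@pytest.fixture(scope="session")
def shaped_results(cfg, factor_set):
    """44 seeded ellipsoid/blob cases across the four site labels."""
    return [
        check_case(generate_case(s, cfg, SEED), factor_set)
        for s in shaped_case_specs(44, seed=SEED, config=cfg)
    ]


def water_box(depth_cm=30.0, lateral_cm=10.0, spacing=0.1):
    """Uniform-water phantom; the beam (gantry 0) enters at the +y face."""
    shape = (
        int(round(lateral_cm / spacing)),
        int(round(depth_cm / spacing)),
        int(round(lateral_cm / spacing)),
    )
    return DensityGrid.uniform_water((0.0, 0.0, 0.0), (spacing,) * 3, shape)


def box_mask(density, lo, hi):
    """Axis-aligned cuboid mask with faces snapped to voxel boundaries."""
    s = density.spacing
    occ = np.zeros(density.shape, dtype=bool)
    i0 = [int(round((lo[a] - density.origin[a]) / s[a])) for a in range(3)]
    i1 = [int(round((hi[a] - density.origin[a]) / s[a])) for a in range(3)]
    occ[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]] = True
    return VoxelMask(density.origin, s, occ)


def sphere_mask(density, center, radius):
    s = density.spacing
    idx = np.indices(density.shape, dtype=float)
    coords = [density.origin[a] + (idx[a] + 0.5) * s[a] for a in range(3)]
    r2 = sum((coords[a] - center[a]) ** 2 for a in range(3))
    return VoxelMask(density.origin, s, r2 <= radius**2)


def brute_force_wed(point, density, step_cm=1e-3, threshold=0.2):
    """10 um Riemann-sum WED oracle for a beam along -y (independent path)."""
    x, y, z = point
    s = density.spacing
    ymax = density.upper[1]
    n = int(np.ceil((ymax - y) / step_cm))
    ys = y + (np.arange(n) + 0.5) * step_cm  # midpoints from the point upstream
    ix = int((x - density.origin[0]) / s[0])
    iz = int((z - density.origin[2]) / s[2])
    iy = np.clip(((ys - density.origin[1]) / s[1]).astype(int), 0, density.shape[1] - 1)
    rsp = density.rsp[ix, iy, iz]
    above = rsp > threshold
    if not above.any():
        return 0.0
    surf = np.max(np.nonzero(above)[0])  # outermost above-threshold sample
    return float(np.sum(rsp[: surf + 1]) * step_cm)
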