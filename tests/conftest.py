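import numpy as np
import pytest

from vesselmorph.grids import BinaryVesselMask, GridSpec
from vesselmorph.phantom import PhantomSpec, make_phantom


def voxel_mask(shape, points, spacing=(0.5, 0.5, 0.5)):
    """Binary mask with foreground exactly at the given voxel indices."""
    vals = np.zeros(shape, dtype=np.uint8)
    pts = np.asarray(points)
    vals[tuple(pts.T)] = 1
    return BinaryVesselMask(grid=GridSpec(shape=shape, spacing=spacing), values=vals)


def solid_cylinder(shape=(48, 48, 48), center=(24, 24), r_vox=3.0, z0=4, z1=44,
                   spacing=(0.5, 0.5, 0.5)):
    """Axis-aligned solid cylinder with its axis through a voxel column."""
    idx = np.indices(shape)
    vals = (
        ((idx[0] - center[0]) ** 2 + (idx[1] - center[1]) ** 2 <= r_vox**2)
        & (idx[2] >= z0)
        & (idx[2] < z1)
    )
    return BinaryVesselMask(grid=GridSpec(shape=shape, spacing=spacing), values=vals.astype(np.uint8))


def brute_force_edt_at(mask, points):
    """Independent radius oracle: nearest background voxel center, in mm.

    Plain windowed search over candidate background voxels, per point.
    """
    spacing = np.asarray(mask.grid.spacing)
    vals = mask.values.astype(bool)
    shape = np.asarray(mask.grid.shape)
    out = np.empty(len(points))
    for t, p in enumerate(np.asarray(points)):
        half = 4
        while True:
            lo = np.maximum(p - half, 0)
            hi = np.minimum(p + half + 1, shape)
            sub = vals[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            bg = np.argwhere(~sub)
            best = (
                np.sqrt((((bg + lo - p) * spacing) ** 2).sum(axis=1)).min()
                if len(bg)
                else np.inf
            )
            full = np.all(lo == 0) and np.all(hi == shape)
            # valid once the window ball certainly contains the optimum
            if best <= half * spacing.min() or full:
                break
            half *= 2
        out[t] = best
    return out


@pytest.fixture(scope="session")
def straight_tube():
    """Rasterized straight tube, r = 2 mm, L = 40 mm, 0.5 mm isotropic grid."""
    return make_phantom(PhantomSpec(kind="straight_tube", radius_mm=2.0, length_mm=40.0))


@pytest.fixture(scope="session")
def y_tree():
    return make_phantom(PhantomSpec(kind="y_tree", radius_mm=2.0, length_mm=40.0))


@pytest.fixture(scope="session")
def semicircle_tube():
    return make_phantom(
        PhantomSpec(kind="arc_tube", radius_mm=2.0, arc_radius_mm=20.0, arc_angle=np.pi)
    )


@pytest.fixture(scope="session")
def subject_table():
    from vesselmorph.stats import simulate_subject_table

    return simulate_subject_table(n=650, seed=0)
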