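"""Shared fixtures: small deterministic clouds built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from crownarch import TreeCloud, StemAxis


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def oracle_cloud() -> TreeCloud:
    """A fixed 18-point cloud exercising every feature code path:

    a short stem line, a tight 6-point tuft (small alpha-shape tetrahedra),
    and scattered crown points spanning several sectors and layers.
    """
    pts = np.array(
        [
            # stem-ish lower points
            [0.02, -0.03, 0.00],
            [-0.04, 0.05, 0.45],
            [0.05, 0.02, 0.90],
            [-0.02, -0.06, 1.35],
            # tight tuft around (0.6, 0.4, 3.0)
            [0.55, 0.35, 2.90],
            [0.75, 0.42, 3.05],
            [0.52, 0.58, 3.10],
            [0.68, 0.30, 3.22],
            [0.47, 0.44, 3.30],
            [0.70, 0.55, 2.95],
            # scattered crown points
            [-1.30, 0.90, 2.10],
            [1.10, -1.20, 2.60],
            [-0.80, -1.40, 3.50],
            [1.45, 0.95, 4.10],
            [-1.15, 1.30, 4.60],
            [0.30, -0.70, 5.10],
            [-0.50, 0.60, 5.60],
            [0.90, 1.10, 6.00],
        ]
    )
    return TreeCloud(tree_id="oracle", points=pts, dtm_z=0.0, species="XX")


def eightfold_crown() -> tuple[TreeCloud, StemAxis, float]:
    """A crown whose occupied voxels are perfectly 8-fold symmetric.

    With voxel size 0.7 and the grid anchored at (-1.4, -1.4), the occupied
    voxel centres per z-level are the dihedral set {(+-1.05, +-0.35),
    (+-0.35, +-1.05)} -- one voxel per sector, all at the same axis distance.
    Three z-levels with 2 / 1 voxel-layers give layer-count vectors (1, 2)
    per sector.  Returns (cloud, explicit vertical axis, voxel size).
    """
    level_points = []
    # cell centres for grid anchored at -1.4 with voxel 0.7:
    # centres at -1.05, -0.35, 0.35, 1.05
    dihedral = [
        (1.05, 0.35), (0.35, 1.05), (-0.35, 1.05), (-1.05, 0.35),
        (-1.05, -0.35), (-0.35, -1.05), (0.35, -1.05), (1.05, -0.35),
    ]
    for z in (0.0, 0.8, 1.5):  # voxel centres 0.35, 1.05, 1.75
        for i, (x, y) in enumerate(dihedral):
            level_points.append([x, y, z])
    pts = np.array(level_points, dtype=float)
    # pin the grid anchor at (-1.4, -1.4): replace two points by positions
    # inside the same cells but touching the anchor coordinates
    pts[3] = [-1.4, 0.30, 0.0]   # cell centred (-1.05, 0.35)
    pts[6] = [0.30, -1.4, 0.0]   # cell centred (0.35, -1.05)
    cloud = TreeCloud(tree_id="sym8", points=pts, dtm_z=-1.0, species="XX")
    axis = StemAxis(point=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))
    return cloud, axis, 0.7


@pytest.fixture()
def symmetric_crown():
    return eightfold_crown()


def uniform_cylinder(rng, n=5000, radius=2.0, height=10.0) -> TreeCloud:
    """Points uniform in a vertical cylinder centred on the z-axis."""
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, height, n)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return TreeCloud(tree_id="cyl", points=pts, dtm_z=0.0)
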