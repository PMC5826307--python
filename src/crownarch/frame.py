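"""Geometric scaffolding derived from a tree cloud.

Everything the crown feature formulas consume is built here: the stem axis
(PCA of the lower stem returns), the crown extent (automatic density-scan
crown base), a cubic voxelization of the crown, the partition of occupied
voxels into 8 azimuthal sectors around the stem axis, equal-thickness
vertical layers, and 3-D convex-hull / alpha-shape volumes.

Conventions (fixed, configurable where noted):

* voxel binning uses half-open ``[min, max)`` intervals per axis, with the
  grid anchored at the crown points' minimum corner;
* sector 1 spans azimuths ``[0°, 45°)`` measured from geographic east,
  counter-clockwise;
* vertical layers split ``[crown_base_z, crown_top_z]`` into ``n_layers``
  equal slabs; a voxel belongs to the slab containing its centre (clipped
  into range so layer counts always sum to the occupied-voxel total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .io import DegenerateInputError, TreeCloud

__all__ = [
    "StemAxis",
    "CrownFrame",
    "DegenerateCrownError",
    "estimate_stem_axis",
    "build_crown_frame",
    "alpha_volume",
    "convex_hull_volume",
]

N_SECTORS = 8


class DegenerateCrownError(ValueError):
    """The crown geometry collapsed (no crown points, zero extent...)."""


@dataclass(frozen=True)
class StemAxis:
    """Stem axis as an anchor point plus an upward unit direction."""

    point: np.ndarray  # (3,)
    direction: np.ndarray  # (3,), unit norm, z-component > 0
    fallback: bool = False  # True when the PCA axis was rejected as too tilted

    def xy_at(self, z: np.ndarray | float) -> np.ndarray:
        """Horizontal axis position(s) at height(s) ``z``."""
        z = np.asarray(z, dtype=float)
        t = (z - self.point[2]) / self.direction[2]
        out = self.point[:2] + np.multiply.outer(t, self.direction[:2])
        return out


def estimate_stem_axis(
    tree: TreeCloud,
    lower_fraction: float = 0.25,
    max_tilt_deg: float = 30.0,
) -> StemAxis:
    """Estimate the stem axis by PCA of the lowest points of the cloud.

    The first principal axis of the points within the lowest
    ``lower_fraction`` of the height range is taken, re-oriented upward.
    If it deviates more than ``max_tilt_deg`` from vertical (e.g. the lower
    crown is dominated by a long branch), the estimate falls back to the
    vertical line through the horizontal centroid of all points, with a
    warning.
    """
    pts = tree.points
    zmin, zmax = pts[:, 2].min(), pts[:, 2].max()
    cut = zmin + lower_fraction * (zmax - zmin)
    lower = pts[pts[:, 2] <= cut]
    centroid_all = pts.mean(axis=0)

    if lower.shape[0] >= 3:
        centred = lower - lower.mean(axis=0)
        # first right singular vector == first principal axis
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        direction = vt[0]
        if direction[2] < 0:
            direction = -direction
        tilt = np.degrees(np.arccos(np.clip(direction[2], -1.0, 1.0)))
        if s[0] > 0 and tilt <= max_tilt_deg:
            return StemAxis(point=lower.mean(axis=0), direction=direction, fallback=False)

    warnings.warn(
        f"tree {tree.tree_id!r}: stem PCA axis rejected (tilt > {max_tilt_deg} deg "
        "or too few stem points); falling back to vertical axis through centroid",
        stacklevel=2,
    )
    point = np.array([centroid_all[0], centroid_all[1], zmin])
    return StemAxis(point=point, direction=np.array([0.0, 0.0, 1.0]), fallback=True)


@dataclass(frozen=True)
class CrownFrame:
    """Derived crown geometry for one tree.

    Occupied voxels are stored as parallel arrays: integer grid indices,
    centre coordinates, point counts, centre heights above the crown base
    (``heights``), horizontal centre distances to the stem axis (``radii``),
    sector labels 1..8 and layer labels 1..n_layers.
    """

    tree_id: str
    axis: StemAxis
    crown_base_z: float
    crown_top_z: float
    Lc: float  # crown length, m
    Rc: float  # crown radius, m
    a_base: float  # projected crown area, m^2
    voxel_size: float
    n_layers: int
    crown_points: np.ndarray  # (m, 3) points with z >= crown_base_z
    grid_origin: np.ndarray  # (3,) corner the voxel grid is anchored at
    voxel_indices: np.ndarray  # (k, 3) int
    voxel_centers: np.ndarray  # (k, 3)
    voxel_counts: np.ndarray  # (k,) int, points per voxel
    heights: np.ndarray  # (k,) centre z - crown_base_z
    radii: np.ndarray  # (k,) horizontal distance centre -> axis
    sectors: np.ndarray  # (k,) int in 1..8
    layers: np.ndarray  # (k,) int in 1..n_layers

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])

    def layer_voxel_counts(self) -> np.ndarray:
        """Occupied-voxel count per vertical layer, shape (n_layers,)."""
        return np.bincount(self.layers, minlength=self.n_layers + 1)[1:]

    def layer_point_counts(self) -> np.ndarray:
        """Point count per vertical layer, shape (n_layers,)."""
        rel = (self.crown_points[:, 2] - self.crown_base_z) / max(self.Lc, 1e-12)
        idx = np.clip((rel * self.n_layers).astype(int), 0, self.n_layers - 1)
        return np.bincount(idx, minlength=self.n_layers)

    def layer_mid_heights(self) -> np.ndarray:
        """Mid-heights of the layers above the crown base, shape (n_layers,)."""
        thick = self.Lc / self.n_layers
        return (np.arange(self.n_layers) + 0.5) * thick

    def sector_layer_matrix(self) -> np.ndarray:
        """Occupied-voxel counts per (sector, layer), shape (8, n_layers)."""
        mat = np.zeros((N_SECTORS, self.n_layers), dtype=int)
        np.add.at(mat, (self.sectors - 1, self.layers - 1), 1)
        return mat


def detect_crown_base(
    z: np.ndarray,
    bin_height: float = 0.5,
    min_bin_fraction: float = 0.05,
    min_bin_count: int = 2,
) -> float:
    """Density-scan crown base: lower edge of the lowest ``bin_height`` slab
    whose point count reaches ``min_bin_fraction`` of the maximum slab count,
    scanning upward.  Sparse stem hits below the live crown are thereby
    skipped without manual segmentation.  ``min_bin_count`` is an absolute
    floor on the threshold: a single return is never evidence of crown, no
    matter how sparse the cloud."""
    zmin = float(z.min())
    nbins = max(1, int(np.ceil((float(z.max()) - zmin) / bin_height)))
    counts, edges = np.histogram(z, bins=nbins, range=(zmin, zmin + nbins * bin_height))
    threshold = max(min_bin_fraction * counts.max(), min(min_bin_count, counts.max()))
    for i, c in enumerate(counts):
        if c >= threshold:
            return float(edges[i])
    return zmin  # unreachable: max bin always passes


def build_crown_frame(
    tree: TreeCloud,
    voxel_size: float = 0.5,
    n_layers: int = 8,
    crown_base_z: float | None = None,
    axis: StemAxis | None = None,
    bin_height: float = 0.5,
    min_bin_fraction: float = 0.05,
    grid_origin: np.ndarray | None = None,
) -> CrownFrame:
    """Voxelize a tree cloud and derive its crown frame.

    Parameters
    ----------
    voxel_size : float
        Edge of the cubic voxels in metres (> 0).
    n_layers : int
        Number of equal-thickness vertical crown layers (>= 2).
    crown_base_z : float, optional
        Manual crown base override; default is the automatic density scan
        (see :func:`detect_crown_base`).
    axis : StemAxis, optional
        Pre-computed stem axis; default :func:`estimate_stem_axis`.
    grid_origin : array-like, optional
        Anchor corner of the voxel grid; default the crown points' minimum
        corner.  An explicit origin makes grids comparable across trees.
    """
    if voxel_size <= 0:
        raise ValueError(f"voxel_size must be > 0, got {voxel_size}")
    if n_layers < 2:
        raise ValueError(f"n_layers must be >= 2, got {n_layers}")
    pts = tree.points
    crown_top_z = float(pts[:, 2].max())
    if crown_base_z is None:
        crown_base_z = detect_crown_base(pts[:, 2], bin_height, min_bin_fraction)
    crown = pts[pts[:, 2] >= crown_base_z]
    if crown.shape[0] == 0:
        raise DegenerateCrownError(
            f"tree {tree.tree_id!r}: all points below crown base z={crown_base_z:.2f}"
        )
    Lc = crown_top_z - crown_base_z
    if Lc <= 0:
        raise DegenerateCrownError(f"tree {tree.tree_id!r}: crown length is not positive")

    if axis is None:
        # radii and sectors are measured from the *vertical* line through the
        # stem footprint.  The PCA axis anchor (centroid of the lower stem
        # returns) is a robust footprint; extrapolating the PCA *direction*
        # up to the crown would amplify its estimation noise, so the frame
        # axis is the vertical line through that anchor.
        est = estimate_stem_axis(tree)
        axis = StemAxis(
            point=np.array([est.point[0], est.point[1], crown_base_z]),
            direction=np.array([0.0, 0.0, 1.0]),
            fallback=est.fallback,
        )

    # crown radius: max horizontal point distance to the axis
    dxy = crown[:, :2] - axis.xy_at(crown[:, 2])
    Rc = float(np.hypot(dxy[:, 0], dxy[:, 1]).max())
    if Rc <= 0:
        raise DegenerateCrownError(f"tree {tree.tree_id!r}: crown radius is zero")

    try:
        a_base = float(ConvexHull(crown[:, :2]).volume)  # 2-D hull "volume" == area
    except QhullError as exc:
        raise DegenerateCrownError(
            f"tree {tree.tree_id!r}: projected crown points are collinear ({exc})"
        ) from exc

    # cubic voxel grid anchored at the crown's minimum corner, [min, max) bins
    origin = crown.min(axis=0) if grid_origin is None else np.asarray(grid_origin, float)
    idx = np.floor((crown - origin) / voxel_size).astype(int)
    vox_idx, counts = np.unique(idx, axis=0, return_counts=True)
    centers = origin + (vox_idx + 0.5) * voxel_size

    heights = centers[:, 2] - crown_base_z
    cxy = centers[:, :2] - axis.xy_at(centers[:, 2])
    radii = np.hypot(cxy[:, 0], cxy[:, 1])
    az = np.mod(np.arctan2(cxy[:, 1], cxy[:, 0]), 2 * np.pi)
    sectors = np.minimum((az / (2 * np.pi / N_SECTORS)).astype(int), N_SECTORS - 1) + 1
    layers = np.clip((heights / (Lc / n_layers)).astype(int), 0, n_layers - 1) + 1

    return CrownFrame(
        tree_id=tree.tree_id,
        axis=axis,
        crown_base_z=float(crown_base_z),
        crown_top_z=crown_top_z,
        Lc=float(Lc),
        Rc=Rc,
        a_base=a_base,
        voxel_size=float(voxel_size),
        n_layers=int(n_layers),
        crown_points=crown,
        grid_origin=origin,
        voxel_indices=vox_idx,
        voxel_centers=centers,
        voxel_counts=counts,
        heights=heights,
        radii=radii,
        sectors=sectors,
        layers=layers,
    )


# ---------------------------------------------------------------------------
# 3-D volumes


def convex_hull_volume(points: np.ndarray) -> float:
    """Volume of the 3-D convex hull; 0 with a warning for degenerate input."""
    pts = np.asarray(points, dtype=float)
    try:
        return float(ConvexHull(pts).volume)
    except (QhullError, ValueError):
        warnings.warn("convex_hull_volume: degenerate (coplanar or too few) points; returning 0")
        return 0.0


def _tet_circumradii(verts: np.ndarray) -> np.ndarray:
    """Circumradii of tetrahedra, verts shape (m, 4, 3).

    The circumcentre c satisfies 2*(v_i - v_0) . c = |v_i|^2 - |v_0|^2 for
    i = 1..3; degenerate (near-flat) tetrahedra get radius +inf so that any
    finite alpha excludes them.
    """
    a = verts[:, 0]
    A = 2.0 * (verts[:, 1:] - a[:, None, :])  # (m, 3, 3)
    b = np.einsum("mij,mij->mi", verts[:, 1:], verts[:, 1:]) - np.einsum(
        "mi,mi->m", a, a
    )[:, None]
    det = np.linalg.det(A)
    radii = np.full(len(verts), np.inf)
    ok = np.abs(det) > 1e-12
    if ok.any():
        centres = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centres - a[ok], axis=1)
    return radii


def alpha_volume(points: np.ndarray, alpha: float) -> float:
    """Volume of the 3-D alpha shape at parameter ``alpha`` (metres).

    Built as the union of Delaunay tetrahedra whose circumradius is at most
    ``alpha``; ``alpha = inf`` therefore recovers the convex hull, and the
    result never exceeds the convex-hull volume.  Coplanar input yields 0
    with a warning rather than an exception.
    """
    pts = np.asarray(points, dtype=float)
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    try:
        tri = Delaunay(pts)
    except (QhullError, ValueError):
        warnings.warn("alpha_volume: degenerate (coplanar or too few) points; returning 0")
        return 0.0
    verts = pts[tri.simplices]  # (m, 4, 3)
    e1 = verts[:, 1] - verts[:, 0]
    e2 = verts[:, 2] - verts[:, 0]
    e3 = verts[:, 3] - verts[:, 0]
    vols = np.abs(np.einsum("mi,mi->m", np.cross(e1, e2), e3)) / 6.0
    if np.isinf(alpha):
        return float(vols.sum())
    radii = _tet_circumradii(verts)
    return float(vols[radii <= alpha].sum())
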