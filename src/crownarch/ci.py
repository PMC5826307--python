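"""Crown-internal (CI) structure parameters P1-P13.

Thirteen dimensionless scalars describing how laser returns are arranged
*inside* a crown: sector-wise centroid heights and radii and their spreads
(P1, P2, P5, P6, P13), the lower-crown footprint ratio (P3), point
concentration in 1 m super-voxels (P4), stem-space occupancy (P7), the
whole-crown centroid height (P8), vertical layer regularity (P9, P10),
alpha-shape compactness (P11) and 8-sector profile symmetry (P12).
Heights entering ratios with the crown length are measured from the crown
base, so those ratios land in [0, 1].

All spreads are population (n-denominator) standard deviations.  Degenerate
cases never return NaN silently: empty sectors are excluded with a warning,
zero-variance profiles contribute correlation 0, and a vanishing P6 makes
P13 the sentinel value 0 with ``p13_sentinel`` set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .frame import N_SECTORS, CrownFrame, alpha_volume, convex_hull_volume

__all__ = ["CIFeatures", "compute_ci_features", "CI_COLUMNS"]

CI_COLUMNS = tuple(f"P{i}" for i in range(1, 14))

P13_EPS = 1e-9


@dataclass(frozen=True)
class CIFeatures:
    """The 13 crown-internal parameter values for one tree."""

    P1: float
    P2: float
    P3: float
    P4: float
    P5: float
    P6: float
    P7: float
    P8: float
    P9: float
    P10: float
    P11: float
    P12: float
    P13: float
    p13_sentinel: bool = False

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name in CI_COLUMNS}


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; a zero-variance vector contributes 0 (logged)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        warnings.warn("P12: zero-variance sector profile; correlation taken as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _projected_hull_area(xy: np.ndarray) -> float:
    try:
        return float(ConvexHull(xy).volume)
    except (QhullError, ValueError):
        warnings.warn("P3: degenerate lower-crown projection; area taken as 0")
        return 0.0


def compute_ci_features(
    frame: CrownFrame,
    alpha: float = 0.5,
    supervoxel_size: float = 1.0,
) -> CIFeatures:
    """Compute P1-P13 from a crown frame.

    ``alpha`` is the alpha-shape parameter of P11 (metres); the P4
    super-voxels are cubes of ``supervoxel_size`` anchored at the crown's
    minimum corner.
    """
    if frame.n_voxels == 0:
        raise ValueError(f"tree {frame.tree_id!r}: no occupied voxels")
    Lc, Rc = frame.Lc, frame.Rc
    crown = frame.crown_points

    # per-sector centroid statistics (P1/P2 components)
    sector_h: list[float] = []
    sector_r: list[float] = []
    for s in range(1, N_SECTORS + 1):
        mask = frame.sectors == s
        if not mask.any():
            warnings.warn(
                f"tree {frame.tree_id!r}: sector {s} empty; excluded from P1/P2 means"
            )
            continue
        sector_h.append(float(frame.heights[mask].mean()) / Lc)
        sector_r.append(float(frame.radii[mask].mean()) / Rc)
    sh = np.array(sector_h)
    sr = np.array(sector_r)
    p1 = float(sh.mean())
    p2 = float(sr.mean())
    p5 = float(sh.std())  # population sd
    p6 = float(sr.std())

    # P3: footprint of the lower third relative to the whole crown footprint
    low = crown[crown[:, 2] - frame.crown_base_z <= Lc / 3.0]
    if low.shape[0] < 3:
        p3 = 0.0
    else:
        p3 = _projected_hull_area(low[:, :2]) / frame.a_base

    # P4: largest point fraction within 1 m super-voxels (anchored at the
    # frame's grid origin, so the two grids are consistent)
    sv = np.floor((crown - frame.grid_origin) / supervoxel_size).astype(int)
    _, sv_counts = np.unique(sv, axis=0, return_counts=True)
    p4 = float(sv_counts.max()) / crown.shape[0]

    # P7: occupied voxels inside the stem space (lower 1/3 height, radius Rc/2)
    stem_space = (frame.heights <= Lc / 3.0) & (frame.radii <= Rc / 2.0)
    p7 = float(stem_space.sum()) / frame.n_voxels

    # P8: whole-crown voxel-centroid height (distinct from P1's mean of sector means)
    p8 = float(frame.heights.mean()) / Lc

    # P9/P10: vertical layer regularity of occupied-voxel counts
    layer_counts = frame.layer_voxel_counts().astype(float)
    p9 = float(layer_counts.std())
    p10 = float(np.abs(np.diff(layer_counts)).sum()) / frame.n_voxels

    # P11: alpha-shape vs convex-hull volume
    hull_vol = convex_hull_volume(crown)
    p11 = alpha_volume(crown, alpha) / hull_vol if hull_vol > 0 else 0.0

    # P12: opposite-sector vs adjacent-sector profile similarity
    mat = frame.sector_layer_matrix().astype(float)
    num = sum(_pearson(mat[i], mat[i + 4]) for i in range(4))
    den = sum(_pearson(mat[i], mat[(i + 1) % N_SECTORS]) for i in range(N_SECTORS))
    if abs(den) < 1e-12:
        warnings.warn(f"tree {frame.tree_id!r}: P12 denominator ~0; P12 set to 0")
        p12 = 0.0
    else:
        p12 = num / den

    # P13 = P5/P6 with a zero-denominator sentinel
    if p6 > P13_EPS:
        p13 = p5 / p6
        sentinel = False
    else:
        warnings.warn(f"tree {frame.tree_id!r}: P6 ~ 0; P13 set to sentinel 0")
        p13 = 0.0
        sentinel = True

    return CIFeatures(
        P1=p1, P2=p2, P3=p3, P4=p4, P5=p5, P6=p6, P7=p7, P8=p8, P9=p9,
        P10=p10, P11=p11, P12=p12, P13=p13, p13_sentinel=sentinel,
    )
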