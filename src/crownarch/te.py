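"""Tree-external (TE) structure parameters.

Ten whole-tree scalars: tree height Ht, crown-length ratio LcHt, the
area-equivalent crown diameter D_EA (diameter of the circle with the same
area as the projected crown cover, hence the 1/pi), the Gaussian spread
Alpha of the vertical crown profile, the slenderness LcD_EA, two profile
landmark ratios (llls_lhls_proxy, ls_lcs_proxy), the mean voxel height Gc,
a two-plane projected laser-penetration coverage P_L, and the projected
coverage LAI_proj.

``llls_lhls_proxy`` and ``ls_lcs_proxy`` carry a ``_proxy`` suffix because
their underlying profile landmarks (lowest/highest local density maxima and
the maximum-density layer) are package-defined operationalizations of
qualitative "main part of growth" descriptors; both are configurable via
user-supplied landmark heights.  ``LAI_proj`` implements a projected
coverage fraction, not a radiative-transfer leaf area index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import ConvexHull, QhullError

from .frame import CrownFrame
from .io import TreeCloud

__all__ = [
    "TEFeatures",
    "compute_te_features",
    "fit_gaussian_profile",
    "profile_local_maxima",
    "TE_COLUMNS",
]

TE_COLUMNS = (
    "Ht",
    "LcHt",
    "D_EA",
    "Alpha",
    "LcD_EA",
    "llls_lhls_proxy",
    "ls_lcs_proxy",
    "Gc",
    "P_L",
    "LAI_proj",
)


@dataclass(frozen=True)
class TEFeatures:
    """The 10 tree-external parameter values for one tree."""

    Ht: float  # m
    LcHt: float
    D_EA: float  # m
    Alpha: float  # m, Gaussian spread of the vertical profile
    LcD_EA: float
    llls_lhls_proxy: float
    ls_lcs_proxy: float
    Gc: float  # m, mean voxel-centre height above ground
    P_L: float
    LAI_proj: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name in TE_COLUMNS}


def _gauss(h: np.ndarray, amp: float, u: float, a: float) -> np.ndarray:
    return amp * np.exp(-((h - u) ** 2) / (2.0 * a**2))


def _gauss_jac(h: np.ndarray, amp: float, u: float, a: float) -> np.ndarray:
    e = np.exp(-((h - u) ** 2) / (2.0 * a**2))
    return np.stack(
        [e, amp * e * (h - u) / a**2, amp * e * (h - u) ** 2 / a**3], axis=1
    )


def fit_gaussian_profile(h: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of ``exp(-(h-u)^2 / (2 alpha^2))`` to a profile.

    ``g`` is normalized to max 1 before fitting; a free amplitude (then
    ~1) absorbs the sampling noise of the single peak bin, which would
    otherwise bias the width low.  Returns ``(u, alpha)``; on
    non-convergence the profile's weighted mean and second moment are
    returned with a warning.
    """
    h = np.asarray(h, dtype=float)
    g = np.asarray(g, dtype=float)
    gmax = g.max()
    if gmax <= 0:
        warnings.warn("Gaussian profile fit: empty profile; returning moments of zeros")
        return float(h.mean()), float(h.std())
    g = g / gmax
    w = g / g.sum()
    u0 = float((w * h).sum())
    a0 = float(np.sqrt((w * (h - u0) ** 2).sum()))
    a0 = max(a0, 1e-3)
    try:
        popt, _ = curve_fit(
            _gauss, h, g, p0=(1.0, u0, a0), method="lm", jac=_gauss_jac,
            xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000,
        )
        # Gauss-Newton polish: the SSE surface is flat in the width, so the
        # solver's step-based stopping leaves ~1e-7 slack; drive the
        # stationarity condition J^T r = 0 to machine precision instead
        x = np.asarray(popt, dtype=float)
        for _ in range(50):
            J = _gauss_jac(h, *x)
            r = _gauss(h, *x) - g
            grad = J.T @ r
            if np.abs(grad).max() < 1e-14:
                break
            try:
                step = np.linalg.solve(J.T @ J, grad)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            x = x - step
        amp, u, a = x
        if not np.isfinite(a) or abs(a) < 1e-9:
            raise RuntimeError("degenerate width")
        return float(u), float(abs(a))
    except (RuntimeError, ValueError):
        warnings.warn("Gaussian profile fit did not converge; using profile moments")
        return u0, a0


def profile_local_maxima(counts: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima of a 1-D profile (strictly above the
    left neighbour, at least the right neighbour)."""
    c = np.asarray(counts, dtype=float)
    if c.size < 3:
        return np.array([], dtype=int)
    left = c[1:-1] > c[:-2]
    right = c[1:-1] >= c[2:]
    return np.nonzero(left & right)[0] + 1


def _grid_coverage(uv: np.ndarray, cell: float) -> float:
    """Occupied-cell area of a 2-D projection grid over the 2-D hull area.

    Cells of size ``cell`` anchored at the projection's min corner; a cell
    is occupied if at least one point falls in it.  Straddling cells can
    push the ratio marginally above 1.
    """
    idx = np.floor((uv - uv.min(axis=0)) / cell).astype(int)
    n_occupied = np.unique(idx, axis=0).shape[0]
    try:
        hull_area = float(ConvexHull(uv).volume)
    except (QhullError, ValueError):
        warnings.warn("projection coverage: collinear projected points; returning 0")
        return 0.0
    return n_occupied * cell * cell / hull_area


def compute_te_features(
    tree: TreeCloud,
    frame: CrownFrame,
    grid_cell: float = 0.5,
    h_lls: float | None = None,
    h_hls: float | None = None,
    profile_bin: float = 0.5,
) -> TEFeatures:
    """Compute the tree-external parameters from a cloud and its crown frame.

    ``h_lls`` / ``h_hls`` override the automatic profile-landmark heights
    (above ground) of the lowest/highest local density maxima.
    """
    if grid_cell <= 0:
        raise ValueError(f"grid_cell must be > 0, got {grid_cell}")
    pts = tree.points
    ht = tree.height
    lc_ht = frame.Lc / ht
    d_ea = 2.0 * np.sqrt(frame.a_base / np.pi)
    lc_d_ea = frame.Lc / d_ea

    # Gaussian spread of the per-layer point-count profile
    profile = frame.layer_point_counts().astype(float)
    h_mid = frame.layer_mid_heights() + frame.crown_base_z
    _, alpha = fit_gaussian_profile(h_mid, profile)

    # profile landmark ratio (lowest vs highest local density maxima)
    if h_lls is None or h_hls is None:
        zmin = float(pts[:, 2].min())
        nbins = max(3, int(np.ceil((float(pts[:, 2].max()) - zmin) / profile_bin)))
        counts, edges = np.histogram(
            pts[:, 2], bins=nbins, range=(zmin, zmin + nbins * profile_bin)
        )
        smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
        peaks = profile_local_maxima(smooth)
        mids = 0.5 * (edges[:-1] + edges[1:]) - tree.dtm_z
        if peaks.size == 0:
            auto_lls = auto_hls = float(mids[int(np.argmax(smooth))])
        else:
            auto_lls = float(mids[peaks[0]])
            auto_hls = float(mids[peaks[-1]])
        h_lls = auto_lls if h_lls is None else h_lls
        h_hls = auto_hls if h_hls is None else h_hls
    if abs(ht - h_hls) < 1e-12 or h_lls == h_hls:
        llls_lhls = 1.0
    else:
        llls_lhls = (ht - h_lls) / (ht - h_hls)

    # relative height of the maximum-density layer
    ls_lcs = float(frame.layer_mid_heights()[int(np.argmax(profile))]) / frame.Lc

    gc = float((frame.voxel_centers[:, 2] - tree.dtm_z).mean())

    p_l = 0.5 * (
        _grid_coverage(frame.crown_points[:, [0, 2]], grid_cell)
        + _grid_coverage(frame.crown_points[:, [1, 2]], grid_cell)
    )
    lai_proj = _grid_coverage(frame.crown_points[:, :2], grid_cell)

    return TEFeatures(
        Ht=float(ht),
        LcHt=float(lc_ht),
        D_EA=float(d_ea),
        Alpha=float(alpha),
        LcD_EA=float(lc_d_ea),
        llls_lhls_proxy=float(llls_lhls),
        ls_lcs_proxy=float(ls_lcs),
        Gc=gc,
        P_L=float(p_l),
        LAI_proj=float(lai_proj),
    )
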