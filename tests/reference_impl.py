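"""Independent brute-force reference for the crown feature definitions.

Everything here is written as explicit per-point / per-voxel loops, straight
from the definitions, with different library routes where possible (shapely
for 2-D hull areas, per-tetrahedron loops for 3-D volumes).  It exists only
as a test oracle and is deliberately slow.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError
from shapely.geometry import MultiPoint


def hull_area_2d(xy) -> float:
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        return 0.0
    geom = MultiPoint([tuple(p) for p in xy]).convex_hull
    return float(getattr(geom, "area", 0.0))


def hull_volume_3d(pts) -> float:
    """Hull volume as the sum of Delaunay tetrahedron volumes (loop)."""
    try:
        tri = Delaunay(np.asarray(pts, dtype=float))
    except (QhullError, ValueError):
        return 0.0
    total = 0.0
    for simplex in tri.simplices:
        a, b, c, d = tri.points[simplex]
        total += abs(np.dot(np.cross(b - a, c - a), d - a)) / 6.0
    return total


def alpha_volume_ref(pts, alpha) -> float:
    """Alpha-shape volume: keep tetrahedra with circumradius <= alpha."""
    try:
        tri = Delaunay(np.asarray(pts, dtype=float))
    except (QhullError, ValueError):
        return 0.0
    total = 0.0
    for simplex in tri.simplices:
        verts = tri.points[simplex]
        a = verts[0]
        A = 2.0 * (verts[1:] - a)
        b = np.array([v @ v - a @ a for v in verts[1:]])
        vol = abs(np.dot(np.cross(verts[1] - a, verts[2] - a), verts[3] - a)) / 6.0
        try:
            centre = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        if abs(np.linalg.det(A)) <= 1e-12:
            continue
        radius = math.dist(centre, a)
        if radius <= alpha:
            total += vol
    return total


def stem_axis_ref(points, lower_fraction=0.25, max_tilt_deg=30.0):
    """(x0, y0) of the vertical working axis, per the estimation rule."""
    pts = np.asarray(points, dtype=float)
    zmin, zmax = pts[:, 2].min(), pts[:, 2].max()
    lower = pts[pts[:, 2] <= zmin + lower_fraction * (zmax - zmin)]
    if len(lower) >= 3:
        centred = lower - lower.mean(axis=0)
        cov = centred.T @ centred
        w, v = np.linalg.eigh(cov)
        direction = v[:, np.argmax(w)]
        if direction[2] < 0:
            direction = -direction
        tilt = math.degrees(math.acos(min(1.0, max(-1.0, direction[2]))))
        if w.max() > 0 and tilt <= max_tilt_deg:
            return float(lower[:, 0].mean()), float(lower[:, 1].mean())
    return float(pts[:, 0].mean()), float(pts[:, 1].mean())


def crown_base_ref(z, bin_height=0.5, min_bin_fraction=0.05, min_bin_count=2):
    z = np.asarray(z, dtype=float)
    zmin = z.min()
    nbins = max(1, math.ceil((z.max() - zmin) / bin_height))
    counts = [0] * nbins
    for val in z:
        i = min(int((val - zmin) // bin_height), nbins - 1)
        counts[i] += 1
    threshold = max(min_bin_fraction * max(counts), min(min_bin_count, max(counts)))
    for i, c in enumerate(counts):
        if c >= threshold:
            return zmin + i * bin_height
    return zmin


def pearson_ref(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa = math.sqrt(((a - a.mean()) ** 2).mean())
    sb = math.sqrt(((b - b.mean()) ** 2).mean())
    if sa < 1e-12 or sb < 1e-12:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def pop_std(values):
    values = list(values)
    mu = sum(values) / len(values)
    return math.sqrt(sum((v - mu) ** 2 for v in values) / len(values))


def all_features_ref(
    points,
    dtm_z=0.0,
    voxel_size=0.5,
    n_layers=8,
    grid_cell=0.5,
    alpha=0.5,
    supervoxel=1.0,
):
    """All 13 CI + 10 TE parameter values, by explicit loops.

    Returns a dict keyed by the public column names.
    """
    pts = np.asarray(points, dtype=float)
    crown_base = crown_base_ref(pts[:, 2])
    crown = pts[pts[:, 2] >= crown_base]
    top = pts[:, 2].max()
    Lc = top - crown_base
    x0, y0 = stem_axis_ref(pts)
    Rc = max(math.hypot(p[0] - x0, p[1] - y0) for p in crown)
    a_base = hull_area_2d(crown[:, :2])

    # voxelization
    origin = crown.min(axis=0)
    voxels = {}
    for p in crown:
        key = tuple(int((p[i] - origin[i]) // voxel_size) for i in range(3))
        voxels[key] = voxels.get(key, 0) + 1
    centres = {k: tuple(origin[i] + (k[i] + 0.5) * voxel_size for i in range(3))
               for k in voxels}

    def sector_of(c):
        az = math.atan2(c[1] - y0, c[0] - x0) % (2 * math.pi)
        return min(int(az / (math.pi / 4)), 7) + 1

    def layer_of(c):
        h = c[2] - crown_base
        return min(max(int(h / (Lc / n_layers)), 0), n_layers - 1) + 1

    heights = {k: centres[k][2] - crown_base for k in voxels}
    radii = {k: math.hypot(centres[k][0] - x0, centres[k][1] - y0) for k in voxels}
    sectors = {k: sector_of(centres[k]) for k in voxels}
    layers = {k: layer_of(centres[k]) for k in voxels}

    # P1/P2/P5/P6 via per-sector means (empty sectors excluded)
    sec_h, sec_r = [], []
    for s in range(1, 9):
        keys = [k for k in voxels if sectors[k] == s]
        if not keys:
            continue
        sec_h.append(sum(heights[k] for k in keys) / len(keys) / Lc)
        sec_r.append(sum(radii[k] for k in keys) / len(keys) / Rc)
    P1 = sum(sec_h) / len(sec_h)
    P2 = sum(sec_r) / len(sec_r)
    P5 = pop_std(sec_h)
    P6 = pop_std(sec_r)

    low_pts = crown[crown[:, 2] - crown_base <= Lc / 3.0]
    P3 = hull_area_2d(low_pts[:, :2]) / a_base if len(low_pts) >= 3 else 0.0

    sv = {}
    for p in crown:
        key = tuple(int((p[i] - origin[i]) // supervoxel) for i in range(3))
        sv[key] = sv.get(key, 0) + 1
    P4 = max(sv.values()) / len(crown)

    P7 = sum(
        1 for k in voxels if heights[k] <= Lc / 3.0 and radii[k] <= Rc / 2.0
    ) / len(voxels)
    P8 = sum(heights.values()) / len(voxels) / Lc

    layer_counts = [sum(1 for k in voxels if layers[k] == i) for i in range(1, n_layers + 1)]
    P9 = pop_std(layer_counts)
    P10 = sum(
        abs(layer_counts[i] - layer_counts[i + 1]) for i in range(n_layers - 1)
    ) / len(voxels)

    hull_vol = hull_volume_3d(crown)
    P11 = alpha_volume_ref(crown, alpha) / hull_vol if hull_vol > 0 else 0.0

    mat = [[sum(1 for k in voxels if sectors[k] == s and layers[k] == l)
            for l in range(1, n_layers + 1)] for s in range(1, 9)]
    num = sum(pearson_ref(mat[i], mat[i + 4]) for i in range(4))
    den = sum(pearson_ref(mat[i], mat[(i + 1) % 8]) for i in range(8))
    P12 = num / den if abs(den) > 1e-12 else 0.0
    P13 = P5 / P6 if P6 > 1e-9 else 0.0

    # --- TE ---
    Ht = top - dtm_z
    LcHt = Lc / Ht
    D_EA = 2.0 * math.sqrt(a_base / math.pi)
    LcD_EA = Lc / D_EA

    point_layers = [0] * n_layers
    for p in crown:
        i = min(max(int((p[2] - crown_base) / (Lc / n_layers)), 0), n_layers - 1)
        point_layers[i] += 1
    mids = [crown_base + (i + 0.5) * Lc / n_layers for i in range(n_layers)]
    # Gaussian fit identical definition -> reuse scipy here is allowed for the
    # oracle only through an independent parametrization: grid+polish
    from scipy.optimize import minimize

    prof = np.array(point_layers, dtype=float)
    prof = prof / prof.max()

    def sse(theta):
        amp, u, a = theta
        if a <= 0 or amp <= 0:
            return 1e9
        g = amp * np.exp(-((np.array(mids) - u) ** 2) / (2 * a * a))
        return float(((g - prof) ** 2).sum())

    w = prof / prof.sum()
    u0 = float((w * np.array(mids)).sum())
    a0 = max(float(np.sqrt((w * (np.array(mids) - u0) ** 2).sum())), 1e-3)
    best = min(
        (minimize(sse, (1.0, u0 * fu, a0 * fa), method="Nelder-Mead",
                  options={"xatol": 1e-13, "fatol": 1e-16, "maxiter": 20000})
         for fu in (0.95, 1.0, 1.05) for fa in (0.5, 1.0, 2.0)),
        key=lambda r: r.fun,
    )
    # polish to machine precision with the analytic gradient
    m = np.array(mids)

    def sse_grad(theta):
        amp, u, a = theta
        e = np.exp(-((m - u) ** 2) / (2 * a * a))
        r = amp * e - prof
        return np.array([
            2 * (r * e).sum(),
            2 * (r * amp * e * (m - u) / a**2).sum(),
            2 * (r * amp * e * (m - u) ** 2 / a**3).sum(),
        ])

    best = minimize(sse, best.x, jac=sse_grad, method="BFGS",
                    options={"gtol": 1e-12, "maxiter": 10000})
    # Newton polish on the analytic gradient (finite-difference Hessian)
    x = np.asarray(best.x, dtype=float)
    for _ in range(60):
        gvec = sse_grad(x)
        if np.abs(gvec).max() < 1e-14:
            break
        H = np.empty((3, 3))
        eps = 1e-6
        for j in range(3):
            dx = np.zeros(3)
            dx[j] = eps
            H[:, j] = (sse_grad(x + dx) - sse_grad(x - dx)) / (2 * eps)
        try:
            step = np.linalg.solve(0.5 * (H + H.T), gvec)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        x = x - step
    Alpha = abs(x[2])

    zmin = pts[:, 2].min()
    nb = max(3, math.ceil((pts[:, 2].max() - zmin) / 0.5))
    counts = [0] * nb
    for p in pts:
        counts[min(int((p[2] - zmin) // 0.5), nb - 1)] += 1
    smooth = [
        (counts[max(i - 1, 0)] * (i > 0) + counts[i] + (counts[i + 1] if i + 1 < nb else 0)) / 3.0
        for i in range(nb)
    ]
    peaks = [i for i in range(1, nb - 1) if smooth[i] > smooth[i - 1] and smooth[i] >= smooth[i + 1]]
    bin_mids = [zmin + (i + 0.5) * 0.5 - dtm_z for i in range(nb)]
    if peaks:
        h_lls, h_hls = bin_mids[peaks[0]], bin_mids[peaks[-1]]
    else:
        h_lls = h_hls = bin_mids[int(np.argmax(smooth))]
    llls_lhls = 1.0 if h_lls == h_hls or abs(Ht - h_hls) < 1e-12 else (Ht - h_lls) / (Ht - h_hls)

    ls_lcs = (mids[int(np.argmax(point_layers))] - crown_base) / Lc
    Gc = sum(centres[k][2] - dtm_z for k in voxels) / len(voxels)

    def coverage(uv):
        uv = np.asarray(uv, dtype=float)
        o = uv.min(axis=0)
        cells = {tuple(int((p[i] - o[i]) // grid_cell) for i in range(2)) for p in uv}
        area = hull_area_2d(uv)
        return len(cells) * grid_cell**2 / area if area > 0 else 0.0

    P_L = 0.5 * (coverage(crown[:, [0, 2]]) + coverage(crown[:, [1, 2]]))
    LAI_proj = coverage(crown[:, :2])

    return {
        "P1": P1, "P2": P2, "P3": P3, "P4": P4, "P5": P5, "P6": P6, "P7": P7,
        "P8": P8, "P9": P9, "P10": P10, "P11": P11, "P12": P12, "P13": P13,
        "Ht": Ht, "LcHt": LcHt, "D_EA": D_EA, "Alpha": Alpha, "LcD_EA": LcD_EA,
        "llls_lhls_proxy": llls_lhls, "ls_lcs_proxy": ls_lcs, "Gc": Gc,
        "P_L": P_L, "LAI_proj": LAI_proj,
    }
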