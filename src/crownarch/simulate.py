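"""Synthetic ALS-like tree clouds for four crown archetypes.

Each archetype is a point-placement recipe emulating the structural
signature of one Hallé architecture model, so that every pipeline stage is
testable without field data:

* ``massart_tiered`` — laser returns concentrated on horizontal annular
  discs at regular tier heights inside a conical envelope (plagiotropic
  whorls, rhythmic growth; Norway-spruce-like, species PA);
* ``rauh_clustered`` — a few upward-elongated point clusters in the upper
  crown over a short crown fraction (orthotropic rhythmic tufts;
  Scots-pine-like, PS);
* ``roux_layered`` — branch clumps spread uniformly over the whole crown
  height plus a populated stem space (continuous plagiotropic growth;
  aspen-like, PT);
* ``attim_columnar`` — near-uniform dense columnar fill (continuous
  orthotropic growth; oak-like, QR).

Tree height and crown length are drawn uniformly from species-typical
boreal ranges; clouds are thinned by Poisson subsampling over the
projected-crown hull to an areal density of ~10 points/m^2 and given
Gaussian positional noise.  The recipes are a test harness guided by the
models' qualitative descriptions, not a claim about real species.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .io import DegenerateInputError, TreeCloud, write_xyz

__all__ = [
    "ArchetypeConfig",
    "DEFAULT_CONFIGS",
    "DEFAULT_COMPOSITION",
    "simulate_tree",
    "simulate_stand",
    "write_stand",
]

ARCHETYPES = ("massart_tiered", "rauh_clustered", "roux_layered", "attim_columnar")


@dataclass(frozen=True)
class ArchetypeConfig:
    """Generator settings for one species archetype.

    ``structure_count`` is the number of tiers / clusters / clumps
    (archetype-dependent); ``concentration`` the fraction of points placed
    in those structured elements rather than diffuse filler; ``density``
    the target areal density in points/m^2 over the projected crown.
    """

    species: str
    archetype: str
    height_range: tuple[float, float]  # m
    crown_length_range: tuple[float, float]  # m
    crown_radius_range: tuple[float, float]  # m
    structure_count: int
    concentration: float = 0.85
    density: float = 10.0  # points / m^2
    noise_sd: float = 0.10  # m

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        for name in ("height_range", "crown_length_range", "crown_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered, got ({lo}, {hi})")
        if self.density <= 0:
            raise ValueError("density must be > 0")


# Height and crown-length ranges are species-typical boreal values for the
# 40-tree reference stand; crown radii are realistic choices (narrow conical
# spruce through broad oak), see docs/methods.md.
DEFAULT_CONFIGS: dict[str, ArchetypeConfig] = {
    "PA": ArchetypeConfig(
        species="PA", archetype="massart_tiered",
        height_range=(17.60, 28.38), crown_length_range=(14.02, 27.38),
        crown_radius_range=(2.0, 3.5), structure_count=8,
    ),
    "PS": ArchetypeConfig(
        species="PS", archetype="rauh_clustered",
        height_range=(16.66, 23.73), crown_length_range=(5.67, 18.83),
        crown_radius_range=(2.5, 4.0), structure_count=3, concentration=0.92,
    ),
    "PT": ArchetypeConfig(
        species="PT", archetype="roux_layered",
        height_range=(20.39, 25.98), crown_length_range=(11.64, 20.11),
        crown_radius_range=(2.5, 4.0), structure_count=3, concentration=0.54,
    ),
    "QR": ArchetypeConfig(
        species="QR", archetype="attim_columnar",
        height_range=(15.17, 25.94), crown_length_range=(13.81, 18.94),
        crown_radius_range=(3.0, 5.0), structure_count=1,
    ),
}

# reference stand composition: 9 spruce, 14 pine, 7 aspen, 10 oak
DEFAULT_COMPOSITION: dict[str, int] = {"PA": 9, "PS": 14, "PT": 7, "QR": 10}


def _balanced_azimuths(rng, k):
    """Azimuths spread around the trunk (phyllotactic balance) with jitter
    and a random global rotation."""
    return (
        2 * np.pi * (np.arange(k) + rng.uniform(-0.25, 0.25, k)) / k
        + rng.uniform(0, 2 * np.pi)
    )


def _massart(rng, n, base, top, rc, tiers):
    """Annular whorl discs at regular tier heights in a conical envelope.

    Branch whorls leave the trunk surroundings open (annulus inner radius
    55% of the local envelope), so the stem space stays sparse; the narrow
    topmost disc concentrates roughly one tier weight of returns in a
    single super-voxel.
    """
    lc = top - base
    tier_frac = (np.arange(tiers) + 0.5) / tiers
    tier_z = base + tier_frac * lc
    tier_r = np.maximum(rc * (1.0 - 0.85 * tier_frac), 0.35)
    which = rng.integers(tiers, size=n)
    r_out = tier_r[which]
    r = r_out * np.sqrt(rng.uniform(0.62**2, 1.0, n))
    theta = rng.uniform(0, 2 * np.pi, n)
    z = tier_z[which] + rng.normal(0, 0.10, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _rauh(rs, rng, n, base, top, rc, clusters, concentration):
    """Tight upward-elongated clusters in the upper crown plus sparse filler,
    placed off-axis so the stem space stays almost empty.  ``rs`` draws the
    branch structure, ``rng`` the individual returns."""
    lc = top - base
    cz = rs.uniform(base + 0.45 * lc, top - 0.05 * lc, clusters)
    cr = rs.uniform(0.55 * rc, 0.75 * rc, clusters)
    # branches surround the trunk: balanced azimuths with jitter
    ct = _balanced_azimuths(rs, clusters)
    cx, cy = cr * np.cos(ct), cr * np.sin(ct)
    n_cl = int(round(concentration * n))
    which = np.resize(np.arange(clusters), n_cl)  # equal-weight clusters
    pts_cl = np.column_stack(
        [
            cx[which] + rng.normal(0, 0.10, n_cl),
            cy[which] + rng.normal(0, 0.10, n_cl),
            # bounded vertical extent: a branch tuft has a finite length
            cz[which] + rng.uniform(-0.6, 0.6, n_cl),
        ]
    )
    n_bg = n - n_cl
    r = rc * np.sqrt(rng.uniform(0.50**2, 0.90**2, n_bg))
    theta = rng.uniform(0, 2 * np.pi, n_bg)
    # filler shares the clusters' zone: the live pine crown is the short
    # upper fraction, and crown-base detection anchors on its dense bottom
    z = rng.uniform(base + 0.45 * lc, top, n_bg)
    pts_bg = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return np.vstack([pts_cl, pts_bg])


def _roux(rs, rng, n, base, top, rc, clumps, concentration):
    """Branch clumps at uniform heights (continuous growth), a thin populated
    stem sleeve, and an annular branch background."""
    lc = top - base
    cz = rs.uniform(base + 0.05 * lc, top - 0.02 * lc, clumps)
    cr = rs.uniform(0.65 * rc, 0.85 * rc, clumps)
    ct = _balanced_azimuths(rs, clumps)
    cx, cy = cr * np.cos(ct), cr * np.sin(ct)
    n_cl = int(round(concentration * n))
    n_stem = int(round(0.03 * n))
    n_bg = n - n_cl - n_stem
    which = np.resize(np.arange(clumps), n_cl)  # equal-weight clumps
    pts_cl = np.column_stack(
        [
            cx[which] + rng.normal(0, 0.08, n_cl),
            cy[which] + rng.normal(0, 0.08, n_cl),
            cz[which] + rng.normal(0, 0.08, n_cl),
        ]
    )
    # stem space: continuous thin sleeve of returns along the trunk
    r = 0.25 * np.sqrt(rng.uniform(0, 1, n_stem))
    theta = rng.uniform(0, 2 * np.pi, n_stem)
    z = rng.uniform(base, top, n_stem)
    pts_stem = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    r = rc * np.sqrt(rng.uniform(0.50**2, 1.0, n_bg))
    theta = rng.uniform(0, 2 * np.pi, n_bg)
    z = rng.uniform(base, top, n_bg)
    pts_bg = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return np.vstack([pts_cl, pts_stem, pts_bg])


def _attim(rs, rng, n, base, top, rc, clumps):
    """Near-uniform columnar fill, clumpy at the sub-metre scale the way a
    dense leafy crown is (55% of returns in a few foliage clumps)."""
    n_cl = int(round(0.55 * n))
    cz = rs.uniform(base + 0.05 * (top - base), top, clumps)
    cr = rc * np.sqrt(rs.uniform(0.55**2, 0.85**2, clumps))
    ct = _balanced_azimuths(rs, clumps)
    cx, cy = cr * np.cos(ct), cr * np.sin(ct)
    which = np.resize(np.arange(clumps), n_cl)  # equal-weight clumps
    pts_cl = np.column_stack(
        [
            cx[which] + rng.normal(0, 0.35, n_cl),
            cy[which] + rng.normal(0, 0.35, n_cl),
            cz[which] + rng.normal(0, 0.35, n_cl),
        ]
    )
    n_bg = n - n_cl
    r = rc * np.sqrt(rng.uniform(0, 1, n_bg))
    theta = rng.uniform(0, 2 * np.pi, n_bg)
    z = rng.uniform(base, top, n_bg)
    pts_bg = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return np.vstack([pts_cl, pts_bg])


def simulate_tree(
    config: ArchetypeConfig,
    rng_seed: int | np.random.SeedSequence,
    tree_id: str | None = None,
) -> TreeCloud:
    """Generate one labeled ALS-like tree cloud (deterministic per seed).

    Crown dimensions are drawn uniformly from the config ranges (crown
    length capped at 92% of the height); the archetype recipe produces an
    oversampled candidate crown, Gaussian noise is added, and the cloud is
    thinned by Poisson subsampling to ``density`` points/m^2 over the
    projected-crown convex hull.  A sparse line of stem returns below the
    crown exercises crown-base detection.

    Randomness is split into three substreams (tree geometry/branch
    structure, crown returns, stem returns) so that the same seed yields
    the same tree *geometry* at any sampling density.
    """
    ss = rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    rs, rng, rstem = (np.random.default_rng(c) for c in ss.spawn(3))
    h = rs.uniform(*config.height_range)
    lc = min(rs.uniform(*config.crown_length_range), 0.92 * h)
    rc = rs.uniform(*config.crown_radius_range)
    base, top = h - lc, h

    n_cand = max(int(6 * config.density * np.pi * rc**2), 800)
    k = config.structure_count
    if config.archetype == "massart_tiered":
        crown = _massart(rng, n_cand, base, top, rc, k)
    elif config.archetype == "rauh_clustered":
        crown = _rauh(rs, rng, n_cand, base, top, rc, k, config.concentration)
    elif config.archetype == "roux_layered":
        crown = _roux(rs, rng, n_cand, base, top, rc, k, config.concentration)
    else:
        crown = _attim(rs, rng, n_cand, base, top, rc, max(k, 1) * 3)
    crown = crown + rng.normal(0, config.noise_sd, crown.shape)

    try:
        a_proj = float(ConvexHull(crown[:, :2]).volume)
    except QhullError:  # pragma: no cover - candidates are never collinear
        a_proj = np.pi * rc**2
    n_target = int(rng.poisson(config.density * a_proj))
    if n_target < crown.shape[0]:
        keep = rng.choice(crown.shape[0], size=n_target, replace=False)
        crown = crown[keep]
    if crown.shape[0] < 10:
        raise DegenerateInputError(
            f"density {config.density} too low: only {crown.shape[0]} points generated"
        )

    # sparse stem returns below the crown (well under the crown-base
    # detection threshold: ~1 return per 1.2 m of trunk)
    if base > 2.0:
        n_stem = int((base - 0.8) / 1.2)
        if n_stem > 0:
            z = np.linspace(0.8, base - 0.4, n_stem) + rstem.normal(0, 0.1, n_stem)
            xy = rstem.normal(0, 0.12, (n_stem, 2))
            crown = np.vstack([crown, np.column_stack([xy, z])])

    offset = rstem.uniform(-25, 25, 2)
    crown[:, :2] += offset
    return TreeCloud(
        tree_id=tree_id or f"{config.species}-sim",
        points=crown,
        dtm_z=0.0,
        species=config.species,
    )


def simulate_stand(
    per_species_counts: dict[str, int] | None = None,
    configs: dict[str, ArchetypeConfig] | None = None,
    seed: int = 0,
) -> tuple[list[TreeCloud], pd.DataFrame]:
    """Generate a labeled stand of trees plus its manifest.

    The default composition is the 9/14/7/10 (PA/PS/PT/QR) reference
    stand.  Per-tree seeds are spawned deterministically from ``seed``.
    """
    counts = dict(DEFAULT_COMPOSITION if per_species_counts is None else per_species_counts)
    configs = dict(DEFAULT_CONFIGS if configs is None else configs)
    for sp, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count for species {sp!r}")
        if c > 0 and sp not in configs:
            raise ValueError(f"no archetype config for species {sp!r}")
    ss = np.random.SeedSequence(seed)
    total = sum(counts.values())
    children = ss.spawn(total)
    clouds: list[TreeCloud] = []
    rows = []
    i = 0
    for sp in counts:
        for j in range(counts[sp]):
            tree_id = f"{sp}{j + 1:02d}"
            cloud = simulate_tree(configs[sp], children[i], tree_id=tree_id)
            clouds.append(cloud)
            rows.append(
                {
                    "tree_id": tree_id,
                    "path": f"{tree_id}.xyz",
                    "dtm_z": cloud.dtm_z,
                    "species": sp,
                    "archetype": configs[sp].archetype,
                    "n_points": cloud.n_points,
                }
            )
            i += 1
    return clouds, pd.DataFrame(rows)


def write_stand(
    clouds: list[TreeCloud], manifest: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write per-tree XYZ files and the manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cloud, path in zip(clouds, manifest["path"]):
        write_xyz(out / path, cloud.points)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
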