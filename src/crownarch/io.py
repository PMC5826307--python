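"""Per-tree point-cloud input/output.

A *tree cloud* is the set of laser returns segmented for one tree, together
with the ground elevation (DTM value) at its stem foot.  Heights above
ground are always derived downstream as ``z - dtm_z``; this module never
modifies coordinates.

Supported on-disk formats:

* whitespace-separated XYZ text (three leading numeric columns; extra
  columns ignored; ``#`` comments allowed),
* uncompressed LAS 1.x, point record formats 0-5 (coordinates only).

LAS support is a deliberately minimal reader/writer: the LAS point record
layout is a fixed binary header plus scaled int32 triplets, which numpy
structured dtypes read directly.  Compressed LAZ is not supported.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TreeCloud",
    "DegenerateInputError",
    "read_tree_cloud",
    "read_manifest",
    "write_xyz",
    "write_las",
]

MIN_POINTS = 10

SPECIES_CODES = ("PA", "PS", "PT", "QR")


class DegenerateInputError(ValueError):
    """Input violates a structural precondition (too few points, no height...)."""


@dataclass(frozen=True)
class TreeCloud:
    """One tree's 3-D laser returns plus ground reference.

    Parameters
    ----------
    tree_id : str
        Identifier used in error messages and output tables.
    points : (n, 3) ndarray
        x, y, z coordinates in metres.  ``n >= 10``, all finite.
    dtm_z : float
        Ground elevation in metres at the stem foot; ``max(z) > dtm_z``.
    species : str or None
        Species label (``PA``, ``PS``, ``PT``, ``QR`` or free text).
    """

    tree_id: str
    points: np.ndarray
    dtm_z: float
    species: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise DegenerateInputError(
                f"tree {self.tree_id!r}: points must be (n, 3), got {pts.shape}"
            )
        if pts.shape[0] < MIN_POINTS:
            raise DegenerateInputError(
                f"tree {self.tree_id!r}: {pts.shape[0]} points < required {MIN_POINTS}"
            )
        if not np.all(np.isfinite(pts)):
            raise DegenerateInputError(f"tree {self.tree_id!r}: non-finite coordinates")
        if not np.isfinite(self.dtm_z):
            raise DegenerateInputError(f"tree {self.tree_id!r}: non-finite dtm_z")
        if float(pts[:, 2].max()) <= float(self.dtm_z):
            raise DegenerateInputError(
                f"tree {self.tree_id!r}: max(z)={pts[:, 2].max():.3f} does not "
                f"exceed dtm_z={self.dtm_z:.3f}"
            )
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "dtm_z", float(self.dtm_z))

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def height(self) -> float:
        """Tree height Ht = max(z) - dtm_z in metres."""
        return float(self.points[:, 2].max() - self.dtm_z)


# ---------------------------------------------------------------------------
# minimal LAS 1.x (uncompressed) support

_LAS_SIGNATURE = b"LASF"
# point record length for formats 0..5 (xyz int32 + attributes we skip)
_LAS_MIN_RECLEN = {0: 20, 1: 28, 2: 26, 3: 34, 4: 57, 5: 63}


def _read_las_xyz(path: Path) -> np.ndarray:
    raw = path.read_bytes()
    if raw[:4] != _LAS_SIGNATURE:
        raise IOError(f"{path}: not a LAS file (bad signature)")
    if len(raw) < 227:
        raise IOError(f"{path}: truncated LAS header")
    ver_major, ver_minor = raw[24], raw[25]
    (offset_to_points,) = struct.unpack_from("<I", raw, 96)
    point_format = raw[104]
    if point_format & 0x80:  # compression bit set by LAZ writers
        raise IOError(f"{path}: compressed LAZ is not supported; decompress first")
    (rec_len,) = struct.unpack_from("<H", raw, 105)
    (n_legacy,) = struct.unpack_from("<I", raw, 107)
    scale = np.array(struct.unpack_from("<3d", raw, 131))
    offset = np.array(struct.unpack_from("<3d", raw, 155))
    n_points = n_legacy
    if n_points == 0 and ver_major == 1 and ver_minor >= 4 and len(raw) >= 247 + 8:
        (n_points,) = struct.unpack_from("<Q", raw, 247)
    if point_format in _LAS_MIN_RECLEN and rec_len < _LAS_MIN_RECLEN[point_format]:
        raise IOError(f"{path}: record length {rec_len} too short for format {point_format}")
    body = raw[offset_to_points : offset_to_points + n_points * rec_len]
    if len(body) < n_points * rec_len:
        raise IOError(f"{path}: truncated point records")
    rec = np.frombuffer(body, dtype=np.dtype([("xyz", "<i4", (3,)), ("rest", f"V{rec_len - 12}")]))
    return rec["xyz"].astype(float) * scale + offset


def write_las(path: str | Path, points: np.ndarray, scale: float = 0.001) -> None:
    """Write xyz coordinates as an uncompressed LAS 1.2, point format 0 file."""
    pts = np.asarray(points, dtype=float)
    offset = pts.min(axis=0)
    header = bytearray(227)
    header[0:4] = _LAS_SIGNATURE
    header[24] = 1  # version major
    header[25] = 2  # version minor
    struct.pack_into("<H", header, 94, 227)  # header size
    struct.pack_into("<I", header, 96, 227)  # offset to point data
    header[104] = 0  # point data format
    struct.pack_into("<H", header, 105, 20)  # record length
    struct.pack_into("<I", header, 107, len(pts))
    struct.pack_into("<3d", header, 131, scale, scale, scale)
    struct.pack_into("<3d", header, 155, *offset)
    struct.pack_into("<3d", header, 179, pts[:, 0].max(), pts[:, 0].min(), pts[:, 1].max())
    struct.pack_into("<3d", header, 203, pts[:, 1].min(), pts[:, 2].max(), pts[:, 2].min())
    rec = np.zeros(len(pts), dtype=np.dtype([("xyz", "<i4", (3,)), ("rest", "V8")]))
    rec["xyz"] = np.round((pts - offset) / scale).astype(np.int64)
    Path(path).write_bytes(bytes(header) + rec.tobytes())


def write_xyz(path: str | Path, points: np.ndarray, fmt: str = "%.3f") -> None:
    """Write points as 3-column whitespace XYZ text."""
    np.savetxt(path, np.asarray(points, dtype=float), fmt=fmt)


def read_tree_cloud(
    path: str | Path,
    dtm_z: float,
    tree_id: str | None = None,
    species: str | None = None,
) -> TreeCloud:
    """Read one tree's point cloud from an XYZ text or uncompressed LAS file.

    Coordinates are returned unmodified; heights above ground are computed
    downstream as ``z - dtm_z``.

    Raises
    ------
    IOError
        Unreadable or unsupported file.
    DegenerateInputError
        Fewer than 10 points, naming the tree id.
    """
    path = Path(path)
    if tree_id is None:
        tree_id = path.stem
    if not path.exists():
        raise IOError(f"point-cloud file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".laz":
        raise IOError(f"{path}: compressed LAZ is not supported; decompress first")
    if suffix == ".las":
        pts = _read_las_xyz(path)
    else:
        try:
            pts = np.loadtxt(path, comments="#", ndmin=2)
        except ValueError as exc:
            raise IOError(f"{path}: could not parse XYZ text ({exc})") from exc
        if pts.size == 0 or pts.shape[1] < 3:
            raise IOError(f"{path}: expected at least 3 numeric columns")
        pts = pts[:, :3]
    return TreeCloud(tree_id=tree_id, points=pts, dtm_z=dtm_z, species=species)


def read_manifest(path: str | Path, base_dir: str | Path | None = None) -> list[TreeCloud]:
    """Read a per-tree manifest CSV (columns: tree_id, path, dtm_z, species).

    Relative cloud paths are resolved against ``base_dir`` (default: the
    manifest's directory).
    """
    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    df = pd.read_csv(path)
    required = {"tree_id", "path", "dtm_z"}
    missing = required - set(df.columns)
    if missing:
        raise IOError(f"{path}: manifest missing columns {sorted(missing)}")
    clouds = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        species = getattr(row, "species", None)
        if species is not None and pd.isna(species):
            species = None
        clouds.append(
            read_tree_cloud(p, dtm_z=float(row.dtm_z), tree_id=str(row.tree_id), species=species)
        )
    return clouds
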