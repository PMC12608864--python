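"""Labeled plant point clouds: container, PLY/XYZ I/O and normal estimation.

A :class:`LabeledCloud` holds XYZ coordinates in meters (z up, gravity
aligned), optional unit normals, optional per-point semantic labels
(0 = background, 1 = stem, 2 = leaf) and optional instance ids (−1 = none,
0..K−1 = leaf instances).  On disk, clouds are PLY files (ASCII or binary
little-endian) whose vertex element may carry ``nx, ny, nz`` as doubles and
``semantic``/``instance`` as 32-bit ints, or whitespace-delimited XYZ text
with optional label columns 4–5.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.neighbors import NearestNeighbors

BACKGROUND, STEM, LEAF = 0, 1, 2
SEMANTIC_NAMES = {BACKGROUND: "background", STEM: "stem", LEAF: "leaf"}

__all__ = [
    "LabeledCloud", "read_cloud", "write_cloud", "estimate_normals",
    "BACKGROUND", "STEM", "LEAF", "CloudFormatError",
]


class CloudFormatError(ValueError):
    """Malformed point-cloud file (bad rows, non-finite values, bad header)."""


@dataclass
class LabeledCloud:
    points: np.ndarray
    normals: Optional[np.ndarray] = None
    semantic: Optional[np.ndarray] = None
    instance: Optional[np.ndarray] = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
        if self.semantic is not None:
            self.semantic = np.asarray(self.semantic, dtype=np.int32).reshape(-1)
        if self.instance is not None:
            self.instance = np.asarray(self.instance, dtype=np.int32).reshape(-1)
        self.validate()

    def __len__(self) -> int:
        return self.points.shape[0]

    def validate(self) -> None:
        n = len(self)
        if not np.isfinite(self.points).all():
            raise CloudFormatError("non-finite coordinates in cloud")
        if self.normals is not None:
            if self.normals.shape != (n, 3):
                raise CloudFormatError("normals shape mismatch")
            if n and not np.allclose(np.linalg.norm(self.normals, axis=1), 1.0, atol=1e-6):
                raise CloudFormatError("normals are not unit length")
        for name, arr in (("semantic", self.semantic), ("instance", self.instance)):
            if arr is not None and arr.shape != (n,):
                raise CloudFormatError(f"{name} length != point count")

    def select(self, idx) -> "LabeledCloud":
        return LabeledCloud(
            self.points[idx],
            None if self.normals is None else self.normals[idx],
            None if self.semantic is None else self.semantic[idx],
            None if self.instance is None else self.instance[idx],
        )

    @property
    def height(self) -> float:
        """Extent along +z; the plant height used by the slicer."""
        if len(self) == 0:
            return 0.0
        z = self.points[:, 2]
        return float(z.max() - z.min())


# --------------------------------------------------------------------------
# PLY dialect
# --------------------------------------------------------------------------

_PLY_FLOAT = {"float": "f4", "float32": "f4", "double": "f8", "float64": "f8"}
_PLY_INT = {"char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
            "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
            "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4"}


def _ply_dtype(name: str) -> str:
    if name in _PLY_FLOAT:
        return _PLY_FLOAT[name]
    if name in _PLY_INT:
        return _PLY_INT[name]
    raise CloudFormatError(f"unsupported ply property type: {name}")


def _read_ply(path: Path) -> LabeledCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise CloudFormatError(f"{path}: not a ply file")
        fmt = None
        n_vertex = 0
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise CloudFormatError(f"{path}: truncated ply header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise CloudFormatError(f"{path}: list property on vertex element")
                props.append((tokens[2], _ply_dtype(tokens[1])))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise CloudFormatError(f"{path}: unsupported ply format {fmt}")
        names = [p[0] for p in props]
        for axis in "xyz":
            if axis not in names:
                raise CloudFormatError(f"{path}: vertex element lacks {axis}")
        if fmt == "ascii":
            raw = fh.read().decode("ascii", "replace").split()
            expected = n_vertex * len(props)
            if len(raw) < expected:
                raise CloudFormatError(f"{path}: expected {expected} vertex values")
            cols = np.array(raw[:expected], dtype=np.float64).reshape(n_vertex, len(props))
            rec = {name: cols[:, i] for i, (name, _) in enumerate(props)}
        else:
            dtype = np.dtype([(name, "<" + code) for name, code in props])
            buf = fh.read(dtype.itemsize * n_vertex)
            if len(buf) != dtype.itemsize * n_vertex:
                raise CloudFormatError(f"{path}: truncated binary vertex data")
            arr = np.frombuffer(buf, dtype=dtype)
            rec = {name: arr[name] for name, _ in props}
    points = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(np.float64)
    if not np.isfinite(points).all():
        bad = int(np.argwhere(~np.isfinite(points).all(axis=1))[0, 0])
        raise CloudFormatError(f"{path}: non-finite coordinate at vertex {bad}")
    normals = None
    if all(k in rec for k in ("nx", "ny", "nz")):
        normals = np.column_stack([rec["nx"], rec["ny"], rec["nz"]]).astype(np.float64)
    semantic = rec["semantic"].astype(np.int32) if "semantic" in rec else None
    instance = rec["instance"].astype(np.int32) if "instance" in rec else None
    return LabeledCloud(points, normals, semantic, instance)


def _write_ply(cloud: LabeledCloud, path: Path, binary: bool = True) -> None:
    props = [("x", "double"), ("y", "double"), ("z", "double")]
    columns = [cloud.points[:, 0], cloud.points[:, 1], cloud.points[:, 2]]
    if cloud.normals is not None:
        props += [("nx", "double"), ("ny", "double"), ("nz", "double")]
        columns += [cloud.normals[:, 0], cloud.normals[:, 1], cloud.normals[:, 2]]
    if cloud.semantic is not None:
        props.append(("semantic", "int"))
        columns.append(cloud.semantic)
    if cloud.instance is not None:
        props.append(("instance", "int"))
        columns.append(cloud.instance)
    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0", f"element vertex {len(cloud)}"]
    header += [f"property {t} {n}" for n, t in props]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            dtype = np.dtype([(n, "<f8" if t == "double" else "<i4") for n, t in props])
            out = np.empty(len(cloud), dtype=dtype)
            for (name, _), col in zip(props, columns):
                out[name] = col
            fh.write(out.tobytes())
        else:
            for i in range(len(cloud)):
                row = []
                for (name, t), col in zip(props, columns):
                    row.append(repr(float(col[i])) if t == "double" else str(int(col[i])))
                fh.write((" ".join(row) + "\n").encode("ascii"))


# --------------------------------------------------------------------------
# XYZ dialect
# --------------------------------------------------------------------------

def _read_xyz(path: Path) -> LabeledCloud:
    rows = []
    width = None
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if width is None:
                width = len(parts)
                if width not in (3, 4, 5):
                    raise CloudFormatError(f"{path}:{lineno}: expected 3–5 columns, got {width}")
            elif len(parts) != width:
                raise CloudFormatError(f"{path}:{lineno}: ragged row ({len(parts)} columns)")
            try:
                rows.append([float(v) for v in parts])
            except ValueError:
                raise CloudFormatError(f"{path}:{lineno}: non-numeric value") from None
    data = np.asarray(rows, dtype=np.float64).reshape(-1, width or 3)
    if data.size and not np.isfinite(data[:, :3]).all():
        bad = int(np.argwhere(~np.isfinite(data[:, :3]).all(axis=1))[0, 0])
        raise CloudFormatError(f"{path}: non-finite coordinate in record {bad}")
    semantic = data[:, 3].astype(np.int32) if width and width >= 4 else None
    instance = data[:, 4].astype(np.int32) if width and width >= 5 else None
    return LabeledCloud(data[:, :3], None, semantic, instance)


def _write_xyz(cloud: LabeledCloud, path: Path) -> None:
    import warnings

    cols = [cloud.points]
    header = "# x y z"
    if cloud.semantic is not None or cloud.instance is not None:
        warnings.warn("xyz format: labels appended as extra columns", stacklevel=3)
        semantic = cloud.semantic if cloud.semantic is not None else np.zeros(len(cloud), np.int32)
        cols.append(semantic[:, None].astype(np.float64))
        header += " semantic"
        if cloud.instance is not None:
            cols.append(cloud.instance[:, None].astype(np.float64))
            header += " instance"
    data = np.hstack(cols)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row[:3]))
            for v in row[3:]:
                fh.write(f" {int(v)}")
            fh.write("\n")


# --------------------------------------------------------------------------
# Public API
# --------------------------------------------------------------------------

def read_cloud(path, format: str = "auto") -> LabeledCloud:
    """Read a PLY or XYZ point cloud; ``auto`` dispatches on the extension."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "auto":
        format = "ply" if path.suffix.lower() == ".ply" else "xyz"
    if format == "ply":
        return _read_ply(path)
    if format == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown format: {format!r}")


def write_cloud(cloud: LabeledCloud, path, format: str = "ply", binary: bool = True) -> None:
    cloud.validate()
    path = Path(path)
    if format == "ply":
        _write_ply(cloud, path, binary=binary)
    elif format == "xyz":
        _write_xyz(cloud, path)
    else:
        raise ValueError(f"unknown format: {format!r}")


def orient_normals(normals: np.ndarray) -> np.ndarray:
    """Flip each normal into the +z hemisphere (ties cascade to +x, then +y)."""
    normals = np.asarray(normals, dtype=np.float64).copy()
    undecided = np.ones(len(normals), dtype=bool)
    for axis in (2, 0, 1):
        comp = normals[:, axis].copy()
        flip = undecided & (comp < 0)
        normals[flip] *= -1.0
        undecided &= comp == 0
    return normals


def estimate_normals(cloud: LabeledCloud, k: int = 16) -> LabeledCloud:
    """Per-point normals from the smallest eigenvector of the k-NN covariance.

    The neighborhood is the point itself plus its k nearest neighbors; the
    sign is fixed to the +z hemisphere.  Returns a new cloud.
    """
    n = len(cloud)
    if k < 3:
        raise ValueError("k must be >= 3")
    if n <= k:
        raise ValueError(f"need at least k+1={k + 1} points, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(cloud.points)
    _, idx = nn.kneighbors(cloud.points)
    neigh = cloud.points[idx]                        # (n, k+1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nij,nik->njk", centered, centered) / (k + 1)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]                          # smallest eigenvalue
    normals = orient_normals(normals)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.where(norms > 0, norms, 1.0)
    return LabeledCloud(cloud.points, normals, cloud.semantic, cloud.instance)
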