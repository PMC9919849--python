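"""Point-cloud containers and file I/O.

The package works in a right-handed coordinate frame with all lengths in
meters.  In the raw sensor frame the rail travel axis is +z; after horizontal
calibration (:mod:`railphen.groundplane`) +z points vertically up.

Supported formats: PLY (ASCII and binary little-endian, vertex properties
``x, y, z[, intensity]``), whitespace XYZ tables, and CSV with a header.
Frame streams — the stand-in for the scanner's native packet capture — are a
directory of per-frame clouds named by index, or a single CSV with a
``frame`` column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PointCloud",
    "Frame",
    "FrameStream",
    "TraitTable",
    "read_cloud",
    "write_cloud",
    "read_frames",
    "write_frames",
    "write_traits",
    "read_traits",
    "CloudIOError",
]


class CloudIOError(ValueError):
    """Raised for malformed point-cloud files."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class PointCloud:
    """An ordered set of 3D points in meters, with optional echo intensity.

    Parameters
    ----------
    xyz:
        ``(n, 3)`` float64 array of coordinates (m).
    intensity:
        ``(n,)`` float64 array of unitless echo strengths in ``[0, 1]``.
        Defaults to zeros.
    source_tag:
        Free-text provenance label.
    aux:
        Optional integer provenance arrays of shape ``(n,)`` (e.g. the frame
        index each point was acquired in, or a simulator scene-point index).
        Carried through every geometric operation and subset.
    """

    xyz: np.ndarray
    intensity: np.ndarray | None = None
    source_tag: str = ""
    aux: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        n = self.xyz.shape[0]
        if not np.all(np.isfinite(self.xyz)):
            bad = int(np.flatnonzero(~np.isfinite(self.xyz).all(axis=1))[0])
            raise ValueError(f"non-finite coordinate at point {bad}")
        if self.intensity is None:
            self.intensity = np.zeros(n, dtype=np.float64)
        else:
            self.intensity = np.asarray(self.intensity, dtype=np.float64).reshape(-1)
            if self.intensity.shape[0] != n:
                raise ValueError("intensity length does not match point count")
            if n and (np.nanmin(self.intensity) < -1e-12 or np.nanmax(self.intensity) > 1 + 1e-12):
                raise ValueError("intensity must lie in [0, 1]")
        for key, arr in self.aux.items():
            a = np.asarray(arr)
            if a.shape[0] != n:
                raise ValueError(f"aux array {key!r} length does not match point count")
            self.aux[key] = a

    def __len__(self) -> int:
        return self.xyz.shape[0]

    # -- geometric ops ------------------------------------------------------

    def translated(self, d: np.ndarray) -> "PointCloud":
        """Return a copy rigidly translated by the 3-vector ``d`` (m)."""
        return PointCloud(self.xyz + np.asarray(d, dtype=np.float64).reshape(3),
                          self.intensity.copy(), self.source_tag,
                          {k: v.copy() for k, v in self.aux.items()})

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "PointCloud":
        """Return a copy under the rigid motion ``p -> R p + t``."""
        R = np.asarray(R, dtype=np.float64)
        t = np.asarray(t, dtype=np.float64).reshape(3)
        return PointCloud(self.xyz @ R.T + t, self.intensity.copy(), self.source_tag,
                          {k: v.copy() for k, v in self.aux.items()})

    def subset(self, index: np.ndarray) -> "PointCloud":
        """Select points by boolean mask or integer index, preserving order."""
        return PointCloud(self.xyz[index], self.intensity[index], self.source_tag,
                          {k: v[index] for k, v in self.aux.items()})

    @staticmethod
    def concat(clouds: Sequence["PointCloud"], source_tag: str = "") -> "PointCloud":
        """Concatenate clouds in order; aux keys present in *all* inputs survive."""
        if not clouds:
            return PointCloud(np.empty((0, 3)), source_tag=source_tag)
        keys = set(clouds[0].aux)
        for c in clouds[1:]:
            keys &= set(c.aux)
        aux = {k: np.concatenate([c.aux[k] for c in clouds]) for k in keys}
        return PointCloud(np.concatenate([c.xyz for c in clouds]),
                          np.concatenate([c.intensity for c in clouds]),
                          source_tag, aux)


@dataclass
class Frame:
    """One scanner sweep, treated as an instantaneous snapshot.

    ``points`` are in sensor-relative coordinates (sensor origin at the
    scanner's optical center for this frame; travel axis +z).
    """

    index: int
    points: PointCloud

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("frame index must be non-negative")


@dataclass
class FrameStream:
    """Time-ordered frames from one acquisition stop."""

    frames: list[Frame]
    rail_meta: object | None = None

    def __post_init__(self) -> None:
        idx = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_points(self) -> int:
        return sum(len(f.points) for f in self.frames)


@dataclass
class TraitTable:
    """Per-plant trait rows: id, height h (m), maximum crown width L (m)."""

    df: pd.DataFrame

    COLUMNS = ("plant_id", "height_m", "crown_width_m", "n_points", "cx", "cy")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"trait table missing columns {missing}")
        if self.df["plant_id"].duplicated().any():
            dup = self.df["plant_id"][self.df["plant_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate plant_id {dup!r}")
        self.df = self.df.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @staticmethod
    def from_rows(rows: Iterable[dict]) -> "TraitTable":
        rows = list(rows)
        df = pd.DataFrame(rows, columns=list(TraitTable.COLUMNS))
        return TraitTable(df)


# ---------------------------------------------------------------------------
# PLY

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}

_INTENSITY_NAMES = ("intensity", "scalar_intensity", "scalar_Intensity")


def _parse_ply_header(raw: bytes, path: Path):
    end = raw.find(b"end_header")
    if raw[:3] != b"ply" or end < 0:
        raise CloudIOError(f"{path}: not a PLY file (missing ply/end_header)")
    end_line = raw.find(b"\n", end)
    header = raw[: end_line].decode("ascii", errors="replace")
    body = raw[end_line + 1:]
    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    for lineno, line in enumerate(header.splitlines(), start=1):
        tok = line.strip().split()
        if not tok or tok[0] in ("ply", "comment", "obj_info"):
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if not elements:
                raise CloudIOError(f"{path}: line {lineno}: property before element")
            if tok[1] == "list":
                elements[-1][2].append((tok[-1], "list"))
            else:
                elements[-1][2].append((tok[-1], tok[1]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise CloudIOError(f"{path}: unsupported PLY format {fmt!r}")
    return fmt, elements, body


def _read_ply(path: Path) -> PointCloud:
    raw = path.read_bytes()
    fmt, elements, body = _parse_ply_header(raw, path)
    # locate the vertex element; elements before it must be fixed-size
    names = [e[0] for e in elements]
    if "vertex" not in names:
        raise CloudIOError(f"{path}: no vertex element in header")
    vi = names.index("vertex")
    count = elements[vi][1]
    props = elements[vi][2]
    if any(t == "list" for _, t in props):
        raise CloudIOError(f"{path}: list properties on vertex element are unsupported")
    pnames = [n for n, _ in props]
    for need in ("x", "y", "z"):
        if need not in pnames:
            raise CloudIOError(f"{path}: vertex element lacks property {need!r}")
    if fmt == "ascii":
        lines = body.decode("ascii", errors="replace").splitlines()
        # skip elements preceding vertex (one line per item)
        skip = sum(e[1] for e in elements[:vi])
        rows = np.empty((count, len(props)), dtype=np.float64)
        for i in range(count):
            line = lines[skip + i] if skip + i < len(lines) else ""
            parts = line.split()
            if len(parts) < len(props):
                raise CloudIOError(f"{path}: vertex line {i}: expected "
                                   f"{len(props)} values, got {len(parts)}")
            try:
                rows[i] = [float(v) for v in parts[: len(props)]]
            except ValueError as exc:
                raise CloudIOError(f"{path}: vertex line {i}: {exc}") from None
        data = {n: rows[:, j] for j, (n, _) in enumerate(props)}
    else:
        offset = 0
        for ename, ecount, eprops in elements[:vi]:
            if any(t == "list" for _, t in eprops):
                raise CloudIOError(f"{path}: binary list element {ename!r} before vertex")
            offset += ecount * sum(np.dtype("<" + _PLY_DTYPES[t]).itemsize for _, t in eprops)
        dtype = np.dtype([(n, "<" + _PLY_DTYPES[t]) for n, t in props])
        if len(body) - offset < count * dtype.itemsize:
            raise CloudIOError(f"{path}: truncated binary vertex data")
        arr = np.frombuffer(body, dtype=dtype, count=count, offset=offset)
        data = {n: arr[n].astype(np.float64) for n, _ in props}
    xyz = np.column_stack([data["x"], data["y"], data["z"]])
    bad = np.flatnonzero(~np.isfinite(xyz).all(axis=1))
    if bad.size:
        raise CloudIOError(f"{path}: non-finite coordinate at vertex {int(bad[0])}")
    intensity = None
    for name in _INTENSITY_NAMES:
        if name in data:
            intensity = data[name]
            break
    return PointCloud(xyz, intensity, source_tag=str(path))


def _write_ply(cloud: PointCloud, path: Path, binary: bool) -> None:
    n = len(cloud)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {n}\n"
        "property double x\n"
        "property double y\n"
        "property double z\n"
        "property double intensity\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            arr = np.empty(n, dtype=np.dtype([(c, "<f8") for c in ("x", "y", "z", "intensity")]))
            arr["x"], arr["y"], arr["z"] = cloud.xyz.T
            arr["intensity"] = cloud.intensity
            fh.write(arr.tobytes())
        else:
            for i in range(n):
                x, y, z = cloud.xyz[i]
                fh.write(f"{x:.6f} {y:.6f} {z:.6f} {cloud.intensity[i]:.6f}\n".encode("ascii"))


# ---------------------------------------------------------------------------
# XYZ / CSV


def _read_xyz(path: Path) -> PointCloud:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise CloudIOError(f"{path}: line {lineno}: expected 3 or 4 columns")
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise CloudIOError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        return PointCloud(np.empty((0, 3)), source_tag=str(path))
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise CloudIOError(f"{path}: inconsistent column counts")
    arr = np.asarray(rows, dtype=np.float64)
    intensity = arr[:, 3] if width == 4 else None
    return PointCloud(arr[:, :3], intensity, source_tag=str(path))


def _read_csv_cloud(path: Path) -> PointCloud:
    df = pd.read_csv(path)
    for need in ("x", "y", "z"):
        if need not in df.columns:
            raise CloudIOError(f"{path}: missing column {need!r}")
    intensity = df["intensity"].to_numpy(float) if "intensity" in df.columns else None
    return PointCloud(df[["x", "y", "z"]].to_numpy(float), intensity, source_tag=str(path))


def read_cloud(path, format: str | None = None) -> PointCloud:
    """Read a point cloud from PLY, XYZ, or CSV.

    ``format`` is inferred from the file extension when omitted.  Coordinates
    are interpreted as meters; unknown PLY vertex properties are ignored and
    an ``intensity`` property is picked up when present.  An empty file is an
    empty cloud, not an error.
    """
    path = Path(path)
    if format is None:
        format = {".ply": "ply", ".xyz": "xyz", ".csv": "csv", ".txt": "xyz"}.get(
            path.suffix.lower())
        if format is None:
            raise CloudIOError(f"{path}: cannot infer format from extension")
    if format == "ply":
        return _read_ply(path)
    if format == "xyz":
        return _read_xyz(path)
    if format == "csv":
        return _read_csv_cloud(path)
    raise CloudIOError(f"unknown format {format!r}")


def write_cloud(cloud: PointCloud, path, format: str | None = None) -> None:
    """Write a cloud re-readable by :func:`read_cloud`.

    ``format`` one of ``ply`` (ASCII), ``ply_binary`` (little-endian, exact
    and byte-stable), ``xyz``, ``csv``; inferred from the extension when
    omitted (``.ply`` defaults to ASCII).
    """
    path = Path(path)
    if format is None:
        format = {".ply": "ply", ".xyz": "xyz", ".csv": "csv", ".txt": "xyz"}.get(
            path.suffix.lower())
        if format is None:
            raise CloudIOError(f"{path}: cannot infer format from extension")
    if format == "ply":
        _write_ply(cloud, path, binary=False)
    elif format == "ply_binary":
        _write_ply(cloud, path, binary=True)
    elif format == "xyz":
        with open(path, "w") as fh:
            for i in range(len(cloud)):
                x, y, z = cloud.xyz[i]
                fh.write(f"{x:.6f} {y:.6f} {z:.6f} {cloud.intensity[i]:.6f}\n")
    elif format == "csv":
        pd.DataFrame({"x": cloud.xyz[:, 0], "y": cloud.xyz[:, 1], "z": cloud.xyz[:, 2],
                      "intensity": cloud.intensity}).to_csv(path, index=False,
                                                            float_format="%.6f")
    else:
        raise CloudIOError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# frame streams

_FRAME_RE = re.compile(r"(\d+)")


def read_frames(path) -> FrameStream:
    """Read a frame stream from a directory of per-frame clouds or one CSV.

    Directory entries are matched by the integer in their stem
    (``frame_0002.ply`` → index 2) and sorted ascending.  A CSV must carry
    columns ``x, y, z[, intensity], frame``; per-frame point order is the file
    row order, and duplicate rows are kept.
    """
    path = Path(path)
    frames: list[Frame] = []
    if path.is_dir():
        seen: dict[int, Path] = {}
        for p in sorted(path.iterdir()):
            if p.suffix.lower() not in (".ply", ".xyz", ".csv", ".txt"):
                continue
            m = _FRAME_RE.search(p.stem)
            if not m:
                raise CloudIOError(f"{p}: no frame index in filename")
            k = int(m.group(1))
            if k in seen:
                raise CloudIOError(f"duplicate frame index {k}: {seen[k]} and {p}")
            seen[k] = p
        for k in sorted(seen):
            frames.append(Frame(k, read_cloud(seen[k])))
    else:
        df = pd.read_csv(path)
        if "frame" not in df.columns:
            raise CloudIOError(f"{path}: missing 'frame' column")
        for need in ("x", "y", "z"):
            if need not in df.columns:
                raise CloudIOError(f"{path}: missing column {need!r}")
        ints = df["frame"].to_numpy()
        if not np.issubdtype(ints.dtype, np.integer):
            if not np.allclose(ints, np.round(ints)):
                raise CloudIOError(f"{path}: non-integer frame index")
            ints = np.round(ints).astype(int)
        for k in np.unique(ints):
            sub = df[ints == k]
            intensity = sub["intensity"].to_numpy(float) if "intensity" in df.columns else None
            frames.append(Frame(int(k), PointCloud(sub[["x", "y", "z"]].to_numpy(float),
                                                   intensity)))
    return FrameStream(frames)


def write_frames(stream: FrameStream, path) -> None:
    """Write a stream as one CSV with a ``frame`` column (read_frames inverse)."""
    path = Path(path)
    parts = []
    for f in stream.frames:
        parts.append(pd.DataFrame({
            "x": f.points.xyz[:, 0], "y": f.points.xyz[:, 1], "z": f.points.xyz[:, 2],
            "intensity": f.points.intensity,
            "frame": np.full(len(f.points), f.index, dtype=int)}))
    df = (pd.concat(parts, ignore_index=True) if parts
          else pd.DataFrame(columns=["x", "y", "z", "intensity", "frame"]))
    df.to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# trait tables


def write_traits(table: TraitTable, path) -> None:
    """Write the trait table as CSV with floats at 6 decimals."""
    df = table.df.copy()
    for col in ("height_m", "crown_width_m", "cx", "cy"):
        df[col] = df[col].map(lambda v: f"{v:.6f}")
    df["n_points"] = df["n_points"].astype(int)
    df.to_csv(path, index=False)


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path)
    return TraitTable(df)
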