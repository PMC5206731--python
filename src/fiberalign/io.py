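"""Tabular file formats: fiber tables, boundary tables, vector-field tables.

Fiber table (CSV with header): one row per polyline vertex, columns
``fiber_id, z_index, vertex_index, x, y``.  Simulated and extracted fibers
share this format, so either feeds the analysis.  An optional importer for
CT-FIRE MAT files converts that tool's vertex-list structure to the same
in-memory form and fails loudly on unknown layouts.

Vector-field tables carry one row per grid cell plus a comment header line
holding the grid metadata, so they round-trip to a full StackField.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd

from .circular import AlignmentVector
from .errors import FiberTableError
from .field import (
    VALID,
    CircularBoundary,
    GridCell,
    GridSpec,
    StackField,
    VectorField,
)
from .geometry import FiberPath

FIBER_COLUMNS = ["fiber_id", "z_index", "vertex_index", "x", "y"]
BOUNDARY_COLUMNS = ["z_index", "cx", "cy", "r"]
_META_PREFIX = "# fiberalign-field "

PathLike = Union[str, Path]


def write_fiber_table(
    fibers_by_slice: Union[Dict[int, Sequence[FiberPath]], Sequence[FiberPath]],
    path: PathLike,
) -> None:
    """Write fibers (one slice, or a {z_index: fibers} dict) as a CSV table."""
    if not isinstance(fibers_by_slice, dict):
        fibers_by_slice = {0: list(fibers_by_slice)}
    rows = []
    for z in sorted(fibers_by_slice):
        for f in fibers_by_slice[z]:
            for i, (x, y) in enumerate(f.vertices):
                rows.append((f.id, z, i, x, y))
    pd.DataFrame(rows, columns=FIBER_COLUMNS).to_csv(path, index=False)


def read_fiber_table(path: PathLike) -> Dict[int, List[FiberPath]]:
    """Read a fiber table into {z_index: [FiberPath, ...]} (sorted by id)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - message passthrough
        raise FiberTableError(f"{path}: cannot parse fiber table: {exc}") from exc
    missing = [c for c in FIBER_COLUMNS if c not in df.columns]
    if missing:
        raise FiberTableError(f"{path}: missing columns {missing}")
    for col in ("x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
            raise FiberTableError(
                f"{path}: non-numeric {col!r} value at line {line}"
            )
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df[["x", "y"]].isna().any().any():
        line = int(df.index[df[["x", "y"]].isna().any(axis=1)][0]) + 2
        raise FiberTableError(f"{path}: missing coordinate at line {line}")
    out: Dict[int, List[FiberPath]] = {}
    for (z, fid), grp in df.groupby(["z_index", "fiber_id"], sort=True):
        grp = grp.sort_values("vertex_index")
        if len(grp) < 2:
            raise FiberTableError(
                f"{path}: fiber {fid!r} in slice {z} has {len(grp)} vertex; need >= 2"
            )
        verts = grp[["x", "y"]].to_numpy(dtype=float)
        try:
            fiber = FiberPath(fid, verts)
        except ValueError as exc:
            raise FiberTableError(f"{path}: fiber {fid!r} in slice {z}: {exc}") from exc
        out.setdefault(int(z), []).append(fiber)
    if not out:
        raise FiberTableError(f"{path}: fiber table holds no fibers")
    return out


def write_boundary_table(
    boundaries: Dict[int, CircularBoundary], path: PathLike
) -> None:
    rows = [
        (z, b.center[0], b.center[1], b.radius)
        for z, b in sorted(boundaries.items())
    ]
    pd.DataFrame(rows, columns=BOUNDARY_COLUMNS).to_csv(path, index=False)


def read_boundary_table(path: PathLike) -> Dict[int, CircularBoundary]:
    """Read {z_index: CircularBoundary} from a CSV with columns z_index,cx,cy,r."""
    df = pd.read_csv(path)
    missing = [c for c in BOUNDARY_COLUMNS if c not in df.columns]
    if missing:
        raise FiberTableError(f"{path}: missing columns {missing}")
    out = {}
    for _, row in df.iterrows():
        out[int(row["z_index"])] = CircularBoundary(
            (float(row["cx"]), float(row["cy"])), float(row["r"])
        )
    return out


def read_ctfire_mat(path: PathLike) -> List[FiberPath]:
    """Import fibers from a CT-FIRE MAT file.

    Expects the vertex-list layout: a struct (``data`` or top level) with
    ``Fa`` — per-fiber vertex index lists — and ``Xa`` — the (n, 2) vertex
    coordinate array the indices (1-based) point into.  Any other layout
    raises rather than guessing.
    """
    from scipy.io import loadmat

    mat = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    root = mat.get("data", mat)
    fa = getattr(root, "Fa", None) if not isinstance(root, dict) else root.get("Fa")
    xa = getattr(root, "Xa", None) if not isinstance(root, dict) else root.get("Xa")
    if fa is None or xa is None:
        raise FiberTableError(
            f"{path}: unrecognized CT-FIRE layout (need 'Fa' and 'Xa' fields)"
        )
    xa = np.asarray(xa, dtype=float)
    if xa.ndim != 2 or xa.shape[1] != 2:
        raise FiberTableError(f"{path}: 'Xa' must be an (n, 2) vertex array")
    fibers = []
    for i, entry in enumerate(np.atleast_1d(fa)):
        v = getattr(entry, "v", entry)
        idx = np.atleast_1d(np.asarray(v)).astype(int).ravel() - 1
        if idx.size < 2 or idx.min() < 0 or idx.max() >= len(xa):
            raise FiberTableError(
                f"{path}: fiber {i}: vertex indices out of range or too few"
            )
        fibers.append(FiberPath(i, xa[idx]))
    if not fibers:
        raise FiberTableError(f"{path}: no fibers in file")
    return fibers


def write_vector_field(field: Union[VectorField, StackField], path: PathLike) -> None:
    """Write a vector field (or stack) as CSV with a metadata comment line.

    One row per grid cell: position, z_index, status, alignment length and
    axial angle (empty when undefined/excluded), and the segment count in
    the sampling circle.  Valid-cell values round-trip losslessly.
    """
    stack = field if isinstance(field, StackField) else StackField([field])
    g = stack.fields[0].grid
    meta = {
        "image_width": g.image_width,
        "image_height": g.image_height,
        "spacing": g.spacing,
        "circle_radius": g.circle_radius,
        "min_fiber_count": g.min_fiber_count,
        "pixel_size": stack.fields[0].pixel_size,
        "z_spacing": stack.fields[0].z_spacing,
    }
    rows = []
    for f in stack.fields:
        for c in f.cells:
            vec = c.vector
            rows.append(
                {
                    "x": c.position[0],
                    "y": c.position[1],
                    "z_index": f.z_index,
                    "status": c.status,
                    "alignment": vec.length if vec is not None else None,
                    "axial_angle": vec.axial_angle
                    if vec is not None and vec.axial_angle is not None
                    else None,
                    "n_segments": c.n_segments,
                }
            )
    df = pd.DataFrame(rows)
    # shortest-repr formatting so valid-cell values round-trip bit-exactly
    for col in ("alignment", "axial_angle"):
        df[col] = df[col].map(lambda v: "" if v is None else repr(float(v)))
    with open(path, "w") as fh:
        fh.write(_META_PREFIX + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False)


def read_vector_field(path: PathLike) -> StackField:
    """Rebuild a StackField from a table written by :func:`write_vector_field`."""
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith(_META_PREFIX):
        raise FiberTableError(f"{path}: not a fiberalign vector-field table")
    meta = json.loads(first[len(_META_PREFIX):])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    grid = GridSpec(
        image_width=int(meta["image_width"]),
        image_height=int(meta["image_height"]),
        spacing=float(meta["spacing"]),
        circle_radius=float(meta["circle_radius"]),
        min_fiber_count=int(meta["min_fiber_count"]),
    )
    fields = []
    for z, grp in df.groupby("z_index", sort=True):
        cells = []
        for _, row in grp.iterrows():
            pos = (float(row["x"]), float(row["y"]))
            n = int(row["n_segments"])
            if row["status"] == VALID:
                angle = None if pd.isna(row["axial_angle"]) else float(row["axial_angle"])
                vec = AlignmentVector(float(row["alignment"]), angle, n, pos)
            else:
                vec = None
            cells.append(GridCell(pos, str(row["status"]), vec, n))
        fields.append(
            VectorField(
                grid,
                cells,
                z_index=int(z),
                z_spacing=float(meta["z_spacing"]),
                pixel_size=float(meta["pixel_size"]),
            )
        )
    return StackField(fields)
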