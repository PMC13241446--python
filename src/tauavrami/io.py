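"""File formats: nodal-field CSV, observation CSV, and ASCII XML VTK.

CSV dialect throughout: comma-separated, mandatory header, UTF-8, '.'
decimal, floats written at repr precision (lossless round-trip).

The VTK writer/reader handles the ASCII XML unstructured-grid (.vtu)
subset this package needs: points, one homogeneous-or-mixed cell block,
named point-data and cell-data scalar arrays.  Cell types are inferred
from node count (1 vertex, 2 line, 3 triangle, 4 tetra, 8 hexahedron).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .atrophy import AtrophyMask, ElementConnectivity
from .coupling import MechanicalField, TauFieldSeries
from .errors import FormatError

__all__ = [
    "read_field",
    "write_field",
    "read_field_csv",
    "write_field_csv",
    "read_field_vtk",
    "write_field_vtk",
    "read_observations_csv",
    "write_tau_series",
    "write_atrophy_series",
]

_VTK_TYPE_BY_NNODES = {1: 1, 2: 3, 3: 5, 4: 10, 8: 12}
DEFAULT_SCALAR_NAME = "MPS"


# ---------------------------------------------------------------------------
# CSV nodal fields


def write_field_csv(path, field: MechanicalField) -> None:
    """Columns node_id[,x,y,z],w0; coordinates written when present."""
    cols = {"node_id": field.node_ids}
    if field.coordinates is not None:
        cols["x"] = field.coordinates[:, 0]
        cols["y"] = field.coordinates[:, 1]
        cols["z"] = field.coordinates[:, 2]
    cols["w0"] = field.w0
    pd.DataFrame(cols).to_csv(path, index=False)


def read_field_csv(path) -> MechanicalField:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse field CSV {path}: {exc}") from exc
    for col in ("node_id", "w0"):
        if col not in df.columns:
            raise FormatError(f"field CSV {path} is missing required column {col!r}")
    if df["node_id"].duplicated().any():
        dups = df.loc[df["node_id"].duplicated(), "node_id"].tolist()[:10]
        raise FormatError(f"field CSV {path} has duplicate node ids {dups}")
    coords = None
    if {"x", "y", "z"}.issubset(df.columns):
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    try:
        return MechanicalField(
            node_ids=df["node_id"].to_numpy(),
            w0=df["w0"].to_numpy(dtype=float),
            coordinates=coords,
        )
    except Exception as exc:
        raise FormatError(f"field CSV {path} invalid: {exc}") from exc


# ---------------------------------------------------------------------------
# minimal ASCII XML VTU


def _fmt(arr: np.ndarray) -> str:
    a = np.asarray(arr)
    if a.dtype.kind in "iub":
        return " ".join(str(int(v)) for v in a.ravel())
    return " ".join(repr(float(v)) for v in a.ravel())


def write_vtu(
    path,
    points: np.ndarray,
    cells: list[np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write an ASCII .vtu file; without cells, one vertex cell per point."""
    points = np.asarray(points, dtype=float)
    n_pts = points.shape[0]
    if cells is None:
        cells = [np.array([i]) for i in range(n_pts)]
    conn, offsets, types = [], [], []
    off = 0
    for c in cells:
        c = np.asarray(c).ravel()
        if len(c) not in _VTK_TYPE_BY_NNODES:
            raise FormatError(f"unsupported cell with {len(c)} nodes")
        conn.extend(int(v) for v in c)
        off += len(c)
        offsets.append(off)
        types.append(_VTK_TYPE_BY_NNODES[len(c)])
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{len(cells)}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(points),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        " ".join(str(v) for v in conn),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(v) for v in offsets),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(str(v) for v in types),
        "</DataArray>",
        "</Cells>",
    ]
    for tag, data in (("PointData", point_data), ("CellData", cell_data)):
        if data:
            lines.append(f"<{tag}>")
            for name, arr in data.items():
                arr = np.asarray(arr)
                vtype = "Int64" if arr.dtype.kind in "iub" else "Float64"
                lines.append(f'<DataArray type="{vtype}" Name="{name}" format="ascii">')
                lines.append(_fmt(arr))
                lines.append("</DataArray>")
            lines.append(f"</{tag}>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_vtu(path):
    """Read points, cells and named data arrays from an ASCII .vtu file."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"cannot parse VTK file {path}: {exc}") from exc
    piece = root.find(".//Piece")
    if piece is None:
        raise FormatError(f"VTK file {path} has no <Piece>")

    def arrays_in(parent_tag):
        out = {}
        parent = piece.find(parent_tag)
        if parent is None:
            return out
        for da in parent.findall("DataArray"):
            if da.get("format", "ascii") != "ascii":
                raise FormatError(f"VTK file {path}: only ascii DataArrays are supported")
            text = da.text or ""
            vals = np.fromstring(text, sep=" ") if text.strip() else np.array([])
            out[da.get("Name", "")] = vals
        return out

    pts_el = piece.find("Points/DataArray")
    if pts_el is None:
        raise FormatError(f"VTK file {path} has no Points array")
    points = np.fromstring(pts_el.text, sep=" ").reshape(-1, 3)
    cell_arrays = arrays_in("Cells")
    cells = None
    if "connectivity" in cell_arrays and "offsets" in cell_arrays:
        conn = cell_arrays["connectivity"].astype(int)
        offsets = cell_arrays["offsets"].astype(int)
        cells, start = [], 0
        for end in offsets:
            cells.append(conn[start:end])
            start = end
    point_data = arrays_in("PointData")
    cell_data = arrays_in("CellData")
    return points, cells, point_data, cell_data


def write_field_vtk(
    path,
    field: MechanicalField,
    conn: ElementConnectivity | None = None,
    scalar_name: str = DEFAULT_SCALAR_NAME,
) -> None:
    if field.coordinates is None:
        raise FormatError("VTK output requires nodal coordinates")
    index = {int(nid): i for i, nid in enumerate(field.node_ids)}
    cells = None
    if conn is not None:
        cells = [np.array([index[int(n)] for n in e]) for e in conn.nodes]
    write_vtu(
        path,
        field.coordinates,
        cells=cells,
        point_data={scalar_name: field.w0, "node_id": np.asarray(field.node_ids)},
    )


def read_field_vtk(
    path, scalar_name: str = DEFAULT_SCALAR_NAME
) -> tuple[MechanicalField, ElementConnectivity | None]:
    points, cells, point_data, _ = read_vtu(path)
    if scalar_name not in point_data:
        raise FormatError(
            f"VTK file {path} has no point-data array {scalar_name!r}; "
            f"available: {sorted(point_data)}"
        )
    if "node_id" in point_data:
        node_ids = point_data["node_id"].astype(int)
    else:
        node_ids = np.arange(points.shape[0])
    field = MechanicalField(
        node_ids=node_ids, w0=point_data[scalar_name], coordinates=points
    )
    conn = None
    if cells is not None and not all(len(c) == 1 for c in cells):
        conn = ElementConnectivity(
            element_ids=np.arange(len(cells)),
            nodes=tuple(node_ids[c] for c in cells),
        )
    return field, conn


def write_field(path, field, conn=None, fmt=None, scalar_name=DEFAULT_SCALAR_NAME):
    """Dispatch on format ('csv'/'vtk', inferred from the suffix by default)."""
    fmt = fmt or ("vtk" if str(path).endswith((".vtu", ".vtk")) else "csv")
    if fmt == "csv":
        write_field_csv(path, field)
    elif fmt == "vtk":
        write_field_vtk(path, field, conn, scalar_name)
    else:
        raise FormatError(f"unknown field format {fmt!r}")


def read_field(path, fmt=None, scalar_name=DEFAULT_SCALAR_NAME):
    """Returns (MechanicalField, ElementConnectivity-or-None)."""
    fmt = fmt or ("vtk" if str(path).endswith((".vtu", ".vtk")) else "csv")
    if fmt == "csv":
        return read_field_csv(path), None
    if fmt == "vtk":
        return read_field_vtk(path, scalar_name)
    raise FormatError(f"unknown field format {fmt!r}")


# ---------------------------------------------------------------------------
# observations and result series


def read_observations_csv(path):
    from .calibration import ObservationSeries

    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse observations CSV {path}: {exc}") from exc
    for col in ("time_days", "tau_at_percent"):
        if col not in df.columns:
            raise FormatError(f"observations CSV {path} is missing column {col!r}")
    return ObservationSeries(df["time_days"].tolist(), df["tau_at_percent"].tolist())


def write_tau_series(
    outdir,
    series: TauFieldSeries,
    coordinates: np.ndarray | None = None,
    conn: ElementConnectivity | None = None,
) -> list[Path]:
    """Write the long CSV, the S(t) table, and (given coordinates) per-time VTU."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    p = outdir / "tau_series.csv"
    series.to_frame().to_csv(p, index=False)
    written.append(p)
    p = outdir / "s_factors.csv"
    series.s_table().to_csv(p, index=False)
    written.append(p)
    if coordinates is not None:
        index = {int(nid): i for i, nid in enumerate(series.node_ids)}
        cells = None
        if conn is not None:
            cells = [np.array([index[int(n)] for n in e]) for e in conn.nodes]
        for j, t in enumerate(series.times):
            p = outdir / f"tau_t{int(round(t)):04d}.vtu"
            write_vtu(
                p,
                coordinates,
                cells=cells,
                point_data={"tau": series.tau[:, j], "node_id": np.asarray(series.node_ids)},
            )
            written.append(p)
    return written


def write_atrophy_series(
    outdir,
    mask: AtrophyMask,
    conn: ElementConnectivity,
    volumes: np.ndarray | None = None,
    coordinates: np.ndarray | None = None,
    node_index: dict[int, int] | None = None,
) -> list[Path]:
    """Write the removal CSV, volume series, and (given geometry) per-time VTU."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    p = outdir / "atrophy_mask.csv"
    mask.to_frame().to_csv(p, index=False)
    written.append(p)
    if volumes is not None:
        p = outdir / "remaining_volume.csv"
        pd.DataFrame({"time_days": mask.times, "remaining_volume_mm3": volumes}).to_csv(
            p, index=False
        )
        written.append(p)
    if coordinates is not None and node_index is not None:
        cells = [np.array([node_index[int(n)] for n in e]) for e in conn.nodes]
        for j, t in enumerate(mask.times):
            p = outdir / f"atrophy_t{int(round(t)):04d}.vtu"
            write_vtu(
                p,
                coordinates,
                cells=cells,
                cell_data={"removed": mask.removed[:, j].astype(int)},
            )
            written.append(p)
    return written
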