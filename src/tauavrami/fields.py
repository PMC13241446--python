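"""Synthetic mechanical fields standing in for finite-element output.

A frontal head impact leaves a smooth, non-negative strain field with a
focal high-strain region near the impact site.  The generator emulates
that pattern over a small mesh: a Gaussian blob of elevated maximum
principal strain on top of a low background, with optional seeded noise,

    w0(x) = clip(background + amplitude * exp(-|x - c|^2 / 2 sigma^2)
                 + N(0, noise_sd), 0, inf).

Two mesh kinds are offered: a regular hexahedral grid (grid3d) and a
triangulated spherical shell (sphere_shell, a crude cortex stand-in).
Uniform (amplitude = 0, noise_sd = 0) and purely random (amplitude = 0,
noise_sd > 0) variants fall out of the same spec.

Defaults mirror a mild-to-moderate frontal impact: background strain
0.02, blob peak amplitude 0.30 (peak MPS ~ 0.3), blob sigma a quarter of
the domain extent, centred on the front (+x) face.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .atrophy import ElementConnectivity
from .coupling import MechanicalField
from .errors import InvalidArgumentError

__all__ = ["SyntheticFieldSpec", "generate_synthetic_field"]


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Recipe for a synthetic strain field over a small mesh.

    seed is mandatory; every random number flows from it.  Lengths are
    mm, strain values are the raw (pre-normalization) scalar.
    """

    seed: int
    mesh_kind: str = "grid3d"
    dims: tuple[int, int, int] = (20, 20, 20)
    spacing: float = 1.0
    radius: float = 10.0
    subdivisions: int = 3
    blob_center: tuple[float, float, float] | None = None
    blob_sigma: float | None = None
    blob_amplitude: float = 0.30
    background: float = 0.02
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.mesh_kind not in ("grid3d", "sphere_shell"):
            raise InvalidArgumentError(f"unknown mesh_kind {self.mesh_kind!r}")
        if self.mesh_kind == "grid3d":
            if len(self.dims) != 3 or any(d < 2 for d in self.dims):
                raise InvalidArgumentError("grid3d needs dims >= 2 nodes per axis")
            if self.spacing <= 0:
                raise InvalidArgumentError("spacing must be positive")
        else:
            if self.radius <= 0 or self.subdivisions < 0:
                raise InvalidArgumentError("sphere_shell needs radius > 0, subdivisions >= 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if self.blob_sigma is not None and self.blob_sigma <= 0:
            raise InvalidArgumentError("blob_sigma must be positive")


def _grid3d(spec: SyntheticFieldSpec):
    nx, ny, nz = spec.dims
    h = spec.spacing
    xs = np.arange(nx) * h
    ys = np.arange(ny) * h
    zs = np.arange(nz) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    # VTK hexahedron node ordering
    hexes = np.column_stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ]
    )
    volumes = np.full(hexes.shape[0], h**3)
    extent = max((nx - 1), (ny - 1), (nz - 1)) * h
    default_center = (xs[-1], ys[-1] / 2.0, zs[-1] / 2.0)  # front (+x) face centre
    return points, hexes, volumes, extent, default_center


def _sphere_shell(spec: SyntheticFieldSpec):
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=spec.radius)
    points = np.asarray(mesh.vertices, dtype=float)
    tris = np.asarray(mesh.faces, dtype=int)
    areas = np.asarray(mesh.area_faces, dtype=float)
    extent = 2.0 * spec.radius
    default_center = (spec.radius, 0.0, 0.0)  # on the shell, +x pole
    return points, tris, areas, extent, default_center


def generate_synthetic_field(
    spec: SyntheticFieldSpec,
) -> tuple[MechanicalField, ElementConnectivity]:
    """Build the mesh and the blob-plus-noise nodal scalar for a spec.

    Deterministic given the seed.  For sphere_shell meshes the per-element
    "volume" entries are triangle areas (a surface measure).
    """
    if spec.mesh_kind == "grid3d":
        points, cells, measures, extent, default_center = _grid3d(spec)
    else:
        points, cells, measures, extent, default_center = _sphere_shell(spec)
    center = np.asarray(
        spec.blob_center if spec.blob_center is not None else default_center, dtype=float
    )
    if center.shape != (3,) or not np.all(np.isfinite(center)):
        raise InvalidArgumentError("blob_center must be a finite 3-vector")
    sigma = spec.blob_sigma if spec.blob_sigma is not None else extent / 4.0
    d2 = np.sum((points - center) ** 2, axis=1)
    w0 = spec.background + spec.blob_amplitude * np.exp(-d2 / (2.0 * sigma**2))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        w0 = w0 + rng.normal(0.0, spec.noise_sd, size=w0.size)
    w0 = np.clip(w0, 0.0, None)
    n = points.shape[0]
    field = MechanicalField(node_ids=np.arange(n), w0=w0, coordinates=points)
    conn = ElementConnectivity(
        element_ids=np.arange(cells.shape[0]),
        nodes=tuple(cells[e] for e in range(cells.shape[0])),
        volumes=measures,
    )
    return field, conn
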