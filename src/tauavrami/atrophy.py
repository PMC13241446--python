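"""Atrophy surrogate: threshold the tau field and track remaining volume.

Mesh elements whose tau exceeds a threshold (0.7 in AT%-unit model
values by default) are marked removed, visualizing where sustained tau
burden could translate into focal tissue loss.  The tau field is nodal,
removal is per element, so a nodal-to-element reduction (mean by
default; max/min available) bridges the two.  Removal is purely
diagnostic: nothing feeds back into the kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coupling import TauFieldSeries
from .errors import InvalidArgumentError

__all__ = [
    "ElementConnectivity",
    "ElementTauSeries",
    "AtrophyMask",
    "element_tau",
    "apply_threshold",
    "remaining_volume",
    "REDUCTION_RULES",
]

REDUCTION_RULES = ("mean", "max", "min")

#: Default removal threshold in AT%-unit model values.
DEFAULT_THRESHOLD = 0.7


@dataclass(frozen=True)
class ElementConnectivity:
    """Element-to-node incidence plus optional per-element volumes (mm^3)."""

    element_ids: np.ndarray
    nodes: tuple[np.ndarray, ...]  # node ids per element, possibly ragged
    volumes: np.ndarray | None = None

    def __post_init__(self):
        ids = np.asarray(self.element_ids)
        object.__setattr__(self, "element_ids", ids)
        nodes = tuple(np.asarray(e) for e in self.nodes)
        object.__setattr__(self, "nodes", nodes)
        if ids.ndim != 1 or ids.size != len(nodes) or ids.size == 0:
            raise InvalidArgumentError("element_ids and nodes must agree, >= 1 element")
        if np.unique(ids).size != ids.size:
            raise InvalidArgumentError("element_ids must be unique")
        if any(e.size == 0 for e in nodes):
            raise InvalidArgumentError("every element needs at least one node")
        if self.volumes is not None:
            vol = np.asarray(self.volumes, dtype=float)
            object.__setattr__(self, "volumes", vol)
            if vol.shape != ids.shape or not np.all(np.isfinite(vol)) or np.any(vol <= 0):
                raise InvalidArgumentError("volumes must be positive, one per element")

    @property
    def n_elements(self) -> int:
        return int(self.element_ids.size)


@dataclass(frozen=True)
class ElementTauSeries:
    """Per-element tau over time, after a nodal-to-element reduction."""

    element_ids: np.ndarray
    times: np.ndarray
    tau: np.ndarray  # shape (n_elements, n_times)
    rule: str


@dataclass(frozen=True)
class AtrophyMask:
    """Per-element boolean removal state over time."""

    element_ids: np.ndarray
    times: np.ndarray
    removed: np.ndarray  # bool, shape (n_elements, n_times)
    threshold: float
    element_tau_rule: str

    def to_frame(self) -> pd.DataFrame:
        n, t = self.removed.shape
        return pd.DataFrame(
            {
                "element_id": np.repeat(self.element_ids, t),
                "time_days": np.tile(self.times, n),
                "removed": self.removed.ravel().astype(int),
            }
        )


def element_tau(
    tau_series: TauFieldSeries,
    conn: ElementConnectivity,
    rule: str = "mean",
) -> ElementTauSeries:
    """Reduce the nodal tau field to one value per element.

    ``rule`` is one of mean / max / min over the element's nodes.
    """
    if rule not in REDUCTION_RULES:
        raise InvalidArgumentError(f"unknown reduction rule {rule!r}; choose from {REDUCTION_RULES}")
    index = {int(nid): i for i, nid in enumerate(tau_series.node_ids)}
    reducer = {"mean": np.mean, "max": np.max, "min": np.min}[rule]
    out = np.empty((conn.n_elements, tau_series.times.size))
    for e, elem_nodes in enumerate(conn.nodes):
        try:
            rows = [index[int(n)] for n in elem_nodes]
        except KeyError as exc:
            raise InvalidArgumentError(
                f"element {conn.element_ids[e]} references unknown node {exc.args[0]}"
            ) from None
        out[e, :] = reducer(tau_series.tau[rows, :], axis=0)
    return ElementTauSeries(
        element_ids=conn.element_ids, times=tau_series.times, tau=out, rule=rule
    )


def apply_threshold(
    elem_tau: ElementTauSeries, threshold: float = DEFAULT_THRESHOLD
) -> AtrophyMask:
    """Mark elements removed where element tau >= threshold.

    tau is non-decreasing in time, so the mask is monotone; a cumulative
    OR along time enforces it against solver-level rounding regardless.
    """
    if not (0 < threshold < 1):
        raise InvalidArgumentError(f"threshold must lie in (0, 1), got {threshold}")
    removed = elem_tau.tau >= threshold
    removed = np.maximum.accumulate(removed, axis=1)
    return AtrophyMask(
        element_ids=elem_tau.element_ids,
        times=elem_tau.times,
        removed=removed,
        threshold=float(threshold),
        element_tau_rule=elem_tau.rule,
    )


#: Decomposition of a VTK-ordered hexahedron into 5 tetrahedra.
_HEX_TETS = ((0, 1, 3, 4), (1, 2, 3, 6), (1, 3, 4, 6), (1, 4, 5, 6), (3, 4, 6, 7))


def geometric_volumes(conn: ElementConnectivity, field) -> np.ndarray:
    """Per-element measure from nodal coordinates.

    Hexahedra (8 nodes) are split into tetrahedra and their volumes summed;
    tetrahedra (4 nodes) use the determinant formula; triangles (3 nodes)
    contribute their area (surface meshes).  Other element arities are
    rejected.
    """
    if field.coordinates is None:
        raise InvalidArgumentError("geometric_volumes needs nodal coordinates")
    index = {int(nid): i for i, nid in enumerate(field.node_ids)}
    xyz = field.coordinates

    def tet_volume(p):
        return abs(np.linalg.det(p[1:] - p[0])) / 6.0

    out = np.empty(conn.n_elements)
    for e, elem_nodes in enumerate(conn.nodes):
        p = xyz[[index[int(n)] for n in elem_nodes]]
        if len(elem_nodes) == 8:
            out[e] = sum(tet_volume(p[list(t)]) for t in _HEX_TETS)
        elif len(elem_nodes) == 4:
            out[e] = tet_volume(p)
        elif len(elem_nodes) == 3:
            out[e] = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        else:
            raise InvalidArgumentError(
                f"cannot compute a volume for a {len(elem_nodes)}-node element"
            )
    return out


def remaining_volume(mask: AtrophyMask, conn: ElementConnectivity) -> np.ndarray:
    """Total volume (mm^3) of elements still present at each time."""
    if conn.volumes is None:
        raise InvalidArgumentError("remaining_volume requires per-element volumes")
    if conn.n_elements != mask.element_ids.size or not np.array_equal(
        np.asarray(conn.element_ids), np.asarray(mask.element_ids)
    ):
        raise InvalidArgumentError("mask and connectivity element ids disagree")
    return (~mask.removed).T @ conn.volumes
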