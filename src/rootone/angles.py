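"""Root branch angles from three labelled points.

A branch angle is measured at the branch vertex (the junction) between a
point on the parent root and a point on the daughter branch.  The points
are picked on a labelled overlay of the skeleton on the root volume in any
external viewer; this module computes the geometric angle for batches of
such triplets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import VolumeError
from .skeleton import JUNCTION, SLAB, TIP, Skeleton
from .volume import BinaryVolume, Volume

# overlay label codes
OVERLAY_BACKGROUND, OVERLAY_ROOT, OVERLAY_SLAB, OVERLAY_JUNCTION, OVERLAY_TIP = range(5)


@dataclass
class AngleTriplet:
    """Parent / vertex / branch points in (z, y, x) voxel coordinates."""

    parent_point: tuple[float, float, float]
    vertex_point: tuple[float, float, float]
    branch_point: tuple[float, float, float]
    voxel_size_um: float = 1.0


def branch_angle(triplet: AngleTriplet) -> float:
    """Angle at the vertex between the parent and branch directions, in degrees.

    Coordinates are scaled to physical units (a no-op for isotropic
    voxels), and the angle is ``arccos`` of the normalized dot product of
    the two vertex-anchored vectors, in [0, 180].  Coincident points are a
    degeneracy error.
    """
    if not triplet.voxel_size_um > 0:
        raise VolumeError("voxel_size_um must be positive")
    vertex = np.asarray(triplet.vertex_point, dtype=np.float64)
    u = (np.asarray(triplet.parent_point, dtype=np.float64) - vertex) * triplet.voxel_size_um
    v = (np.asarray(triplet.branch_point, dtype=np.float64) - vertex) * triplet.voxel_size_um
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise VolumeError("degenerate triplet: parent/branch point coincides with vertex")
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def angles_from_table(table: pd.DataFrame, voxel_size_um: float) -> pd.DataFrame:
    """Compute angles for a table with columns pz..px, vz..vx, bz..bx.

    Returns the input plus an ``angle_deg`` column rounded to 2 decimals.
    """
    out = table.copy()
    angles = []
    for _, row in table.iterrows():
        t = AngleTriplet(
            parent_point=(row["pz"], row["py"], row["px"]),
            vertex_point=(row["vz"], row["vy"], row["vx"]),
            branch_point=(row["bz"], row["by"], row["bx"]),
            voxel_size_um=voxel_size_um,
        )
        angles.append(round(branch_angle(t), 2))
    out["angle_deg"] = angles
    return out


def overlay_skeleton(root: BinaryVolume, skeleton: Skeleton) -> Volume:
    """Superimpose the classified skeleton on the root volume for point picking.

    Labels: 0 background, 1 root, 2 skeleton slab, 3 junction, 4 tip.
    """
    if root.shape != skeleton.labels.shape:
        raise VolumeError("root volume and skeleton dimensions differ")
    out = np.zeros(root.shape, dtype=np.uint8)
    out[root.data] = OVERLAY_ROOT
    out[skeleton.labels == SLAB] = OVERLAY_SLAB
    out[skeleton.labels == JUNCTION] = OVERLAY_JUNCTION
    out[skeleton.labels == TIP] = OVERLAY_TIP
    return Volume(out, root.voxel_size_um)
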