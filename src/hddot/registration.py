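"""Optode registration: template digitisation -> participant scalp surface.

A template digitisation (tile centres, cranial landmarks, and the cap's
anterior white dot, all measured on a phantom) is mapped to a
participant's scaled head model in three steps:

1. a least-squares affine transform between the template and participant
   cranial landmark sets;
2. corrective rotations about the x (pitch) and z (yaw) axes derived from
   the offset between the template and the participant-measured position
   of the cap's midline dot (when no measurement exists the template
   placement is used unchanged and flagged);
3. snapping each tile centre to the nearest scalp-surface node, laying the
   tile-local source/detector offsets in the local tangent plane, and
   projecting every optode onto the scalp.

A single 3-D dot offset cannot fix three rotational degrees of freedom;
the pitch/yaw pair zeroes the dot's elevation and azimuth about the
rotation pivot and the residual (roll) is reported, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .arrays import OptodeArray, TileSpec
from .mesh import LANDMARK_NAMES, TriSurface

__all__ = [
    "TemplateDigitisation",
    "DotOffset",
    "RegisteredOptodes",
    "landmark_affine",
    "apply_affine",
    "dot_rotation",
    "rotation_xz",
    "register_optodes",
    "template_from_layout",
]


@dataclass
class TemplateDigitisation:
    """Phantom-digitised tile centres, landmarks and midline-dot position (mm)."""

    tile_centres: np.ndarray  # (n_docks, 3)
    tile_orientations: np.ndarray  # (n_docks, 3) tile-local +x in template space
    landmarks: dict[str, np.ndarray]
    midline_dot: np.ndarray

    def landmark_array(self) -> np.ndarray:
        return np.vstack([self.landmarks[k] for k in LANDMARK_NAMES])


@dataclass(frozen=True)
class DotOffset:
    """Measured cap-dot position relative to the nasion, or absent."""

    measured_dot: np.ndarray | None  # (3,) mm, nasion-anchored frame

    @property
    def present(self) -> bool:
        return self.measured_dot is not None


@dataclass
class RegisteredOptodes:
    """Per-participant optode positions on the scalp surface (mm)."""

    tile_centres: np.ndarray  # (n_tiles, 3), snapped to scalp nodes
    source_positions: np.ndarray  # (n_src, 3)
    detector_positions: np.ndarray  # (n_det, 3)
    source_tile: np.ndarray
    detector_tile: np.ndarray
    wavelengths: tuple[float, ...]
    provenance: str  # "participant-specific" | "template-fallback"
    snap_warnings: list[int]  # tiles whose centre moved > 20 mm when snapping

    def as_array(self) -> OptodeArray:
        return OptodeArray(
            source_positions=self.source_positions,
            detector_positions=self.detector_positions,
            source_tile=self.source_tile,
            detector_tile=self.detector_tile,
            wavelengths=self.wavelengths,
        )


def template_from_layout(layout) -> TemplateDigitisation:
    """Treat a cap layout's dock poses as the phantom digitisation."""
    return TemplateDigitisation(
        tile_centres=layout.dock_positions.copy(),
        tile_orientations=layout.dock_orientations.copy(),
        landmarks={k: v.copy() for k, v in layout.landmarks.items()},
        midline_dot=layout.midline_dot.copy(),
    )


# ---------------------------------------------------------------------------
# landmark affine

def landmark_affine(
    src_landmarks: np.ndarray, dst_landmarks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares affine A (4x4 homogeneous) minimising sum ||A src - dst||^2.

    Requires at least four non-coplanar point pairs.  Returns (A, residuals)
    where residuals are the per-point Euclidean errors after the fit.
    """
    src = np.asarray(src_landmarks, float)
    dst = np.asarray(dst_landmarks, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3 or len(src) < 4:
        raise ValueError("need >= 4 paired 3-D landmarks of equal shape")
    X = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(X, tol=1e-6 * max(1.0, np.abs(src).max())) < 4:
        raise ValueError("landmark configuration is coplanar/degenerate")
    coef, *_ = np.linalg.lstsq(X, dst, rcond=None)
    A = np.eye(4)
    A[:3, :3] = coef[:3].T
    A[:3, 3] = coef[3]
    resid = np.linalg.norm(X @ coef - dst, axis=1)
    return A, resid


def apply_affine(A: np.ndarray, pts: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, float))
    return pts @ A[:3, :3].T + A[:3, 3]


# ---------------------------------------------------------------------------
# dot rotations

def _azimuth_elevation(v: np.ndarray) -> tuple[float, float]:
    # azimuth about z measured from +y toward +x; elevation toward +z
    az = np.arctan2(v[0], v[1])
    el = np.arctan2(v[2], np.hypot(v[0], v[1]))
    return float(az), float(el)


def dot_rotation(
    template_dot: np.ndarray,
    measured_dot: DotOffset,
    origin: np.ndarray,
) -> tuple[float, float]:
    """Pitch (about x) and yaw (about z) angles aligning the template dot.

    Both dots are expressed in the participant head frame; angles are the
    elevation and azimuth differences of the two dot directions about the
    given pivot.  Returns (0, 0) when no measurement is available.
    """
    if not measured_dot.present:
        return 0.0, 0.0
    t = np.asarray(template_dot, float) - origin
    m = np.asarray(measured_dot.measured_dot, float) - origin
    if np.linalg.norm(t) < 1e-9 or np.linalg.norm(m) < 1e-9:
        raise ValueError("dot coincides with the rotation origin; direction undefined")
    az_t, el_t = _azimuth_elevation(t)
    az_m, el_m = _azimuth_elevation(m)
    pitch = el_m - el_t
    yaw = az_m - az_t
    return pitch, yaw


def rotation_xz(pitch: float, yaw: float) -> np.ndarray:
    """Rotation matrix Rx(pitch) @ Rz(-yaw) for the midline-dot correction.

    With azimuth measured from +y toward +x, moving a midline point to a
    larger azimuth requires a negative mathematical rotation about z, hence
    the sign.
    """
    cp, sp = np.cos(pitch), np.sin(pitch)
    cy, sy = np.cos(-yaw), np.sin(-yaw)
    Rx = np.array([[1, 0, 0], [0, cp, -sp], [0, sp, cp]])
    Rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1]])
    return Rx @ Rz


# ---------------------------------------------------------------------------
# scalp snapping

def _vertex_normals(surface: TriSurface) -> np.ndarray:
    tm = surface.as_trimesh()
    return np.asarray(tm.vertex_normals)


def project_to_surface(
    surface: TriSurface, points: np.ndarray, k: int = 24
) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on the triangle surface for each query point.

    Candidate faces are found by a KD-tree over face centroids (k nearest),
    then the exact point-triangle distance is evaluated on the candidates.
    Returns (projected_points, distances).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    tris = surface.vertices[surface.faces]  # (F, 3, 3)
    centroids = tris.mean(axis=1)
    k = min(k, len(centroids))
    _, cand = cKDTree(centroids).query(pts, k=k)
    cand = np.atleast_2d(cand)
    n, kk = cand.shape
    flat_tris = tris[cand.ravel()]
    flat_pts = np.repeat(pts, kk, axis=0)
    closest = trimesh.triangles.closest_point(flat_tris, flat_pts)
    d = np.linalg.norm(closest - flat_pts, axis=1).reshape(n, kk)
    best = d.argmin(axis=1)
    return closest.reshape(n, kk, 3)[np.arange(n), best], d[np.arange(n), best]


def register_optodes(
    template: TemplateDigitisation,
    tile: TileSpec,
    transform: np.ndarray,
    rotations: tuple[float, float],
    scalp: TriSurface,
    pivot: np.ndarray | None = None,
    provenance: str = "participant-specific",
    snap_warn_mm: float = 20.0,
) -> RegisteredOptodes:
    """Place the template array on a participant scalp surface.

    Tile centres are affinely transformed, rotated about the pivot (scalp
    centroid by default), and snapped to the nearest scalp node.  Sources
    and detectors are laid out at the tile-local offsets in the tangent
    plane of the snapped centre (normal from area-weighted incident faces,
    local x from the transported dock orientation re-orthogonalised), then
    projected to their closest point on the scalp surface.
    """
    tm = scalp.as_trimesh()
    if pivot is None:
        pivot = tm.vertices.mean(axis=0)
    pivot = np.asarray(pivot, float)
    R = rotation_xz(*rotations)

    centres = apply_affine(transform, template.tile_centres)
    centres = (centres - pivot) @ R.T + pivot
    # transport orientations through the linear parts only (directions)
    orient = template.tile_orientations @ transform[:3, :3].T @ R.T

    tree = cKDTree(np.asarray(tm.vertices))
    normals = _vertex_normals(scalp)
    dist, vidx = tree.query(centres)
    snapped = np.asarray(tm.vertices)[vidx]
    warnings = [int(i) for i in np.flatnonzero(dist > snap_warn_mm)]

    src_pos, det_pos, src_tile, det_tile = [], [], [], []
    for k, (c, n, o) in enumerate(zip(snapped, normals[vidx], orient)):
        n = n / np.linalg.norm(n)
        e1 = o - (o @ n) * n
        if np.linalg.norm(e1) < 1e-9:
            e1 = np.cross(n, [0.0, 0.0, 1.0])
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        for xy in tile.source_offsets:
            src_pos.append(c + xy[0] * e1 + xy[1] * e2)
            src_tile.append(k)
        for xy in tile.detector_offsets:
            det_pos.append(c + xy[0] * e1 + xy[1] * e2)
            det_tile.append(k)
    src_pos = np.asarray(src_pos).reshape(-1, 3)
    det_pos = np.asarray(det_pos).reshape(-1, 3)
    src_on, _ = project_to_surface(scalp, src_pos)
    det_on, _ = project_to_surface(scalp, det_pos)
    return RegisteredOptodes(
        tile_centres=snapped,
        source_positions=src_on,
        detector_positions=det_on,
        source_tile=np.asarray(src_tile, int),
        detector_tile=np.asarray(det_tile, int),
        wavelengths=tile.wavelengths,
        provenance=provenance,
        snap_warnings=warnings,
    )
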