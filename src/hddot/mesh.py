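"""Four-tissue tetrahedral head model: orientation, scaling, measurements.

The head model labels every tetrahedron as white matter (WM), grey matter
(GM), cerebrospinal fluid (CSF) or extra-cerebral tissue (ECT), and carries
the five cranial landmarks (Nz nasion, Iz inion, Ar/Al pre-auricular
points, Cz vertex) on the scalp.  A participant-specific model is obtained
by orienting the template into a canonical landmark frame and then
iteratively rescaling coordinate pairs until the model's head
circumference and the two landmark arcs match the participant's scalp
measurements to within 5 mm.

Conventions: units mm everywhere in memory (measurements in cm at the
interface, as recorded with a tape measure); canonical frame has the inion
at the origin, the nasion on +y, the pre-auricular points at equal z, and
the vertex up (+z).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, cKDTree

TISSUES = ("WM", "GM", "CSF", "ECT")
LANDMARK_NAMES = ("Nz", "Iz", "Ar", "Al", "Cz")

__all__ = [
    "TetHeadMesh",
    "TriSurface",
    "HeadMeasurements",
    "orient_head",
    "measure_head",
    "scale_to_participant",
    "nodal_volumes",
    "tet_volumes",
    "boundary_surface",
    "interface_surface",
    "read_gmsh",
    "write_gmsh",
]


@dataclass
class TriSurface:
    """Triangle surface extracted from the volume mesh.

    ``volume_nodes`` maps each surface vertex back to its volume-mesh node
    index, preserving provenance so per-node fields can be moved between
    the two representations without interpolation.
    """

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int, indices into vertices
    volume_nodes: np.ndarray | None = None  # (n,) indices into the volume mesh

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass
class TetHeadMesh:
    """Labelled four-tissue tetrahedral head mesh with cranial landmarks."""

    nodes: np.ndarray  # (N, 3) mm
    tets: np.ndarray  # (E, 4) int
    tissue: np.ndarray  # (E,) str in TISSUES
    landmarks: dict[str, np.ndarray]  # name -> (3,)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.tissue = np.asarray(self.tissue)
        unknown = set(np.unique(self.tissue)) - set(TISSUES)
        if unknown:
            raise ValueError(f"unknown tissue labels {unknown}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def landmark_array(self) -> np.ndarray:
        return np.vstack([self.landmarks[k] for k in LANDMARK_NAMES])

    def with_nodes(self, nodes: np.ndarray, landmarks: dict | None = None) -> "TetHeadMesh":
        return TetHeadMesh(
            nodes=nodes,
            tets=self.tets,
            tissue=self.tissue,
            landmarks={k: np.asarray(v, float) for k, v in (landmarks or self.landmarks).items()},
        )

    def scalp_surface(self) -> TriSurface:
        return boundary_surface(self)

    def cortical_surface(self) -> TriSurface:
        """Outer GM boundary: faces shared between GM and CSF tetrahedra."""
        return interface_surface(self, "GM", "CSF")


@dataclass(frozen=True)
class HeadMeasurements:
    """Scalp tape measurements, cm (plausible infant range ~30-60 cm)."""

    circumference: float
    nz_cz_iz: float
    ar_cz_al: float

    def as_array(self) -> np.ndarray:
        return np.array([self.circumference, self.nz_cz_iz, self.ar_cz_al])


# ---------------------------------------------------------------------------
# geometry primitives

def tet_volumes(mesh: TetHeadMesh) -> np.ndarray:
    p = mesh.nodes[mesh.tets]
    v = np.einsum(
        "ei,ei->e",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    ) / 6.0
    return v


def nodal_volumes(mesh: TetHeadMesh) -> np.ndarray:
    """Barycentric-lumped node volumes: each tet gives 1/4 V to each vertex."""
    v = tet_volumes(mesh)
    if np.any(v <= 0):
        raise ValueError(f"{int((v <= 0).sum())} inverted or degenerate tetrahedra")
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.tets.ravel(), np.repeat(v / 4.0, 4))
    return out


_FACE_LOCAL = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])


def _all_faces(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All 4E faces with their owning tet index."""
    faces = tets[:, _FACE_LOCAL].reshape(-1, 3)
    owner = np.repeat(np.arange(len(tets)), 4)
    return faces, owner


def _face_groups(tets: np.ndarray):
    faces, owner = _all_faces(tets)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T[::-1])
    key_sorted = key[order]
    first = np.ones(len(key_sorted), dtype=bool)
    first[1:] = np.any(key_sorted[1:] != key_sorted[:-1], axis=1)
    group = np.cumsum(first) - 1
    return faces[order], owner[order], group


def _orient_outward(mesh: TetHeadMesh, faces: np.ndarray, owners: np.ndarray) -> np.ndarray:
    """Flip boundary faces so their normals point out of the owning tet."""
    tet_pts = mesh.nodes[mesh.tets[owners]]
    centroid = tet_pts.mean(axis=1)
    p = mesh.nodes[faces]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    inward = np.einsum("fi,fi->f", n, centroid - p.mean(axis=1)) > 0
    faces = faces.copy()
    faces[inward] = faces[inward][:, ::-1]
    return faces


def _compact_surface(mesh: TetHeadMesh, faces: np.ndarray) -> TriSurface:
    used = np.unique(faces)
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriSurface(
        vertices=mesh.nodes[used].copy(), faces=remap[faces], volume_nodes=used
    )


def boundary_surface(mesh: TetHeadMesh) -> TriSurface:
    """Closed boundary of the tet mesh (the scalp for a head model)."""
    faces, owner, group = _face_groups(mesh.tets)
    counts = np.bincount(group)
    single = counts[group] == 1
    bfaces = _orient_outward(mesh, faces[single], owner[single])
    return _compact_surface(mesh, bfaces)


def interface_surface(mesh: TetHeadMesh, tissue_a: str, tissue_b: str) -> TriSurface:
    """Faces shared by one tet of ``tissue_a`` and one of ``tissue_b``."""
    faces, owner, group = _face_groups(mesh.tets)
    counts = np.bincount(group)
    lab = mesh.tissue[owner]
    keep = np.zeros(len(faces), dtype=bool)
    paired = counts[group] == 2
    # paired faces come consecutively after the lexsort
    idx = np.flatnonzero(paired)
    idx_first = idx[::2]
    la, lb = lab[idx_first], lab[idx_first + 1]
    match = ((la == tissue_a) & (lb == tissue_b)) | ((la == tissue_b) & (lb == tissue_a))
    sel = idx_first[match]
    own_a = np.where(lab[sel] == tissue_a, owner[sel], owner[sel + 1])
    ifaces = _orient_outward(mesh, faces[sel], own_a)
    return _compact_surface(mesh, ifaces)


# ---------------------------------------------------------------------------
# orientation

def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _rot_y(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def orient_head(mesh: TetHeadMesh) -> TetHeadMesh:
    """Canonicalise the pose: Iz at origin, Nz on +y, equal-z pre-auriculars.

    The inion is taken as the origin and the inion->nasion line defines +y;
    the model is then rotated about y until Ar and Al share a z coordinate,
    with the vertex kept on the +z side.  Idempotent to rounding.
    """
    lm = {k: np.asarray(v, float) for k, v in mesh.landmarks.items()}
    missing = [k for k in LANDMARK_NAMES if k not in lm]
    if missing:
        raise ValueError(f"missing landmarks {missing}")
    axis = lm["Nz"] - lm["Iz"]
    if np.linalg.norm(axis) < 1e-9:
        raise ValueError("degenerate landmarks: Nz coincides with Iz")
    R1 = _rotation_between(axis, np.array([0.0, 1.0, 0.0]))

    def apply(R, t, pts):
        return (pts - t) @ R.T

    t = lm["Iz"]
    ar, al = apply(R1, t, lm["Ar"]), apply(R1, t, lm["Al"])
    dx, dz = ar[0] - al[0], ar[2] - al[2]
    theta = np.arctan2(dz, dx) if abs(dx) + abs(dz) > 1e-12 else 0.0
    R = _rot_y(theta) @ R1
    if (R @ (lm["Cz"] - t))[2] < 0:
        R = _rot_y(np.pi) @ R
    nodes = apply(R, t, mesh.nodes)
    new_lm = {k: apply(R, t, v) for k, v in lm.items()}
    return mesh.with_nodes(nodes, new_lm)


# ---------------------------------------------------------------------------
# measurement

def _surface_graph(surface: TriSurface):
    f = surface.faces
    i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    w = np.linalg.norm(surface.vertices[i] - surface.vertices[j], axis=1)
    n = len(surface.vertices)
    g = coo_matrix((w, (i, j)), shape=(n, n))
    return (g + g.T).tocsr() * 0.5


def _geodesic_through(surface: TriSurface, a: np.ndarray, via: np.ndarray, b: np.ndarray) -> float:
    """Shortest scalp path a -> via -> b along surface edges (mm)."""
    tree = cKDTree(surface.vertices)
    ia, iv, ib = tree.query([a, via, b])[1]
    g = _surface_graph(surface)
    d = dijkstra(g, indices=[int(iv)], directed=False)[0]
    return float(d[ia] + d[ib])


def _cross_section_perimeter(surface: TriSurface, z_level: float) -> float:
    """Convex-hull perimeter of the scalp cross-section at axial level z.

    The convex hull of the section approximates the path of a tape pulled
    taut around the head, robust to small surface dimples.
    """
    tm = surface.as_trimesh()
    lines = trimesh.intersections.mesh_plane(
        tm, plane_normal=[0.0, 0.0, 1.0], plane_origin=[0.0, 0.0, z_level]
    )
    if len(lines) == 0:
        raise ValueError(f"no scalp cross-section at z={z_level:.1f} mm (open surface?)")
    pts = np.asarray(lines).reshape(-1, 3)[:, :2]
    hull = ConvexHull(pts)
    loop = pts[hull.vertices]
    return float(np.linalg.norm(np.diff(np.vstack([loop, loop[:1]]), axis=0), axis=1).sum())


def measure_head(mesh: TetHeadMesh, surface: TriSurface | None = None) -> HeadMeasurements:
    """Circumference and landmark arcs of an oriented head model, in cm.

    Circumference: convex-hull perimeter of the scalp section at the mean
    axial (z) level of Nz and Iz.  Arcs: shortest surface path through Cz
    (Dijkstra on the scalp triangle graph with exact edge lengths).
    """
    if surface is None:
        surface = mesh.scalp_surface()
    lm = mesh.landmarks
    z = 0.5 * (lm["Nz"][2] + lm["Iz"][2])
    circ = _cross_section_perimeter(surface, z)
    nz_cz_iz = _geodesic_through(surface, lm["Nz"], lm["Cz"], lm["Iz"])
    ar_cz_al = _geodesic_through(surface, lm["Ar"], lm["Cz"], lm["Al"])
    return HeadMeasurements(circ / 10.0, nz_cz_iz / 10.0, ar_cz_al / 10.0)


_AXIS_PAIRS = {  # measurement -> coordinate pair it drives
    "circumference": (0, 1),  # x, y (the axial plane sets the perimeter)
    "nz_cz_iz": (1, 2),  # y, z
    "ar_cz_al": (0, 2),  # x, z
}
_MEASURE_ORDER = ("circumference", "nz_cz_iz", "ar_cz_al")


def scale_to_participant(
    mesh: TetHeadMesh,
    target: HeadMeasurements,
    tol_mm: float = 5.0,
    max_iter: int = 50,
) -> tuple[TetHeadMesh, list[dict]]:
    """Iteratively scale an oriented head model to scalp measurements.

    First an isotropic scale by the circumference ratio; thereafter, each
    iteration rescales the coordinate pair driven by the measurement with
    the greatest absolute discrepancy (ties broken in the fixed order
    circumference, Nz-Cz-Iz, Ar-Cz-Al) by the ratio target/current, until
    all three discrepancies are within ``tol_mm``.  Returns the scaled mesh
    and an iteration log.  Topology and tissue labels are untouched.
    """
    t = target.as_array()
    if np.any(t <= 0):
        raise ValueError("target measurements must be positive")
    log: list[dict] = []
    cur = measure_head(mesh)
    s0 = target.circumference / cur.circumference
    nodes = mesh.nodes * s0
    lm = {k: v * s0 for k, v in mesh.landmarks.items()}
    work = mesh.with_nodes(nodes, lm)
    log.append({"step": "isotropic", "factor": s0, "measured_cm": cur.as_array()})
    for it in range(max_iter):
        cur = measure_head(work)
        disc = cur.as_array() - t  # cm
        log.append({"step": it, "measured_cm": cur.as_array(), "residual_cm": disc.copy()})
        if np.all(np.abs(disc) * 10.0 <= tol_mm):
            return work, log
        # greatest |discrepancy| drives the rescale; ties fall to the fixed order
        best = int(np.argsort([-abs(d) for d in disc], kind="stable")[0])
        name = _MEASURE_ORDER[best]
        factor = t[best] / cur.as_array()[best]
        ax = _AXIS_PAIRS[name]
        nodes = work.nodes.copy()
        nodes[:, ax] *= factor
        lm = {k: v.copy() for k, v in work.landmarks.items()}
        for v in lm.values():
            v[list(ax)] *= factor
        work = work.with_nodes(nodes, lm)
        log[-1].update({"rescaled": name, "factor": factor})
    cur = measure_head(work)
    resid = (cur.as_array() - t) * 10.0
    raise RuntimeError(
        f"head scaling did not converge in {max_iter} iterations; residuals {resid} mm"
    )


# ---------------------------------------------------------------------------
# minimal GMSH v2.2 ASCII I/O (tissue labels as physical tags 1..4 = WM..ECT)

_TISSUE_TAG = {t: i + 1 for i, t in enumerate(TISSUES)}
_TAG_TISSUE = {v: k for k, v in _TISSUE_TAG.items()}


def write_gmsh(mesh: TetHeadMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n")
        fh.write(f"{mesh.n_nodes}\n")
        for i, p in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write("$EndNodes\n$Elements\n")
        fh.write(f"{len(mesh.tets)}\n")
        for e, (tet, lab) in enumerate(zip(mesh.tets, mesh.tissue), start=1):
            tag = _TISSUE_TAG[str(lab)]
            a, b, c, d = (tet + 1).tolist()
            fh.write(f"{e} 4 2 {tag} {tag} {a} {b} {c} {d}\n")
        fh.write("$EndElements\n$Landmarks\n")
        for k in LANDMARK_NAMES:
            p = mesh.landmarks[k]
            fh.write(f"{k} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write("$EndLandmarks\n")


def read_gmsh(path) -> TetHeadMesh:
    nodes, tets, tissue, landmarks = [], [], [], {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        tok = lines[i].strip()
        if tok == "$Nodes":
            n = int(lines[i + 1])
            for k in range(n):
                parts = lines[i + 2 + k].split()
                nodes.append([float(x) for x in parts[1:4]])
            i += n + 2
        elif tok == "$Elements":
            n = int(lines[i + 1])
            for k in range(n):
                parts = lines[i + 2 + k].split()
                if int(parts[1]) != 4:
                    continue
                ntags = int(parts[2])
                tag = int(parts[3]) if ntags else 1
                conn = [int(x) - 1 for x in parts[3 + ntags:7 + ntags]]
                tets.append(conn)
                tissue.append(_TAG_TISSUE.get(tag, "ECT"))
            i += n + 2
        elif tok == "$Landmarks":
            j = i + 1
            while lines[j].strip() != "$EndLandmarks":
                parts = lines[j].split()
                landmarks[parts[0]] = np.array([float(x) for x in parts[1:4]])
                j += 1
            i = j
        i += 1
    return TetHeadMesh(
        nodes=np.array(nodes), tets=np.array(tets), tissue=np.array(tissue), landmarks=landmarks
    )
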