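"""Synthetic layered head phantoms (slab and hemisphere) with known truth.

These phantoms stand in for an MRI-derived infant head model: a labelled
four-tissue tetrahedral mesh (extra-cerebral tissue, CSF, grey matter,
white matter from the outside in) with the five cranial landmarks placed
on the scalp.  They are *synthetic* — built from closed-form geometry so
every downstream stage (measurement, registration, forward modelling,
reconstruction) can be verified against analytic expectations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .mesh import TetHeadMesh, tet_volumes

__all__ = ["make_phantom", "hemisphere_phantom", "slab_phantom"]

#: outside-in tissue order for the ``layers`` argument
LAYER_ORDER = ("ECT", "CSF", "GM")  # remainder is WM


def make_phantom(
    kind: str,
    layers: tuple[float, float, float] = (7.0, 2.0, 4.0),
    resolution: float = 7.0,
    **kw,
) -> TetHeadMesh:
    """Build a layered phantom head mesh.

    Parameters
    ----------
    kind : "hemisphere" or "slab"
    layers : outside-in thicknesses (mm) of ECT, CSF, GM; the interior is WM.
    resolution : target edge length h (mm).
    """
    layers = tuple(float(t) for t in layers)
    if len(layers) != 3 or any(t <= 0 for t in layers):
        raise ValueError("layers must be three positive thicknesses (ECT, CSF, GM)")
    if min(layers) < resolution / 4.0:
        raise ValueError(
            f"resolution {resolution} mm too coarse to resolve a {min(layers)} mm layer"
        )
    if kind == "hemisphere":
        return hemisphere_phantom(layers=layers, h=resolution, **kw)
    if kind == "slab":
        return slab_phantom(layers=layers, h=resolution, **kw)
    raise ValueError(f"unknown phantom kind {kind!r}")


# ---------------------------------------------------------------------------
# hemisphere

def _half_shell(radius: float, h: float, rng) -> np.ndarray:
    """Near-uniform points on the half-sphere z>0 of given radius, spacing ~h."""
    if radius < h / 2:
        return np.zeros((0, 3))
    n = max(4, int(round(2.0 * np.pi * radius**2 / h**2)))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    z = (i + 0.5) / n  # z/r in (0, 1)
    phi = i * golden + rng.uniform(0, 2 * np.pi)
    rho = np.sqrt(1.0 - z**2)
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _ring(radius: float, h: float, rng) -> np.ndarray:
    if radius < h / 2:
        return np.zeros((0, 3))
    n = max(6, int(round(2.0 * np.pi * radius / h)))
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False) + rng.uniform(0, 2 * np.pi)
    return radius * np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])


def hemisphere_phantom(
    radius: float = 70.0,
    layers: tuple[float, float, float] = (7.0, 2.0, 4.0),
    h: float = 7.0,
    landmark_elevation_deg: float = 8.0,
    seed: int = 71,
) -> TetHeadMesh:
    """Layered hemisphere (flat base at z=0, crown at +z), radius in mm.

    Nodes are placed on concentric half-shells — one exactly at each tissue
    interface so layers thinner than h stay resolved radially — plus base
    rings, then tetrahedralised by Delaunay (the hemisphere is convex, so
    the Delaunay tetrahedra fill it exactly).  Landmarks sit on the scalp
    shell slightly above the base plane, the vertex Cz at the pole.
    """
    rng = np.random.default_rng(seed)
    t_ect, t_csf, t_gm = layers
    interfaces = [radius, radius - t_ect, radius - t_ect - t_csf, radius - t_ect - t_csf - t_gm]
    if interfaces[-1] <= h:
        raise ValueError("layers leave no room for white matter interior")
    # radii: every interface, subdivided where a layer is thicker than h,
    # then the WM interior marched inward at spacing h
    radii = []
    for r_out, r_in in zip(interfaces[:-1], interfaces[1:]):
        n_sub = max(1, int(round((r_out - r_in) / h)))
        radii.extend(np.linspace(r_out, r_in, n_sub + 1)[:-1])
    r = interfaces[-1]
    while r > h * 0.75:
        radii.append(r)
        r -= h
    pts = [np.zeros((1, 3))]
    for r in radii:
        pts.append(_half_shell(r, h, rng))
        pts.append(_ring(r, h, rng))
    pts = np.vstack(pts)

    el = np.deg2rad(landmark_elevation_deg)
    c, s = np.cos(el), np.sin(el)
    lm_pts = np.array(
        [
            [0.0, radius * c, radius * s],  # Nz
            [0.0, -radius * c, radius * s],  # Iz
            [radius * c, 0.0, radius * s],  # Ar
            [-radius * c, 0.0, radius * s],  # Al
            [0.0, 0.0, radius],  # Cz
        ]
    )
    # drop generated points that would crowd the landmark nodes, then append
    keep = cKDTree(lm_pts).query(pts)[0] > 0.45 * h
    pts = np.vstack([pts[keep], lm_pts])
    landmarks = dict(zip(("Nz", "Iz", "Ar", "Al", "Cz"), lm_pts))

    tri = Delaunay(pts)
    tets = tri.simplices.astype(np.int64)
    mesh_nodes = pts
    # orient all tets positively; drop slivers from near-degenerate configs
    p = mesh_nodes[tets]
    vol = np.einsum(
        "ei,ei->e", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), p[:, 3] - p[:, 0]
    ) / 6.0
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    vol = np.abs(vol)
    tets = tets[vol > 1e-9]
    vol = vol[vol > 1e-9]

    centroid_r = np.linalg.norm(mesh_nodes[tets].mean(axis=1), axis=1)
    tissue = np.full(len(tets), "WM", dtype=object)
    tissue[centroid_r > interfaces[3]] = "GM"
    tissue[centroid_r > interfaces[2]] = "CSF"
    tissue[centroid_r > interfaces[1]] = "ECT"
    return TetHeadMesh(nodes=mesh_nodes, tets=tets, tissue=np.array(tissue, dtype=str), landmarks=landmarks)


# ---------------------------------------------------------------------------
# slab

_KUHN = np.array(  # six tetrahedra splitting the unit cube along (0,0,0)-(1,1,1)
    [
        [0, 1, 3, 7],
        [0, 1, 5, 7],
        [0, 2, 3, 7],
        [0, 2, 6, 7],
        [0, 4, 5, 7],
        [0, 4, 6, 7],
    ]
)


def slab_phantom(
    size: tuple[float, float, float] = (60.0, 60.0, 30.0),
    layers: tuple[float, float, float] = (7.0, 2.0, 4.0),
    h: float = 5.0,
) -> TetHeadMesh:
    """Layered rectangular slab; the scalp is the planar top face (z = Lz).

    Tissue layers are measured downward from the top face.  Landmarks sit
    on the top face: Cz at its centre, Nz/Iz at the +y/-y edge midpoints,
    Ar/Al at the +x/-x edge midpoints.  A Kuhn (six-tetrahedra) subdivision
    of a structured grid keeps the mesh conforming and deterministic.
    """
    Lx, Ly, Lz = (float(v) for v in size)
    nx, ny, nz = (max(1, int(round(L / h))) for L in (Lx, Ly, Lz))
    xs = np.linspace(0, Lx, nx + 1)
    ys = np.linspace(0, Ly, ny + 1)
    zs = np.linspace(0, Lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    corners = np.stack(
        [nid(I + ((c >> 2) & 1), J + ((c >> 1) & 1), K + (c & 1)) for c in range(8)], axis=-1
    ).reshape(-1, 8)
    tets = corners[:, _KUHN].reshape(-1, 4)
    p = nodes[tets]
    vol = np.einsum(
        "ei,ei->e", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), p[:, 3] - p[:, 0]
    ) / 6.0
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]

    depth = Lz - nodes[tets].mean(axis=1)[:, 2]
    t_ect, t_csf, t_gm = layers
    tissue = np.full(len(tets), "WM", dtype=object)
    tissue[depth < t_ect + t_csf + t_gm] = "GM"
    tissue[depth < t_ect + t_csf] = "CSF"
    tissue[depth < t_ect] = "ECT"

    landmarks = {
        "Cz": np.array([Lx / 2, Ly / 2, Lz]),
        "Nz": np.array([Lx / 2, Ly, Lz]),
        "Iz": np.array([Lx / 2, 0.0, Lz]),
        "Ar": np.array([Lx, Ly / 2, Lz]),
        "Al": np.array([0.0, Ly / 2, Lz]),
    }
    return TetHeadMesh(
        nodes=nodes, tets=tets.astype(np.int64), tissue=np.array(tissue, dtype=str), landmarks=landmarks
    )
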