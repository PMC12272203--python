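"""Continuous-wave photon diffusion forward model and sensitivity Jacobian.

The forward problem is the CW diffusion approximation on the tetrahedral
head mesh,

    -div( kappa grad Phi ) + mu_a Phi = q,     kappa = 1/(3 (mu_a + mu_s')),

with a Robin (partial-current) boundary condition
``kappa dPhi/dn + Phi / (2 A) = 0`` on the whole mesh boundary, where the
reflection factor A follows Schweiger's polynomial fit in the tissue
refractive index.  First-order (P1) Lagrange elements are used and the
absorption term is assembled from the P1-interpolated *nodal* absorption
field, so the sensitivity matrix computed here is the exact derivative of
the discrete system with respect to nodal mu_a — the adjoint and
brute-force finite-difference Jacobians agree to rounding on any mesh.

Sources are modelled as point loads one transport mean free path
``1/(mu_a + mu_s')`` below the scalp along the inward normal, distributed
barycentrically over the enclosing tetrahedron; detectors use the same
construction, which makes source-detector reciprocity exact.

Entries of the Jacobian are d(Delta OD)/d(mu_a at node), units mm (a
volume-weighted sensitivity): positive, since raising absorption anywhere
raises the measured optical density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .mesh import TetHeadMesh, TriSurface, nodal_volumes, tet_volumes

__all__ = [
    "OpticalProperties",
    "default_optical_properties",
    "DiffusionSolver",
    "solve_diffusion",
    "JacobianMatrix",
    "compute_jacobian",
    "coverage_threshold",
    "SensitivityMask",
    "sensitivity_mask",
    "group_coverage",
    "surface_mapper",
]

#: reduced-scattering floor (1/mm) keeping the diffusion approximation usable
#: in low-scattering CSF
MUSP_FLOOR = 0.3


@dataclass(frozen=True)
class OpticalProperties:
    """Per-tissue, per-wavelength absorption/scattering (1/mm) and index n.

    ``mua[tissue][wavelength]`` and ``musp[tissue][wavelength]``; the
    packaged defaults are literature-typical infant-head values and are
    configuration, not ground truth.
    """

    mua: dict[str, dict[float, float]]
    musp: dict[str, dict[float, float]]
    n: float = 1.4

    def __post_init__(self):
        for tissue, by_wl in self.mua.items():
            for wl, v in by_wl.items():
                if v <= 0:
                    raise ValueError(f"mua must be positive ({tissue}@{wl})")
        for tissue, by_wl in self.musp.items():
            for wl, v in by_wl.items():
                if v <= 0:
                    raise ValueError(f"musp must be positive ({tissue}@{wl})")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")

    def musp_floored(self, tissue: str, wl: float) -> float:
        return max(self.musp[tissue][wl], MUSP_FLOOR)


def default_optical_properties() -> OpticalProperties:
    """Literature-typical infant head optical properties (non-normative)."""
    return OpticalProperties(
        mua={
            "ECT": {735.0: 0.017, 850.0: 0.019},
            "CSF": {735.0: 0.004, 850.0: 0.004},
            "GM": {735.0: 0.018, 850.0: 0.019},
            "WM": {735.0: 0.017, 850.0: 0.021},
        },
        musp={
            "ECT": {735.0: 1.75, 850.0: 1.60},
            "CSF": {735.0: 0.30, 850.0: 0.30},
            "GM": {735.0: 0.85, 850.0: 0.75},
            "WM": {735.0: 1.20, 850.0: 1.05},
        },
        n=1.4,
    )


def _reflection_factor(n: float) -> float:
    """Internal-reflection boundary factor A(n) (Schweiger et al. fit)."""
    if abs(n - 1.0) < 1e-12:
        return 1.0
    r = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r) / (1.0 - r)


# ---------------------------------------------------------------------------
# assembly helpers

def _tet_gradients(mesh: TetHeadMesh) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric gradients (E, 4, 3) and volumes (E,)."""
    p = mesh.nodes[mesh.tets]
    m = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=1)
    vol = np.linalg.det(m) / 6.0
    minv = np.linalg.inv(m)
    g123 = np.transpose(minv, (0, 2, 1))  # rows: grad lambda_1..3
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), vol


def _assemble_stiffness(mesh, grads, vol, kappa_e) -> sp.csr_matrix:
    Ke = np.einsum("e,eia,eja->eij", kappa_e * vol, grads, grads)
    return _scatter(mesh, Ke)


def _assemble_mass_nodal(mesh, vol, mua_nodal) -> sp.csr_matrix:
    """Mass-weighted absorption from the P1-interpolated nodal field.

    M_ij = sum_e (V_e/120) * (S + a_i + a_j + delta_ij (S + 2 a_i)),
    S = sum of the four nodal values on the element.
    """
    a = mua_nodal[mesh.tets]  # (E, 4)
    S = a.sum(axis=1)
    E = len(vol)
    Me = np.empty((E, 4, 4))
    Me[:] = S[:, None, None]
    Me += a[:, :, None] + a[:, None, :]
    idx = np.arange(4)
    Me[:, idx, idx] += S[:, None] + 2 * a
    Me *= (vol / 120.0)[:, None, None]
    return _scatter(mesh, Me)


def _scatter(mesh, elem_mats) -> sp.csr_matrix:
    t = mesh.tets
    i = np.repeat(t, 4, axis=1).ravel()
    j = np.tile(t, (1, 4)).ravel()
    return sp.coo_matrix(
        (elem_mats.ravel(), (i, j)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()


def _assemble_boundary(mesh: TetHeadMesh, boundary: TriSurface, coef: float) -> sp.csr_matrix:
    """Robin boundary mass: coef * integral(phi_i phi_j) over boundary faces."""
    faces = boundary.volume_nodes[boundary.faces]
    p = mesh.nodes[faces]
    area = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    base = (np.ones((3, 3)) + np.eye(3)) / 12.0
    Be = coef * area[:, None, None] * base[None]
    i = np.repeat(faces, 3, axis=1).ravel()
    j = np.tile(faces, (1, 3)).ravel()
    return sp.coo_matrix((Be.ravel(), (i, j)), shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()


def _tissue_to_nodes(mesh: TetHeadMesh, per_tissue: dict[str, float], vol) -> np.ndarray:
    """Volume-weighted average of element tissue values onto nodes."""
    elem_val = np.array([per_tissue[str(t)] for t in mesh.tissue])
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    np.add.at(num, mesh.tets.ravel(), np.repeat(elem_val * vol, 4))
    np.add.at(den, mesh.tets.ravel(), np.repeat(vol, 4))
    return num / den


# ---------------------------------------------------------------------------
# solver

class DiffusionSolver:
    """Factorised CW diffusion operator for one mesh/properties/wavelength.

    Assembles K = S(kappa) + M(mu_a) + (1/2A) B once and LU-factorises it;
    ``solve`` then handles any number of right-hand sides, which makes the
    many source/detector solves of a whole-cap Jacobian cheap.
    """

    def __init__(
        self,
        mesh: TetHeadMesh,
        props: OpticalProperties,
        wavelength: float,
        scalp: TriSurface | None = None,
    ):
        self.mesh = mesh
        self.props = props
        self.wavelength = float(wavelength)
        self.scalp = scalp if scalp is not None else mesh.scalp_surface()
        grads, vol = _tet_gradients(mesh)
        if np.any(vol <= 0):
            raise ValueError("mesh contains inverted tetrahedra")
        self.vol = vol
        wl = self.wavelength
        mua_t = {t: props.mua[t][wl] for t in props.mua}
        musp_t = {t: props.musp_floored(t, wl) for t in props.musp}
        self.mua_nodal = _tissue_to_nodes(mesh, mua_t, vol)
        kappa_e = np.array(
            [1.0 / (3.0 * (mua_t[str(t)] + musp_t[str(t)])) for t in mesh.tissue]
        )
        self.kappa_e = kappa_e
        A = _reflection_factor(props.n)
        K = (
            _assemble_stiffness(mesh, grads, vol, kappa_e)
            + _assemble_mass_nodal(mesh, vol, self.mua_nodal)
            + _assemble_boundary(mesh, self.scalp, 1.0 / (2.0 * A))
        )
        self.system = K
        try:
            self._lu = splu(K.tocsc())
        except RuntimeError as err:  # singular: disconnected mesh etc.
            raise ValueError(f"diffusion system could not be factorised: {err}") from err
        self._tet_tree = cKDTree(mesh.nodes[mesh.tets].mean(axis=1))
        self._grads = grads

    # -- source placement ---------------------------------------------------

    def _barycentric_load(self, point: np.ndarray) -> sp.csc_matrix:
        """Unit point source as barycentric weights in the enclosing tet."""
        point = np.asarray(point, float)
        _, cand = self._tet_tree.query(point, k=min(40, len(self.mesh.tets)))
        cand = np.atleast_1d(cand)
        best, best_min = None, -np.inf
        for e in cand:
            tet = self.mesh.tets[e]
            p0 = self.mesh.nodes[tet[0]]
            lam123 = (point - p0) @ np.linalg.pinv(
                np.stack(
                    [
                        self.mesh.nodes[tet[1]] - p0,
                        self.mesh.nodes[tet[2]] - p0,
                        self.mesh.nodes[tet[3]] - p0,
                    ]
                )
            )
            lam = np.concatenate([[1.0 - lam123.sum()], lam123])
            m = lam.min()
            if m > best_min:
                best, best_min = (tet, lam), m
            if m >= -1e-9:
                break
        tet, lam = best
        lam = np.clip(lam, 0.0, None)
        lam = lam / lam.sum()
        rhs = np.zeros(self.mesh.n_nodes)
        rhs[tet] = lam
        return rhs

    def bury(self, position: np.ndarray, tissue: str = "ECT") -> np.ndarray:
        """Move a scalp position one transport mean free path inward."""
        wl = self.wavelength
        ltr = 1.0 / (self.props.mua[tissue][wl] + self.props.musp_floored(tissue, wl))
        centre = self.mesh.nodes.mean(axis=0)
        # inward direction: towards the nearest scalp vertex normal flipped
        tm = self.scalp.as_trimesh()
        vi = cKDTree(np.asarray(tm.vertices)).query(np.asarray(position, float))[1]
        n = np.asarray(tm.vertex_normals)[vi]
        inward = -n / np.linalg.norm(n)
        if inward @ (centre - np.asarray(position, float)) < 0:
            inward = -inward
        return np.asarray(position, float) + ltr * inward

    def load_vector(self, position, buried: bool = True) -> np.ndarray:
        p = self.bury(position) if buried else np.asarray(position, float)
        return self._barycentric_load(p)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve K Phi = rhs; rhs may be (N,) or (N, k)."""
        return self._lu.solve(np.asarray(rhs))

    def fluence(self, position, buried: bool = True) -> np.ndarray:
        return self.solve(self.load_vector(position, buried=buried))


def solve_diffusion(
    mesh: TetHeadMesh,
    props: OpticalProperties,
    source_position,
    wavelength: float,
    buried: bool = True,
    scalp: TriSurface | None = None,
) -> np.ndarray:
    """One-shot nodal fluence for a single source (see DiffusionSolver)."""
    solver = DiffusionSolver(mesh, props, wavelength, scalp=scalp)
    return solver.fluence(source_position, buried=buried)


# ---------------------------------------------------------------------------
# Jacobian

@dataclass
class JacobianMatrix:
    """Sensitivity of channel Delta OD to nodal absorption change.

    ``data`` has one row per (channel, wavelength) measurement in the order
    of ``measurements`` (columns: channel, source, detector, wavelength,
    separation); columns are volume-mesh nodes.
    """

    data: np.ndarray  # (n_meas, n_nodes)
    channel: np.ndarray  # (n_meas,) dual-wavelength channel id
    source: np.ndarray
    detector: np.ndarray
    wavelength: np.ndarray
    separation: np.ndarray
    amplitude: np.ndarray  # model baseline intensity per measurement

    def rows_for_wavelength(self, wl: float) -> np.ndarray:
        return np.flatnonzero(np.isclose(self.wavelength, wl))

    def select(self, rows) -> "JacobianMatrix":
        rows = np.asarray(rows)
        return JacobianMatrix(
            data=self.data[rows],
            channel=self.channel[rows],
            source=self.source[rows],
            detector=self.detector[rows],
            wavelength=self.wavelength[rows],
            separation=self.separation[rows],
            amplitude=self.amplitude[rows],
        )


def _incidence(mesh: TetHeadMesh) -> sp.csr_matrix:
    """Node x (element, local-vertex) incidence for fast per-node scatter."""
    tets = mesh.tets
    ne4 = tets.size
    return sp.csr_matrix(
        (np.ones(ne4), (tets.ravel(), np.arange(ne4))), shape=(mesh.n_nodes, ne4)
    )


def _adjoint_rows_batch(
    solver: DiffusionSolver,
    inc: sp.csr_matrix,
    phi_s: np.ndarray,  # (N, B) source fields per channel in batch
    phi_d: np.ndarray,  # (N, B) detector fields per channel in batch
) -> np.ndarray:
    """Exact discrete d(Delta OD)/d(mu_a nodal), unnormalised by amplitude.

    Expands sum_ij (int phi_n phi_i phi_j) a_i b_j over each tet in closed
    form (the P1 moment integral is V/120 times 1 + coincidence factors)
    and accumulates per node through the node-element incidence.  Returns
    (N, B).
    """
    mesh, vol = solver.mesh, solver.vol
    tets = mesh.tets
    a = phi_d[tets]  # (E, 4, B)
    b = phi_s[tets]
    Sa, Sb = a.sum(axis=1), b.sum(axis=1)  # (E, B)
    dot = (a * b).sum(axis=1)
    base = vol[:, None] * (Sa * Sb + dot)  # n-independent part (E, B)
    per_node = (
        base[:, None, :]
        + vol[:, None, None] * (a * Sb[:, None, :] + b * Sa[:, None, :] + 2.0 * a * b)
    ) / 120.0
    return inc @ per_node.reshape(tets.size, -1)


def compute_jacobian(
    mesh: TetHeadMesh,
    props: OpticalProperties,
    optodes,
    channels,
    wavelengths=(735.0, 850.0),
    scalp: TriSurface | None = None,
) -> JacobianMatrix:
    """Adjoint (Rytov) Jacobian for every channel at every wavelength.

    ``optodes`` provides ``source_positions`` / ``detector_positions``;
    ``channels`` is a list of dual-wavelength Channel records.  Rows are
    ordered wavelength-major, channel-minor.  Reciprocity (swap source and
    detector) is exact because source and adjoint loads are constructed
    identically.
    """
    if scalp is None:
        scalp = mesh.scalp_surface()
    src = np.asarray(optodes.source_positions, float)
    det = np.asarray(optodes.detector_positions, float)
    n_src, n_det = len(src), len(det)
    for ch in channels:
        if ch.source_index >= n_src or ch.detector_index >= n_det:
            raise ValueError(
                f"channel references unknown optode (source {ch.source_index}, "
                f"detector {ch.detector_index})"
            )
    rows, meta = [], {"channel": [], "source": [], "detector": [], "wavelength": [],
                      "separation": [], "amplitude": []}
    inc = _incidence(mesh)
    s_idx = np.array([ch.source_index for ch in channels], dtype=int)
    d_idx = np.array([ch.detector_index for ch in channels], dtype=int)
    batch = 64
    for wl in wavelengths:
        solver = DiffusionSolver(mesh, props, wl, scalp=scalp)
        src_loads = np.stack([solver.load_vector(p) for p in src], axis=1)
        det_loads = np.stack([solver.load_vector(p) for p in det], axis=1)
        phi_src = solver.solve(src_loads)  # (N, n_src)
        phi_det = solver.solve(det_loads)  # (N, n_det)
        amps = np.einsum("nc,nc->c", det_loads[:, d_idx], phi_src[:, s_idx])
        for lo in range(0, len(channels), batch):
            sl = slice(lo, min(lo + batch, len(channels)))
            block = _adjoint_rows_batch(
                solver, inc, phi_src[:, s_idx[sl]], phi_det[:, d_idx[sl]]
            )  # (N, B)
            rows.append((block / amps[sl]).T)
        for k, ch in enumerate(channels):
            meta["channel"].append(k)
            meta["source"].append(ch.source_index)
            meta["detector"].append(ch.detector_index)
            meta["wavelength"].append(wl)
            meta["separation"].append(ch.separation)
            meta["amplitude"].append(amps[k])
    return JacobianMatrix(
        data=np.vstack(rows),
        channel=np.asarray(meta["channel"]),
        source=np.asarray(meta["source"]),
        detector=np.asarray(meta["detector"]),
        wavelength=np.asarray(meta["wavelength"]),
        separation=np.asarray(meta["separation"]),
        amplitude=np.asarray(meta["amplitude"]),
    )


# ---------------------------------------------------------------------------
# coverage

def coverage_threshold(
    mean_nodal_volume: float,
    delta_mua: float,
    pthresh: float = 1.0,
    actvol: float = 1000.0,
) -> float:
    """Jacobian magnitude above which a node counts as covered.

    A node is covered when an absorption change ``delta_mua`` (1/mm) in an
    ``actvol`` mm^3 block would change the measured intensity by more than
    ``pthresh`` percent: threshold = ln((100+pthresh)/100) / (delta_mua *
    actvol / V), with V the mesh's mean nodal (Voronoi) volume.
    """
    if mean_nodal_volume <= 0:
        raise ValueError("mean nodal volume must be positive")
    if delta_mua <= 0 or actvol <= 0 or pthresh < 0:
        raise ValueError("delta_mua and actvol must be positive, pthresh >= 0")
    return float(np.log((100.0 + pthresh) / 100.0) / (delta_mua * actvol / mean_nodal_volume))


@dataclass
class SensitivityMask:
    """Boolean coverage per cortical-surface node for one participant."""

    covered: np.ndarray  # (n_cortical,) bool
    participant: str = ""
    separation_band: tuple[float, float] | None = None


def surface_mapper(cortex: TriSurface, mesh: TetHeadMesh, radius: float = 3.0) -> sp.csr_matrix:
    """Sparse operator averaging volume-node fields onto cortical nodes.

    Row i averages (unweighted) over all volume nodes within ``radius`` mm
    of cortical node i; rows with no neighbour are left empty (callers see
    NaN via ``apply_surface_map``).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(mesh.nodes)
    neigh = tree.query_ball_point(cortex.vertices, r=radius)
    rows, cols, vals = [], [], []
    for i, nb in enumerate(neigh):
        if not nb:
            continue
        w = 1.0 / len(nb)
        rows.extend([i] * len(nb))
        cols.extend(nb)
        vals.extend([w] * len(nb))
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(cortex.vertices), mesh.n_nodes)
    )


def sensitivity_mask(
    J: JacobianMatrix,
    threshold: float,
    cortical_map: sp.csr_matrix,
    participant: str = "",
    separation_band: tuple[float, float] | None = None,
) -> SensitivityMask:
    """Binarised array coverage on the cortical surface.

    A cortical node is covered iff any retained measurement's sensitivity,
    mapped to the surface by the same 3 mm-radius mean used for images,
    exceeds the threshold.  Wavelengths present in J are combined by OR.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n_cort = cortical_map.shape[0]
    if len(J.data) == 0:
        return SensitivityMask(np.zeros(n_cort, dtype=bool), participant, separation_band)
    surf = cortical_map @ np.abs(J.data).T  # (n_cort, n_meas)
    covered = (surf > threshold).any(axis=1)
    return SensitivityMask(np.asarray(covered), participant, separation_band)


def group_coverage(
    masks: list[SensitivityMask], fraction: float = 0.75
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node coverage count and the 'at least 75% of participants' mask.

    Inclusion is boundary-inclusive: count / N >= fraction.
    """
    if not masks:
        raise ValueError("no masks given")
    n = len(masks[0].covered)
    for m in masks:
        if len(m.covered) != n:
            raise ValueError("masks defined on different cortical surfaces")
    count = np.sum([m.covered for m in masks], axis=0)
    include = count / len(masks) >= fraction - 1e-12
    return count, include
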