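"""Tikhonov image reconstruction, chromophore unmixing, surface mapping.

Block-averaged Delta OD is inverted per wavelength with a zeroth-order
Tikhonov-regularised pseudo-inverse in the underdetermined form

    x = J^T (J J^T + lambda * sigma * I)^(-1) y,

where sigma is the largest diagonal entry of J J^T, so the hyperparameter
lambda (default 0.01) is relative to the scale of the sensitivity matrix
(the usual DOT convention; pass ``relative=False`` for an absolute
lambda).  The per-wavelength absorption images are then unmixed node-wise
through the 2x2 extinction matrix into oxy-/deoxy-haemoglobin
concentration changes (HbO, HbR, micromolar), and mapped to the cortical
surface by an unweighted mean over volume nodes within 3 mm of each
cortical surface node.  Reconstruction uses good channels up to 40 mm
source-detector separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

from .forward import JacobianMatrix
from .preprocess import BLOCK_GRID, BlockAverage

__all__ = [
    "ExtinctionTable",
    "default_extinction",
    "TikhonovInverter",
    "invert_tikhonov",
    "unmix_chromophores",
    "map_to_surface",
    "apply_surface_map",
    "CorticalImageSeries",
    "reconstruct_series",
]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction of HbO and HbR per wavelength.

    ``epsilon[wavelength] = (eps_HbO, eps_HbR)`` in 1/(cm*M) (decadic, as
    compiled spectra are tabulated); ``matrix`` converts to the natural-log
    mm^-1 per micromolar units used by the absorption images.
    """

    epsilon: dict[float, tuple[float, float]]
    citation: str = ""

    def matrix(self, wavelengths=(735.0, 850.0)) -> np.ndarray:
        """E such that dmua(wl) [1/mm] = E @ (dHbO, dHbR) [uM]."""
        rows = []
        for wl in wavelengths:
            if wl not in self.epsilon:
                raise KeyError(f"no extinction entry for {wl} nm")
            e_hbo, e_hbr = self.epsilon[wl]
            rows.append([e_hbo, e_hbr])
        # decadic 1/(cm M) -> natural-log 1/mm per uM: ln10 / (10 mm/cm) / 1e6
        E = np.asarray(rows, float) * LN10 * 1e-7
        cond = np.linalg.cond(E)
        if not np.isfinite(cond) or cond > 100:
            raise ValueError(f"extinction matrix ill-conditioned (cond={cond:.3g})")
        return E


def default_extinction() -> ExtinctionTable:
    """Compiled haemoglobin spectra at the instrument wavelengths."""
    return ExtinctionTable(
        epsilon={735.0: (450.0, 1050.0), 850.0: (1058.0, 691.0)},
        citation="compiled in-vitro haemoglobin extinction spectra "
        "(Prahl/Gratzer compilation), 64.5 kg/mol haemoglobin",
    )


# ---------------------------------------------------------------------------
# Tikhonov

class TikhonovInverter:
    """Cached dual-form Tikhonov inverse for one sensitivity matrix.

    Factorises (J J^T + lambda * sigma * I) once; ``solve`` then maps any
    number of Delta OD columns to nodal Delta mu_a images.
    """

    def __init__(self, J: np.ndarray, lam: float = 0.01, relative: bool = True):
        J = np.asarray(J, float)
        if J.size == 0 or not np.any(J):
            raise ValueError("all-zero or empty sensitivity matrix")
        self.J = J
        gram = J @ J.T
        sigma = float(gram.diagonal().max()) if relative else 1.0
        self.effective_lambda = lam * sigma
        gram[np.diag_indices_from(gram)] += self.effective_lambda
        self._chol = la.cho_factor(gram, lower=True)

    def solve(self, y: np.ndarray) -> np.ndarray:
        """y: (n_meas,) or (n_meas, k) -> (n_nodes,) or (n_nodes, k)."""
        return self.J.T @ la.cho_solve(self._chol, np.asarray(y, float))


def invert_tikhonov(
    J, y: np.ndarray, lam: float = 0.01, relative: bool = True
) -> tuple[np.ndarray, float]:
    """One-shot zeroth-order Tikhonov solution; returns (x, effective lambda)."""
    Jm = J.data if isinstance(J, JacobianMatrix) else J
    inv = TikhonovInverter(Jm, lam=lam, relative=relative)
    return inv.solve(y), inv.effective_lambda


# ---------------------------------------------------------------------------
# spectral unmixing

def unmix_chromophores(
    dmua_by_wavelength: dict[float, np.ndarray], ext: ExtinctionTable
) -> tuple[np.ndarray, np.ndarray]:
    """Node-wise solve of dmua(wl) = E (dHbO, dHbR); returns uM images.

    Input images for the two wavelengths must share node ordering; shapes
    (n_nodes,) or (n_nodes, n_times).
    """
    wavelengths = sorted(dmua_by_wavelength)
    if len(wavelengths) != 2:
        raise ValueError("chromophore unmixing needs exactly two wavelengths")
    E = ext.matrix(wavelengths)
    a = np.asarray(dmua_by_wavelength[wavelengths[0]], float)
    b = np.asarray(dmua_by_wavelength[wavelengths[1]], float)
    if a.shape != b.shape:
        raise ValueError("wavelength images differ in shape")
    stacked = np.stack([a, b])  # (2, ...)
    Einv = np.linalg.inv(E)
    out = np.tensordot(Einv, stacked, axes=(1, 0))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# surface mapping

def map_to_surface(
    nodal_values: np.ndarray, surface_map: sp.csr_matrix
) -> np.ndarray:
    """Average nodal volume fields onto cortical-surface nodes.

    ``surface_map`` comes from :func:`hddot.forward.surface_mapper`; rows
    without any volume node in radius yield NaN (undefined).
    """
    vals = surface_map @ np.asarray(nodal_values, float)
    empty = np.asarray(surface_map.sum(axis=1)).ravel() == 0
    if vals.ndim == 1:
        vals[empty] = np.nan
    else:
        vals[empty, :] = np.nan
    return vals


apply_surface_map = map_to_surface


# ---------------------------------------------------------------------------
# full series

@dataclass
class CorticalImageSeries:
    """Delta HbO / Delta HbR (uM) per cortical node per block-grid time."""

    hbo: np.ndarray  # (n_cortical, n_times)
    hbr: np.ndarray
    grid: np.ndarray
    condition: str = ""
    participant: str = ""
    coverage: np.ndarray | None = None  # bool per cortical node

    def masked(self) -> "CorticalImageSeries":
        if self.coverage is None:
            return self
        hbo = np.where(self.coverage[:, None], self.hbo, np.nan)
        hbr = np.where(self.coverage[:, None], self.hbr, np.nan)
        return CorticalImageSeries(
            hbo=hbo, hbr=hbr, grid=self.grid, condition=self.condition,
            participant=self.participant, coverage=self.coverage,
        )


def reconstruct_series(
    blocks: dict[float, BlockAverage] | BlockAverage,
    J: JacobianMatrix,
    ext: ExtinctionTable,
    surface_map: sp.csr_matrix,
    good: np.ndarray | None = None,
    sep_max: float = 40.0,
    lam: float = 0.01,
    min_channels: int = 10,
    coverage: np.ndarray | None = None,
    inverters: dict[float, TikhonovInverter] | None = None,
) -> CorticalImageSeries:
    """Reconstruct a cortical HbO/HbR image series from one block average.

    ``blocks`` is a single BlockAverage whose channel table contains both
    wavelengths (rows aligned with J).  Good channels at or below
    ``sep_max`` mm are selected per wavelength, inverted, unmixed and
    surface-mapped.  Pre-built ``inverters`` (keyed by wavelength, built on
    the same channel selection) may be supplied to amortise the
    factorisation across participants and conditions.
    """
    block = blocks
    if good is None:
        good = np.ones(len(J.data), dtype=bool)
    good = np.asarray(good, bool)
    dmua: dict[float, np.ndarray] = {}
    for wl in np.unique(J.wavelength):
        rows = np.flatnonzero(good & (J.separation <= sep_max) & np.isclose(J.wavelength, wl))
        if len(rows) < min_channels:
            raise ValueError(
                f"only {len(rows)} usable channels at {wl} nm (minimum {min_channels})"
            )
        y = block.data[rows]
        if inverters is not None and wl in inverters:
            inv = inverters[wl]
        else:
            inv = TikhonovInverter(J.data[rows], lam=lam)
        dmua[float(wl)] = inv.solve(y)
    hbo, hbr = unmix_chromophores(dmua, ext)
    return CorticalImageSeries(
        hbo=map_to_surface(hbo, surface_map),
        hbr=map_to_surface(hbr, surface_map),
        grid=block.grid.copy(),
        condition=block.condition,
        coverage=coverage,
    )
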