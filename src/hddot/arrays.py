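"""Whole-head cap geometry: hexagonal optode tiles, dock layout, channels.

The headgear modelled here is a soft cap carrying 33 hexagonal
source–detector modules ("tiles"), each with three dual-wavelength LED
sources (735 and 850 nm) and four photodiode detectors.  Within a tile,
every source–detector pair is separated by either ~10 mm or ~20 mm.  With
all docks occupied the cap carries 99 sources and 132 detectors, and pairing
every source with every detector yields 13,068 dual-wavelength channels.

A *dual-wavelength channel* is one (source position, detector) pair; the
two wavelengths of the LED at that position share the channel record.  The
per-wavelength measurement count is therefore twice the channel count.

The tile-local layout and the cap's dock poses are data (YAML), not code:
the exact manufactured coordinates are proprietary, so the packaged layout
is a documented canonical stand-in that reproduces the 10/20 mm intra-tile
structure and an even whole-scalp dock distribution on a reference scalp
sphere.  Substituting a vendor digitisation is a matter of swapping the
file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

NOMINAL_WAVELENGTHS = (735.0, 850.0)

__all__ = [
    "TileSpec",
    "CapLayout",
    "OptodeArray",
    "Channel",
    "default_tile",
    "default_cap_layout",
    "load_tile",
    "load_cap_layout",
    "build_array",
    "enumerate_channels",
    "channels_to_frame",
    "separation_histogram",
]


@dataclass(frozen=True)
class TileSpec:
    """Tile-local optode geometry (planar, mm) and nominal wavelengths."""

    source_offsets: np.ndarray  # (3, 2)
    detector_offsets: np.ndarray  # (4, 2)
    wavelengths: tuple[float, ...] = NOMINAL_WAVELENGTHS

    def __post_init__(self):
        src = np.asarray(self.source_offsets, dtype=float)
        det = np.asarray(self.detector_offsets, dtype=float)
        if src.shape != (3, 2):
            raise ValueError(f"expected 3 planar sources, got shape {src.shape}")
        if det.shape != (4, 2):
            raise ValueError(f"expected 4 planar detectors, got shape {det.shape}")
        object.__setattr__(self, "source_offsets", src)
        object.__setattr__(self, "detector_offsets", det)

    def intra_tile_separations(self) -> np.ndarray:
        """All 12 source–detector distances (mm)."""
        d = self.source_offsets[:, None, :] - self.detector_offsets[None, :, :]
        return np.linalg.norm(d, axis=-1).ravel()


@dataclass(frozen=True)
class CapLayout:
    """Dock poses of the reference cap on a reference scalp.

    Each dock pose is a centre position (mm), an outward unit normal and an
    in-plane orientation vector (tile-local +x transported to 3-D).  The
    landmark template and the anterior midline dot live in the same frame.
    """

    dock_positions: np.ndarray  # (n_docks, 3)
    dock_normals: np.ndarray  # (n_docks, 3)
    dock_orientations: np.ndarray  # (n_docks, 3)
    landmarks: dict[str, np.ndarray]  # Nz, Iz, Ar, Al, Cz
    midline_dot: np.ndarray  # (3,)
    scalp_radius: float  # reference scalp sphere radius, mm

    @property
    def n_docks(self) -> int:
        return len(self.dock_positions)


@dataclass
class OptodeArray:
    """Global optode positions (mm) with tile membership."""

    source_positions: np.ndarray  # (n_src, 3)
    detector_positions: np.ndarray  # (n_det, 3)
    source_tile: np.ndarray  # (n_src,) dock index
    detector_tile: np.ndarray  # (n_det,) dock index
    wavelengths: tuple[float, ...] = NOMINAL_WAVELENGTHS

    @property
    def n_sources(self) -> int:
        return len(self.source_positions)

    @property
    def n_detectors(self) -> int:
        return len(self.detector_positions)


@dataclass(frozen=True)
class Channel:
    """One dual-wavelength source–detector pairing."""

    source_index: int
    detector_index: int
    separation: float  # mm, Euclidean
    wavelengths: tuple[float, ...] = NOMINAL_WAVELENGTHS


def default_tile() -> TileSpec:
    """Canonical hexagonal tile reproducing the 10/20 mm intra-tile pairs.

    Sources sit at radius 10 mm at azimuths 0/120/240 deg; detectors at the
    tile centre and radius 10 mm at azimuths 60/180/300 deg.  Every
    source–detector pair is then at exactly 10 mm (centre and the two
    adjacent ring detectors) or 20 mm (the diametrically opposite one).
    """
    r = 10.0
    ang_src = np.deg2rad([0.0, 120.0, 240.0])
    ang_det = np.deg2rad([60.0, 180.0, 300.0])
    src = np.column_stack([r * np.cos(ang_src), r * np.sin(ang_src)])
    det = np.vstack([[0.0, 0.0], np.column_stack([r * np.cos(ang_det), r * np.sin(ang_det)])])
    return TileSpec(source_offsets=src, detector_offsets=det)


def _fibonacci_cap_points(n: int, radius: float, z_min_frac: float) -> np.ndarray:
    """n roughly-even points on the spherical cap z/R in [z_min_frac, 1]."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    z = z_min_frac + (i + 0.5) / n * (1.0 - z_min_frac)
    phi = i * golden
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return radius * pts


def default_cap_layout(n_docks: int = 33, scalp_radius: float = 71.6) -> CapLayout:
    """Reference 33-dock whole-head layout on a 45 cm-circumference scalp sphere.

    Docks are spread over the spherical cap above ~5 deg elevation (clearing
    the ears and face) by a Fibonacci spiral, which gives a near-uniform
    inter-tile spacing of ~30 mm and hence a continuum of between-tile
    channel separations from ~10 mm upward.  This is a template
    approximation of the manufactured cap, not ground truth.
    """
    z_min = np.sin(np.deg2rad(5.0))
    pos = _fibonacci_cap_points(n_docks, scalp_radius, z_min)
    nrm = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    # in-plane orientation: local "east" (tangent along increasing azimuth)
    east = np.column_stack([-pos[:, 1], pos[:, 0], np.zeros(len(pos))])
    bad = np.linalg.norm(east, axis=1) < 1e-9  # pole dock
    east[bad] = [1.0, 0.0, 0.0]
    east /= np.linalg.norm(east, axis=1, keepdims=True)
    east -= (east * nrm).sum(axis=1, keepdims=True) * nrm
    east /= np.linalg.norm(east, axis=1, keepdims=True)

    el = np.deg2rad(8.0)  # landmarks sit slightly above the cap brim
    c, s = np.cos(el), np.sin(el)
    R = scalp_radius
    landmarks = {
        "Nz": np.array([0.0, R * c, R * s]),
        "Iz": np.array([0.0, -R * c, R * s]),
        "Ar": np.array([R * c, 0.0, R * s]),
        "Al": np.array([-R * c, 0.0, R * s]),
        "Cz": np.array([0.0, 0.0, R]),
    }
    el_dot = np.deg2rad(16.0)  # anterior white dot just above the nasion
    midline_dot = np.array([0.0, R * np.cos(el_dot), R * np.sin(el_dot)])
    return CapLayout(
        dock_positions=pos,
        dock_normals=nrm,
        dock_orientations=east,
        landmarks=landmarks,
        midline_dot=midline_dot,
        scalp_radius=scalp_radius,
    )


# ---------------------------------------------------------------------------
# YAML round trip (units are mm throughout)

def save_cap_layout(layout: CapLayout, path) -> None:
    doc = {
        "units": "mm",
        "scalp_radius": float(layout.scalp_radius),
        "docks": [
            {
                "position": [float(v) for v in p],
                "normal": [float(v) for v in n],
                "orientation": [float(v) for v in o],
            }
            for p, n, o in zip(layout.dock_positions, layout.dock_normals, layout.dock_orientations)
        ],
        "landmarks": {k: [float(x) for x in v] for k, v in layout.landmarks.items()},
        "midline_dot": [float(v) for v in layout.midline_dot],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_cap_layout(path=None) -> CapLayout:
    """Load a cap layout from YAML; default: the packaged reference layout."""
    if path is None:
        ref = importlib.resources.files("hddot.data") / "cap_layout.yaml"
        with importlib.resources.as_file(ref) as p:
            return load_cap_layout(p)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    docks = doc["docks"]
    return CapLayout(
        dock_positions=np.array([d["position"] for d in docks], dtype=float),
        dock_normals=np.array([d["normal"] for d in docks], dtype=float),
        dock_orientations=np.array([d["orientation"] for d in docks], dtype=float),
        landmarks={k: np.array(v, dtype=float) for k, v in doc["landmarks"].items()},
        midline_dot=np.array(doc["midline_dot"], dtype=float),
        scalp_radius=float(doc["scalp_radius"]),
    )


def save_tile(tile: TileSpec, path) -> None:
    doc = {
        "units": "mm",
        "source_offsets": tile.source_offsets.tolist(),
        "detector_offsets": tile.detector_offsets.tolist(),
        "wavelengths_nm": list(tile.wavelengths),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_tile(path=None) -> TileSpec:
    if path is None:
        ref = importlib.resources.files("hddot.data") / "tile.yaml"
        with importlib.resources.as_file(ref) as p:
            return load_tile(p)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return TileSpec(
        source_offsets=np.array(doc["source_offsets"], dtype=float),
        detector_offsets=np.array(doc["detector_offsets"], dtype=float),
        wavelengths=tuple(float(w) for w in doc["wavelengths_nm"]),
    )


# ---------------------------------------------------------------------------
# Array construction and channel enumeration

def _dock_frame(layout: CapLayout, d: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = layout.dock_normals[d]
    e1 = layout.dock_orientations[d]
    e1 = e1 - (e1 @ n) * n
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return layout.dock_positions[d], e1, e2


def build_array(layout: CapLayout, tile: TileSpec, filled_docks=None) -> OptodeArray:
    """Place a tile in each filled dock; dock indices are 0-based.

    Tile-local (x, y) offsets are mapped into the dock's tangent frame, so
    the optodes lie on the plane tangent to the reference scalp at the dock
    centre.
    """
    if filled_docks is None:
        filled_docks = range(layout.n_docks)
    filled = sorted(set(int(d) for d in filled_docks))
    bad = [d for d in filled if d < 0 or d >= layout.n_docks]
    if bad:
        raise ValueError(f"unknown dock indices {bad}; cap has docks 0..{layout.n_docks - 1}")
    src_pos, det_pos, src_tile, det_tile = [], [], [], []
    for d in filled:
        centre, e1, e2 = _dock_frame(layout, d)
        for xy in tile.source_offsets:
            src_pos.append(centre + xy[0] * e1 + xy[1] * e2)
            src_tile.append(d)
        for xy in tile.detector_offsets:
            det_pos.append(centre + xy[0] * e1 + xy[1] * e2)
            det_tile.append(d)
    return OptodeArray(
        source_positions=np.array(src_pos, dtype=float).reshape(-1, 3),
        detector_positions=np.array(det_pos, dtype=float).reshape(-1, 3),
        source_tile=np.array(src_tile, dtype=int),
        detector_tile=np.array(det_tile, dtype=int),
        wavelengths=tile.wavelengths,
    )


def enumerate_channels(array: OptodeArray, max_separation: float | None = None) -> list[Channel]:
    """All (source position, detector) pairings as dual-wavelength channels.

    ``max_separation`` (mm) keeps only channels at or below that Euclidean
    separation; ``None`` is unlimited.
    """
    if max_separation is not None and max_separation < 0:
        raise ValueError(f"max_separation must be non-negative, got {max_separation}")
    if array.n_sources == 0 or array.n_detectors == 0:
        return []
    sep = np.linalg.norm(
        array.source_positions[:, None, :] - array.detector_positions[None, :, :], axis=-1
    )
    si, di = np.nonzero(np.ones_like(sep, dtype=bool))
    seps = sep[si, di]
    if max_separation is not None:
        keep = seps <= max_separation
        si, di, seps = si[keep], di[keep], seps[keep]
    return [
        Channel(int(s), int(d), float(r), array.wavelengths)
        for s, d, r in zip(si, di, seps)
    ]


def channels_to_frame(channels: list[Channel]) -> pd.DataFrame:
    """Per-wavelength measurement table: one row per (channel, wavelength)."""
    rows = []
    for k, ch in enumerate(channels):
        for wl in ch.wavelengths:
            rows.append(
                {
                    "channel": k,
                    "source": ch.source_index,
                    "detector": ch.detector_index,
                    "wavelength": wl,
                    "separation": ch.separation,
                }
            )
    return pd.DataFrame(rows)


def separation_histogram(
    channels: list[Channel], bin_width: float = 5.0, offset: float = 2.5
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of channel separations with half-open bins [lo, hi).

    Bins are offset so that, with the default 5 mm width, the bin labelled
    "30 mm" spans [27.5, 32.5) — bin centres land on multiples of the width.
    Returns ``(edges, counts)`` with ``len(edges) = len(counts) + 1``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    seps = np.array([c.separation for c in channels], dtype=float)
    if len(seps) == 0:
        return np.array([0.0, bin_width]) - offset + bin_width, np.zeros(1, dtype=int)
    lo = np.floor((seps.min() + offset) / bin_width) * bin_width - offset
    hi = seps.max()
    n_bins = int(np.floor((hi - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.floor((seps - lo) / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts
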