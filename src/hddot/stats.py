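"""Group-level node-wise statistics on cortical image series.

For each cortical node, haemoglobin concentration changes within the
response window (default 11-15 s post-stimulus, capturing the infant
haemodynamic peak) are concatenated across participants and grid samples
into one vector and tested with a one-sample t-test against zero; the two
experimental conditions are compared with a paired t-test on the aligned
vectors.  Only nodes covered in at least 75% of participants are tested,
and significance is Bonferroni-controlled over the number of tested
nodes.  Seed regions are defined as all cortical nodes within 5 mm of a
peak (or peak-negative) node of the group map, and seed time-courses are
participant means over the region, averaged across participants with the
standard error of the mean.

Note the concatenation across time samples follows the block-average
convention of the analysis it implements and inflates the nominal degrees
of freedom (df = vector length - 1, reported as such); a participant-mean
mode (one value per participant) is available via ``participant_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .reconstruct import CorticalImageSeries

__all__ = [
    "WindowSpec",
    "StatMap",
    "SeedRegion",
    "window_values",
    "one_sample_tmap",
    "paired_tmap",
    "define_seed",
    "seed_timecourse",
]


@dataclass(frozen=True)
class WindowSpec:
    """Post-stimulus response window, seconds (0 <= start < end <= 20)."""

    start: float = 11.0
    end: float = 15.0

    def __post_init__(self):
        if not (0 <= self.start < self.end <= 20):
            raise ValueError(f"invalid window {self.start}-{self.end} s")

    def grid_mask(self, grid: np.ndarray) -> np.ndarray:
        return (grid >= self.start - 1e-9) & (grid <= self.end + 1e-9)


@dataclass
class StatMap:
    """Node-wise t statistics with Bonferroni-corrected significance."""

    t: np.ndarray  # (n_nodes,), NaN where untested
    p: np.ndarray
    df: np.ndarray
    significant: np.ndarray  # bool
    tested: np.ndarray  # bool
    n_tested: int
    alpha: float
    label: str = ""


@dataclass
class SeedRegion:
    """Peak-centred cortical region: all nodes within ``radius`` mm."""

    centre: int
    members: np.ndarray  # node indices, centre included
    polarity: str  # "peak-positive" | "peak-negative"
    label: str = ""
    radius: float = 5.0


def window_values(
    images: list[CorticalImageSeries],
    window: WindowSpec,
    chromophore: str = "hbo",
    participant_mean: bool = False,
) -> np.ndarray:
    """Concatenated response vectors, (n_nodes, n_participants * n_window).

    Window samples are grid times t with start <= t <= end (inclusive).
    Participants uncovered at a node contribute NaN entries there, which
    the t-map operations drop per node.  With ``participant_mean`` each
    participant contributes one value per node (the window mean).
    """
    if not images:
        raise ValueError("no image series given")
    grid = images[0].grid
    sel = window.grid_mask(grid)
    cols = []
    for im in images:
        if im.hbo.shape[0] != images[0].hbo.shape[0] or len(im.grid) != len(grid):
            raise ValueError("image series do not share surface/grid")
        data = getattr(im, chromophore)
        block = np.asarray(data)[:, sel]
        if im.coverage is not None:
            block = np.where(im.coverage[:, None], block, np.nan)
        if participant_mean:
            block = np.nanmean(block, axis=1, keepdims=True)
        cols.append(block)
    return np.concatenate(cols, axis=1)


def _t_one_sample(vec: np.ndarray) -> tuple[float, float, float]:
    v = vec[np.isfinite(vec)]
    n = len(v)
    if n < 2:
        return np.nan, np.nan, np.nan
    sd = v.std(ddof=1)
    if sd == 0:
        return np.nan, np.nan, float(n - 1)
    t = v.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p), float(n - 1)


def one_sample_tmap(
    vectors: np.ndarray,
    tested: np.ndarray,
    alpha: float = 0.05,
    label: str = "",
) -> StatMap:
    """Node-wise one-sample t against zero, Bonferroni over tested nodes.

    ``vectors`` is (n_nodes, n_values); ``tested`` the group-coverage
    inclusion mask.  Zero-variance or under-sampled nodes get NaN t and
    are excluded from significance (never declared significant).
    """
    tested = np.asarray(tested, bool)
    n_nodes = vectors.shape[0]
    t = np.full(n_nodes, np.nan)
    p = np.full(n_nodes, np.nan)
    df = np.full(n_nodes, np.nan)
    for i in np.flatnonzero(tested):
        t[i], p[i], df[i] = _t_one_sample(vectors[i])
    n_tested = int(tested.sum())
    thresh = alpha / max(n_tested, 1)
    significant = np.zeros(n_nodes, dtype=bool)
    ok = tested & np.isfinite(p)
    significant[ok] = p[ok] < thresh
    return StatMap(
        t=t, p=p, df=df, significant=significant, tested=tested,
        n_tested=n_tested, alpha=alpha, label=label,
    )


def paired_tmap(
    values_a: np.ndarray,
    values_b: np.ndarray,
    tested: np.ndarray,
    alpha: float = 0.05,
    label: str = "",
) -> StatMap:
    """Paired t-test per node: one-sample t on A - B (positive = A larger).

    A and B must be element-wise aligned (same participant/sample order).
    """
    if values_a.shape != values_b.shape:
        raise ValueError("paired value arrays differ in shape")
    return one_sample_tmap(values_a - values_b, tested, alpha=alpha, label=label)


def define_seed(
    group_map: np.ndarray,
    region_mask: np.ndarray,
    vertices: np.ndarray,
    radius: float = 5.0,
    polarity: str = "peak-positive",
    label: str = "",
) -> SeedRegion:
    """Seed region around the extremal node of a group map within a mask.

    The centre is the argmax (``peak-positive``) or argmin
    (``peak-negative``) of the map over ``region_mask``; members are all
    cortical nodes within ``radius`` mm (Euclidean) of the centre.  Ties
    resolve to the lowest node index.
    """
    region_mask = np.asarray(region_mask, bool)
    vals = np.where(region_mask, np.asarray(group_map, float), np.nan)
    if not np.isfinite(vals).any():
        raise ValueError("region mask is empty or entirely uncovered")
    if polarity == "peak-negative":
        centre = int(np.nanargmin(vals))
    elif polarity == "peak-positive":
        centre = int(np.nanargmax(vals))
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    d = np.linalg.norm(vertices - vertices[centre], axis=1)
    members = np.flatnonzero(d <= radius + 1e-12)
    return SeedRegion(centre=centre, members=members, polarity=polarity,
                      label=label, radius=radius)


def seed_timecourse(
    images: list[CorticalImageSeries],
    seed: SeedRegion,
    chromophore: str = "hbo",
) -> dict[str, np.ndarray]:
    """Group mean +- SEM time-course over the seed region.

    Per participant, the spatial mean over seed members (covered members
    only); then mean and SEM (sd/sqrt(n)) across participants per grid
    time.  Participants with no covered member are excluded and reported.
    """
    per_participant = []
    excluded = []
    for k, im in enumerate(images):
        data = np.asarray(getattr(im, chromophore), float)[seed.members]
        if im.coverage is not None:
            cov = im.coverage[seed.members]
            data = data[cov]
        if data.size == 0 or not np.isfinite(data).any():
            excluded.append(k)
            continue
        per_participant.append(np.nanmean(data, axis=0))
    if not per_participant:
        raise ValueError("no participant covers the seed region")
    stack = np.vstack(per_participant)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return {
        "grid": images[0].grid.copy(),
        "mean": mean,
        "sem": sem,
        "n": np.array(n),
        "excluded": np.array(excluded, dtype=int),
    }
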