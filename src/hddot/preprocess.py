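"""Channel QC, Delta-OD conversion, motion correction and block averaging.

The preprocessing chain follows the standard Homer-style fNIRS sequence,
in this fixed order:

    channel QC -> intensity to Delta OD -> motion detection ->
    spline correction -> wavelet correction -> trial validation ->
    block average onto the canonical -2..20 s, 4 Hz grid (89 samples)

Defaults throughout are the study values: a good channel has
coefficient of variation < 8%, mean intensity > 5e-5 V and separation
< 60 mm; motion detection uses tMotion = tMask = 1.0 s, AMPthresh = 0.5,
STDEVthresh = 15; the spline smoothing parameter is p = 0.99 and the
wavelet outlier fence is a = 0.8 interquartile ranges.  An experimental
trial is valid when the infant looked at the screen for at least 60% of
it and it was not preceded by an alerting sound; a participant needs at
least three valid trials of each experimental condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.linalg import solveh_banded
from scipy.ndimage import maximum_filter1d, minimum_filter1d

__all__ = [
    "RawRecording",
    "ODTimeSeries",
    "TrialLog",
    "BlockAverage",
    "BLOCK_GRID",
    "qc_channels",
    "intensity_to_od",
    "detect_motion",
    "find_clean_segment",
    "correct_spline",
    "correct_wavelet",
    "validate_trials",
    "block_average",
    "smoothing_spline",
]

#: canonical block-average grid: -2 .. 20 s inclusive at 4 Hz (89 samples)
BLOCK_GRID = np.round(np.arange(-8, 81) * 0.25, 10)

EXPERIMENTAL_CONDITIONS = ("social", "non-social")


@dataclass
class RawRecording:
    """Multichannel optical intensity time series (volts).

    ``channels`` is a per-row measurement table with at least the columns
    ``source``, ``detector``, ``wavelength`` (nm) and ``separation`` (mm).
    """

    intensity: np.ndarray  # (n_meas, n_samples) V
    fs: float  # Hz
    channels: pd.DataFrame
    participant: str = ""

    def __post_init__(self):
        self.intensity = np.atleast_2d(np.asarray(self.intensity, float))
        if len(self.channels) != len(self.intensity):
            raise ValueError("channel table and intensity row count differ")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.intensity.shape[1]) / self.fs


@dataclass
class ODTimeSeries:
    """Change in optical density, -ln(I / mean(I)), per measurement row."""

    od: np.ndarray  # (n_meas, n_samples)
    fs: float
    channels: pd.DataFrame
    mean_intensity: np.ndarray  # (n_meas,) for invertibility
    participant: str = ""

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.od.shape[1]) / self.fs

    def to_intensity(self) -> np.ndarray:
        return self.mean_intensity[:, None] * np.exp(-self.od)


@dataclass
class TrialLog:
    """Stimulus presentation log.

    One row per trial: ``condition`` in {social, non-social, baseline},
    ``onset`` (s), ``duration`` (s), ``looking_fraction`` in [0, 1] and
    ``alert_flag`` (trial followed an attention-alerting sound).
    """

    trials: pd.DataFrame

    def __post_init__(self):
        t = self.trials.sort_values("onset").reset_index(drop=True)
        if (t["duration"] <= 0).any():
            raise ValueError("trial durations must be positive")
        ends = t["onset"] + t["duration"]
        if (t["onset"].values[1:] < ends.values[:-1] - 1e-9).any():
            raise ValueError("trials overlap")
        self.trials = t


@dataclass
class BlockAverage:
    """Per-channel epoch mean on the canonical grid for one condition."""

    data: np.ndarray  # (n_meas, 89)
    condition: str
    n_trials: int
    channels: pd.DataFrame
    grid: np.ndarray = field(default_factory=lambda: BLOCK_GRID.copy())


# ---------------------------------------------------------------------------
# channel QC

def qc_channels(
    rec: RawRecording,
    clean_segment: tuple[float, float] | None = None,
    cov_thresh: float = 8.0,
    intensity_thresh: float = 5e-5,
    separation_thresh: float = 60.0,
) -> pd.DataFrame:
    """Good-channel criteria: CoV, mean intensity, separation.

    A channel passes when its coefficient of variation (std/mean of raw
    intensity, in percent, computed on ``clean_segment`` — the whole
    recording by default) is below ``cov_thresh``, its mean intensity
    exceeds ``intensity_thresh`` volts, and its source-detector separation
    is below ``separation_thresh`` mm.  Returns the QC report with
    pass/fail and failure reasons per measurement row.
    """
    x = rec.intensity
    if clean_segment is not None:
        lo, hi = clean_segment
        if lo < 0 or hi * rec.fs > x.shape[1] + 1e-9 or hi <= lo:
            raise ValueError("clean segment outside recording")
        x = x[:, int(round(lo * rec.fs)): int(round(hi * rec.fs))]
    mean = x.mean(axis=1)
    std = x.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(mean > 0, 100.0 * std / mean, np.inf)
    sep = rec.channels["separation"].to_numpy()
    fail_cov = ~(cov < cov_thresh)
    fail_int = ~(mean > intensity_thresh)
    fail_sep = ~(sep < separation_thresh)
    reasons = [
        ",".join(
            r for r, f in (("cov", fc), ("intensity", fi), ("separation", fsp)) if f
        )
        for fc, fi, fsp in zip(fail_cov, fail_int, fail_sep)
    ]
    report = rec.channels.copy()
    report["cov_percent"] = cov
    report["mean_intensity"] = mean
    report["good"] = ~(fail_cov | fail_int | fail_sep)
    report["reasons"] = reasons
    return report


# ---------------------------------------------------------------------------
# Delta OD

def intensity_to_od(rec: RawRecording) -> ODTimeSeries:
    """Delta OD = -ln(I / mean(I)) per channel; exactly invertible."""
    bad = np.argwhere(rec.intensity <= 0)
    if len(bad):
        r, c = bad[0]
        raise ValueError(
            f"non-positive intensity at channel row {r}, sample {c} "
            f"({len(bad)} offending samples total)"
        )
    mean = rec.intensity.mean(axis=1)
    od = -np.log(rec.intensity / mean[:, None])
    return ODTimeSeries(
        od=od, fs=rec.fs, channels=rec.channels, mean_intensity=mean,
        participant=rec.participant,
    )


# ---------------------------------------------------------------------------
# motion detection

def _robust_std(x: np.ndarray) -> np.ndarray:
    med = np.median(x, axis=1, keepdims=True)
    return 1.4826 * np.median(np.abs(x - med), axis=1)


def detect_motion(
    od: ODTimeSeries,
    t_motion: float = 1.0,
    amp_thresh: float = 0.5,
    stdev_thresh: float = 15.0,
    t_mask: float = 1.0,
) -> np.ndarray:
    """Flag motion artifacts per channel (boolean channels x samples mask).

    Within every sliding window of length ``t_motion`` the peak-to-peak
    signal change is compared against ``amp_thresh`` and against
    ``stdev_thresh`` times the channel's robust (MAD-derived) standard
    deviation; when either is exceeded, all samples of the window plus
    ``t_mask`` seconds on each side are flagged.
    """
    w = int(round(t_motion * od.fs))
    if w < 2:
        raise ValueError("t_motion shorter than two samples at this rate")
    x = od.od
    # peak-to-peak over the trailing window ending at each sample
    hi = maximum_filter1d(x, size=w, axis=1, mode="nearest")
    lo = minimum_filter1d(x, size=w, axis=1, mode="nearest")
    ptp = hi - lo
    sd = _robust_std(x)
    thr = np.minimum(amp_thresh, stdev_thresh * sd)[:, None]
    hit = ptp > thr
    # a hit marks its whole (centred) window, then +- t_mask
    grow = w + 2 * int(round(t_mask * od.fs))
    return maximum_filter1d(hit, size=grow, axis=1, mode="constant") > 0


def find_clean_segment(
    mask: np.ndarray, fs: float, min_s: float = 20.0, bad_fraction: float = 0.2
) -> tuple[float, float] | None:
    """Longest artifact-free stretch, for clean-segment channel QC.

    A sample is globally bad when more than ``bad_fraction`` of channels
    flag it; returns the longest clean run as (start_s, end_s), or None if
    none reaches ``min_s``.  This automates the manual step of choosing a
    visually artifact-free segment for the coefficient of variation.
    """
    col_bad = np.asarray(mask, bool).mean(axis=0) > bad_fraction
    best = None
    run_start = None
    for i, bad in enumerate(np.append(col_bad, True)):
        if not bad and run_start is None:
            run_start = i
        elif bad and run_start is not None:
            if best is None or i - run_start > best[1] - best[0]:
                best = (run_start, i)
            run_start = None
    if best is None or (best[1] - best[0]) / fs < min_s:
        return None
    return best[0] / fs, best[1] / fs


# ---------------------------------------------------------------------------
# smoothing spline (Reinsch algorithm, natural boundary, banded solve)

def smoothing_spline(t: np.ndarray, y: np.ndarray, p: float) -> np.ndarray:
    """Natural cubic smoothing spline fitted values at the data sites.

    Minimises p * sum (y - f)^2 + (1 - p) * int f''^2, i.e. the classic
    csaps parameterisation; p = 1 interpolates.  ``y`` may be (n,) or
    (m, n) — all rows share the sites ``t`` and are solved together
    through one banded factorisation (Reinsch scheme).
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    t = np.asarray(t, float)
    Y = np.atleast_2d(np.asarray(y, float))
    n = len(t)
    if n < 3:
        return Y[0].copy() if np.ndim(y) == 1 else Y.copy()
    lam = (1.0 - p) / p
    h = np.diff(t)
    if np.any(h <= 0):
        raise ValueError("sites must be strictly increasing")
    # Q^T y: second divided differences
    inv_h = 1.0 / h
    d2 = Y[:, :-2] * inv_h[:-1] - Y[:, 1:-1] * (inv_h[:-1] + inv_h[1:]) + Y[:, 2:] * inv_h[1:]
    # R (tridiagonal, order n-2)
    r_diag = (h[:-1] + h[1:]) / 3.0
    r_off = h[1:-1] / 6.0
    # Q^T Q (pentadiagonal)
    q0 = inv_h[:-1]
    q1 = -(inv_h[:-1] + inv_h[1:])
    q2 = inv_h[1:]
    d_main = q0**2 + q1**2 + q2**2
    d_1 = q1[:-1] * q0[1:] + q2[:-1] * q1[1:]
    d_2 = q2[:-2] * q0[2:]
    m = n - 2
    ab = np.zeros((3, m))
    ab[2] = r_diag + lam * d_main
    if m > 1:
        ab[1, 1:] = r_off + lam * d_1
    if m > 2:
        ab[0, 2:] = lam * d_2
    gamma = solveh_banded(ab, d2.T, lower=False)  # (m, n_rhs)
    # f = y - lam * Q gamma
    Qg = np.zeros_like(Y)
    g = gamma.T  # (n_rhs, m)
    Qg[:, :-2] += g * q0
    Qg[:, 1:-1] += g * q1
    Qg[:, 2:] += g * q2
    f = Y - lam * Qg
    return f[0] if np.ndim(y) == 1 else f


# ---------------------------------------------------------------------------
# spline motion correction

def _runs(mask_row: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(mask_row.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask_row[0]:
        starts.insert(0, 0)
    if mask_row[-1]:
        ends.append(len(mask_row))
    return list(zip(starts, ends))


def correct_spline(od: ODTimeSeries, mask: np.ndarray, p: float = 0.99) -> ODTimeSeries:
    """Spline motion correction of flagged segments.

    Per flagged contiguous segment, a cubic smoothing spline (parameter
    ``p``) is fitted to the segment and subtracted; the residual segment
    is anchored to the data preceding the artifact, and all subsequent
    samples are level-shifted so the corrected series is continuous
    through the artifact (step artifacts are thereby removed — the
    differences between unflagged samples are preserved, their absolute
    level may move).  A segment at the recording start is anchored to the
    following data instead.  Segments sharing the same extent across
    channels are corrected in one banded solve.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != od.od.shape:
        raise ValueError("mask shape must match the OD matrix")
    x = od.od.copy()
    n = x.shape[1]
    groups: dict[tuple[int, int], list[int]] = {}
    for c in range(x.shape[0]):
        if not mask[c].any():
            continue
        for seg in _runs(mask[c]):
            groups.setdefault(seg, []).append(c)
    w = max(1, int(round(0.5 * od.fs)))  # anchoring window, ~0.5 s
    for (i0, i1) in sorted(groups):  # time order: later shifts see earlier ones
        chans = groups[(i0, i1)]
        t = np.arange(i0, i1) / od.fs
        seg = x[np.ix_(chans, range(i0, i1))]
        fit = smoothing_spline(t, seg, p)
        resid = seg - fit
        ws = min(w, i1 - i0)
        if i0 > 0:
            pre = x[np.ix_(chans, range(max(0, i0 - w), i0))].mean(axis=1)
            resid += (pre - resid[:, :ws].mean(axis=1))[:, None]
        elif i1 < n:
            post = x[np.ix_(chans, range(i1, min(n, i1 + w)))].mean(axis=1)
            resid += (post - resid[:, -ws:].mean(axis=1))[:, None]
        x[np.ix_(chans, range(i0, i1))] = resid
        if i0 > 0 and i1 < n:
            # shift everything after the artifact to meet the segment end
            post = x[np.ix_(chans, range(i1, min(n, i1 + w)))].mean(axis=1)
            delta = resid[:, -ws:].mean(axis=1) - post
            x[chans, i1:] += delta[:, None]
    return ODTimeSeries(
        od=x, fs=od.fs, channels=od.channels, mean_intensity=od.mean_intensity,
        participant=od.participant,
    )


# ---------------------------------------------------------------------------
# wavelet motion correction

def correct_wavelet(od: ODTimeSeries, a: float = 0.8, wavelet: str = "db2") -> ODTimeSeries:
    """Wavelet outlier suppression.

    Each channel is decomposed by a multilevel discrete wavelet transform;
    within each detail level, coefficients outside
    [Q1 - a*IQR, Q3 + a*IQR] (quartiles of that channel's level) are set
    to zero; the signal is then recomposed.  Haemodynamic content yields
    near-Gaussian, zero-centred coefficients and survives; isolated
    spikes and baseline steps concentrate in outlying coefficients.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    x = od.od
    n = x.shape[1]
    level = int(np.floor(np.log2(max(n, 2)))) - 4
    if level < 1:
        import warnings

        warnings.warn("signal too short for wavelet decomposition; passthrough")
        return od
    level = min(level, pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len))
    coeffs = pywt.wavedec(x, wavelet, level=level, axis=1)
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        q1, q3 = np.percentile(detail, [25, 75], axis=1)
        iqr = q3 - q1
        lo = (q1 - a * iqr)[:, None]
        hi = (q3 + a * iqr)[:, None]
        out.append(np.where((detail < lo) | (detail > hi), 0.0, detail))
    rec = pywt.waverec(out, wavelet, axis=1)[:, :n]
    return ODTimeSeries(
        od=rec, fs=od.fs, channels=od.channels, mean_intensity=od.mean_intensity,
        participant=od.participant,
    )


# ---------------------------------------------------------------------------
# trial validation and block averaging

def validate_trials(
    log: TrialLog, look_thresh: float = 0.60, min_trials: int = 3
) -> tuple[pd.DataFrame, bool]:
    """Looking-time validity and participant inclusion.

    An experimental trial is valid iff looking_fraction >= look_thresh and
    it did not follow an alerting sound; the participant is included iff
    every experimental condition retains at least ``min_trials`` valid
    trials.  Returns (trials with a ``valid`` column, included flag).
    """
    t = log.trials.copy()
    if len(t) == 0:
        raise ValueError("empty trial log")
    is_exp = t["condition"].isin(EXPERIMENTAL_CONDITIONS)
    alert = t.get("alert_flag", pd.Series(False, index=t.index)).fillna(False)
    t["valid"] = is_exp & (t["looking_fraction"] >= look_thresh) & ~alert.astype(bool)
    counts = t[t["valid"]].groupby("condition").size()
    included = all(counts.get(c, 0) >= min_trials for c in EXPERIMENTAL_CONDITIONS)
    return t, included


def block_average(
    od: ODTimeSeries,
    trials: pd.DataFrame,
    conditions=EXPERIMENTAL_CONDITIONS,
    pre: float = 2.0,
    post: float = 20.0,
    out_fs: float = 4.0,
) -> dict[str, BlockAverage]:
    """Epoch, baseline-correct and average Delta OD per condition.

    Each valid trial is resampled by linear interpolation onto the fixed
    grid -pre..post at ``out_fs`` (inclusive endpoints), the mean of its
    pre-stimulus interval (-pre..0 s) is subtracted, and epochs are
    averaged.  Trials extending beyond the recording are dropped with a
    warning.
    """
    grid = np.round(np.arange(-pre * out_fs, post * out_fs + 0.5) / out_fs, 10)
    times = od.times
    out: dict[str, BlockAverage] = {}
    for cond in conditions:
        sel = trials[(trials["condition"] == cond) & trials.get("valid", True)]
        epochs = []
        for _, tr in sel.iterrows():
            tt = tr["onset"] + grid
            if tt[0] < times[0] - 1e-9 or tt[-1] > times[-1] + 1e-9:
                import warnings

                warnings.warn(
                    f"trial at {tr['onset']:.1f}s exceeds recording bounds; dropped"
                )
                continue
            # shared-clock linear interpolation, vectorised across channels
            j = np.clip(np.searchsorted(times, tt) - 1, 0, len(times) - 2)
            w = (tt - times[j]) / (times[j + 1] - times[j])
            w = np.clip(w, 0.0, 1.0)
            ep = od.od[:, j] * (1.0 - w) + od.od[:, j + 1] * w
            base = ep[:, grid <= 0].mean(axis=1, keepdims=True)
            epochs.append(ep - base)
        data = (
            np.mean(epochs, axis=0)
            if epochs
            else np.zeros((od.od.shape[0], len(grid)))
        )
        out[cond] = BlockAverage(
            data=data, condition=cond, n_trials=len(epochs), channels=od.channels,
            grid=grid,
        )
    return out
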