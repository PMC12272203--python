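"""End-to-end orchestration: recordings -> group maps and seed analyses.

``run_pipeline`` executes the full chain on a synthetic cohort (or any
collection of recordings sharing a Jacobian):

    channel QC -> Delta OD -> motion detect/spline/wavelet ->
    trial validation -> block average -> coverage masking ->
    Tikhonov reconstruction + unmixing + surface mapping ->
    windowed group t-maps (Bonferroni) -> seed regions/time-courses

All stage parameters carry the study defaults and are echoed, together
with per-stage counts, into the returned manifest so every numeric output
is auditable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import preprocess as pp
from .forward import coverage_threshold, group_coverage, sensitivity_mask
from .mesh import nodal_volumes
from .reconstruct import CorticalImageSeries, TikhonovInverter, reconstruct_series
from .simulate import SyntheticCohort, detection_sensitivity
from .stats import WindowSpec, define_seed, one_sample_tmap, paired_tmap, seed_timecourse, window_values

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "preprocess_participant"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage parameter, defaulting to the study values."""

    cov_thresh_percent: float = 8.0
    intensity_thresh_v: float = 5e-5
    separation_thresh_mm: float = 60.0
    t_motion_s: float = 1.0
    t_mask_s: float = 1.0
    amp_thresh: float = 0.5
    stdev_thresh: float = 15.0
    spline_p: float = 0.99
    wavelet_a: float = 0.8
    look_thresh: float = 0.60
    min_trials: int = 3
    pre_s: float = 2.0
    post_s: float = 20.0
    out_fs: float = 4.0
    tikhonov_lambda: float = 0.01
    recon_sep_max_mm: float = 40.0
    surface_radius_mm: float = 3.0
    coverage_pthresh_percent: float = 1.0
    coverage_actvol_mm3: float = 1000.0
    coverage_dmua_fraction: float = 0.10
    group_fraction: float = 0.75
    window: WindowSpec = WindowSpec(11.0, 15.0)
    seed_radius_mm: float = 5.0
    alpha: float = 0.05


@dataclass
class ParticipantResult:
    participant: str
    qc: object
    included: bool
    trials: object
    blocks: dict
    images: dict  # condition -> CorticalImageSeries
    mask: object
    motion_mask_fraction: float
    artifact_sensitivity: float


@dataclass
class PipelineResult:
    participants: list
    include_mask: np.ndarray  # group >=75% coverage inclusion per cortical node
    coverage_count: np.ndarray
    tmaps: dict  # (condition, chromophore) -> StatMap
    paired: dict  # chromophore -> StatMap
    group_maps: dict  # (condition, chromophore) -> group-mean window map
    seeds: dict
    seed_tcs: dict
    manifest: dict


def preprocess_participant(
    recording, trial_log, cfg: PipelineConfig, truth=None
) -> tuple[dict, object, bool, object, float, float]:
    """QC through block average for one participant.

    The CoV criterion is evaluated on the longest artifact-free stretch
    found by a motion-detection pre-pass (automating the study's manual
    clean-segment choice); the whole recording is the fallback.
    """
    od = pp.intensity_to_od(recording)
    mask = pp.detect_motion(
        od, t_motion=cfg.t_motion_s, amp_thresh=cfg.amp_thresh,
        stdev_thresh=cfg.stdev_thresh, t_mask=cfg.t_mask_s,
    )
    clean = pp.find_clean_segment(mask, recording.fs)
    qc = pp.qc_channels(
        recording,
        clean_segment=clean,
        cov_thresh=cfg.cov_thresh_percent,
        intensity_thresh=cfg.intensity_thresh_v,
        separation_thresh=cfg.separation_thresh_mm,
    )
    good = qc["good"].to_numpy()
    sens = np.nan
    if truth is not None and truth.artifact_events is not None:
        sens = detection_sensitivity(
            mask[good], truth.artifact_events, recording.fs, t_mask=cfg.t_mask_s
        )
    # motion correction on retained channels only; excluded rows pass through
    sub = pp.ODTimeSeries(
        od=od.od[good], fs=od.fs, channels=od.channels[good],
        mean_intensity=od.mean_intensity[good], participant=od.participant,
    )
    sub = pp.correct_spline(sub, mask[good], p=cfg.spline_p)
    sub = pp.correct_wavelet(sub, a=cfg.wavelet_a)
    od.od[good] = sub.od
    trials, included = pp.validate_trials(
        trial_log, look_thresh=cfg.look_thresh, min_trials=cfg.min_trials
    )
    blocks = pp.block_average(
        od, trials, pre=cfg.pre_s, post=cfg.post_s, out_fs=cfg.out_fs
    )
    return qc, trials, included, blocks, float(mask.mean()), sens


def run_pipeline(
    cohort: SyntheticCohort, cfg: PipelineConfig = PipelineConfig()
) -> PipelineResult:
    """Run the whole analysis on a synthetic cohort; deterministic."""
    J = cohort.jacobian
    smap = cohort.surface_map
    mean_v = float(nodal_volumes(cohort.mesh).mean())
    mua_gm_850 = cohort.props.mua["GM"][850.0]
    thr = coverage_threshold(
        mean_v,
        delta_mua=cfg.coverage_dmua_fraction * mua_gm_850,
        pthresh=cfg.coverage_pthresh_percent,
        actvol=cfg.coverage_actvol_mm3,
    )
    participants = []
    masks = []
    for part in cohort.participants:
        recording = cohort.make_recording(part)
        qc, trials, included, blocks, mask_frac, art_sens = preprocess_participant(
            recording, part.trial_log, cfg, truth=part.truth
        )
        del recording
        good = qc["good"].to_numpy()
        recon_rows = good & (J.separation <= cfg.recon_sep_max_mm)
        mask = sensitivity_mask(
            J.select(np.flatnonzero(recon_rows)), thr, smap, participant=part.participant
        )
        images = {}
        if included:
            inverters = {
                float(wl): TikhonovInverter(
                    J.data[recon_rows & np.isclose(J.wavelength, wl)],
                    lam=cfg.tikhonov_lambda,
                )
                for wl in np.unique(J.wavelength)
            }
            for cond, block in blocks.items():
                im = reconstruct_series(
                    block, J, cohort.ext, smap, good=good,
                    sep_max=cfg.recon_sep_max_mm, lam=cfg.tikhonov_lambda,
                    coverage=mask.covered, inverters=inverters,
                )
                im.participant = part.participant
                images[cond] = im
        participants.append(
            ParticipantResult(
                participant=part.participant, qc=qc, included=included,
                trials=trials, blocks=blocks, images=images, mask=mask,
                motion_mask_fraction=mask_frac, artifact_sensitivity=art_sens,
            )
        )
        if included:
            masks.append(mask)
    if not masks:
        raise RuntimeError("no participant passed trial validation")
    count, include = group_coverage(masks, fraction=cfg.group_fraction)

    conditions = sorted({c for p in participants if p.included for c in p.images})
    tmaps, group_maps, paired = {}, {}, {}
    windowed = {}
    for cond in conditions:
        images = [p.images[cond] for p in participants if p.included]
        for chrom in ("hbo", "hbr"):
            vecs = window_values(images, cfg.window, chromophore=chrom)
            windowed[(cond, chrom)] = vecs
            tmaps[(cond, chrom)] = one_sample_tmap(
                vecs, include, alpha=cfg.alpha, label=f"{cond}/{chrom}"
            )
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                group_maps[(cond, chrom)] = np.where(
                    include, np.nanmean(vecs, axis=1), np.nan
                )
    if len(conditions) == 2:
        a, b = conditions
        for chrom in ("hbo", "hbr"):
            paired[chrom] = paired_tmap(
                windowed[(b, chrom)], windowed[(a, chrom)], include,
                alpha=cfg.alpha, label=f"{b}-{a}/{chrom}",
            )

    seeds, seed_tcs = {}, {}
    for cond in conditions:
        images = [p.images[cond] for p in participants if p.included]
        gm = group_maps[(cond, "hbo")]
        if np.isfinite(gm).any():
            seed = define_seed(
                gm, include, cohort.cortex.vertices, radius=cfg.seed_radius_mm,
                polarity="peak-positive", label=f"{cond} peak",
            )
            seeds[cond] = seed
            seed_tcs[cond] = {
                chrom: seed_timecourse(images, seed, chromophore=chrom)
                for chrom in ("hbo", "hbr")
            }

    manifest = {
        "config": asdict(cfg),
        "coverage_threshold": thr,
        "mean_nodal_volume_mm3": mean_v,
        "n_participants": len(participants),
        "n_included": int(sum(p.included for p in participants)),
        "n_cortical_nodes": int(len(include)),
        "n_tested_nodes": int(include.sum()),
        "bonferroni_alpha": cfg.alpha / max(int(include.sum()), 1),
        "good_channels_per_participant": [
            int(p.qc["good"].sum() // 2) for p in participants
        ],
        "grid_samples": len(pp.BLOCK_GRID),
    }
    return PipelineResult(
        participants=participants, include_mask=include, coverage_count=count,
        tmaps=tmaps, paired=paired, group_maps=group_maps, seeds=seeds,
        seed_tcs=seed_tcs, manifest=manifest,
    )
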