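# hddot — whole-head infant high-density diffuse optical tomography

`hddot` is an end-to-end analysis pipeline for whole-head HD-DOT in
infants: it takes multichannel dual-wavelength (735/850 nm) optical
intensity recordings from a 33-tile scalp cap and produces cortical maps
of oxy-/deoxy-haemoglobin concentration change (ΔHbO, ΔHbR) with
group-level statistics. Because real infant recordings cannot be shared,
the package includes a first-class synthetic-data generator that emulates
the array geometry, the social/non-social stimulus paradigm, physiological
noise and motion artifacts with known ground truth, so every stage of the
pipeline is verifiable.

## Who this is for

Researchers analysing (or planning) dense optical neuroimaging of the
infant brain: fNIRS/DOT methodologists who need a transparent, tested
reference for the full chain from raw intensities to statistical maps, and
simulation users who want a controllable phantom study with recoverable
truth.

## The pipeline

1. **Array model** — 33 hexagonal tiles, each with 3 dual-wavelength
   sources and 4 detectors at 10/20 mm intra-tile separations; fully
   populated: 99 sources × 132 detectors = 13,068 dual-wavelength
   channels.
2. **Head model** — a four-tissue (scalp/skull "ECT", CSF, grey, white)
   tetrahedral mesh with cranial landmarks (Nz, Iz, Ar, Al, Cz), oriented
   into a canonical frame and scaled iteratively until circumference and
   the two landmark arcs match the participant's scalp measurements within
   5 mm.
3. **Optode registration** — landmark affine, pitch/yaw correction from
   the cap's midline-dot offset, and snapping to the scalp surface.
4. **Forward model** — continuous-wave photon diffusion
   `-∇·(κ∇Φ) + μa Φ = q`, `κ = 1/(3(μa+μs'))`, P1 finite elements with a
   Robin boundary; the channel×node sensitivity (Jacobian) is the exact
   discrete adjoint, `J[c,n] = ∂(ΔOD_c)/∂μa_n`.
5. **Preprocessing** — good channels require CoV < 8 %, mean intensity
   > 5·10⁻⁵ V, separation < 60 mm; ΔOD = −ln(I/mean I); motion detection
   (tMotion = tMask = 1 s, AMPthresh = 0.5, STDEVthresh = 15); cubic
   smoothing-spline correction (p = 0.99) then wavelet outlier suppression
   (a = 0.8 IQR); trials valid at ≥ 60 % looking time, participants kept
   with ≥ 3 valid trials per condition; block average on the fixed
   −2…20 s, 4 Hz grid (89 samples).
6. **Reconstruction** — zeroth-order Tikhonov
   `x = Jᵀ(JJᵀ + λσI)⁻¹ y` with λ = 0.01 (relative to σ = max diag JJᵀ),
   channels ≤ 40 mm; node-wise spectral unmixing through the 2×2
   extinction matrix; surface mapping by a 3 mm-radius mean around each
   cortical node.
7. **Coverage & statistics** — a node is covered when a 10 % μa change in
   1 cm³ would change measured intensity by > 1 %; group maps keep nodes
   covered in ≥ 75 % of participants; windowed (11–15 s) one-sample and
   paired t-maps with Bonferroni correction over tested nodes; 5 mm seed
   regions and mean ± SEM time-courses.

## Worked example

```python
from hddot.simulate import SimulationConfig, simulate_cohort, recovery_report
from hddot.pipeline import run_pipeline

cohort = simulate_cohort(SimulationConfig(seed=1, n_participants=16))
result = run_pipeline(cohort)

m = result.manifest
print(m["n_included"], "of", m["n_participants"], "participants included")
print(m["n_tested_nodes"], "of", m["n_cortical_nodes"], "cortical nodes tested")

rep = recovery_report(cohort, result.group_maps[("social", "hbo")],
                      result.seed_tcs["social"]["hbo"], condition="social",
                      include=result.include_mask)
print("localisation error: %.1f mm" % rep["localisation_error_mm"])
print("seed peak time: %.2f s" % rep["seed_peak_time_s"])
```

Output (seed 1; several minutes on one CPU):

```
16 of 16 participants included
1228 of 1380 cortical nodes tested
localisation error: 6.5 mm
seed peak time: 13.50 s
```

The QC stage retains a median of ~2,554 good dual-wavelength channels per
synthetic participant; group analysis keeps the cortical nodes covered in
at least 75 % of participants; the strongest simulated focus (right
temporal, social-preferring) is recovered at the group-map peak 6.5 mm
from its true centre, and the group seed time-course peaks at 13.5 s,
inside the 11–15 s response window, where the generative response kernel
peaks at 12 s. The sensorimotor focus simulated with negative ΔHbO and
positive ΔHbR comes back with the same inverted signature.

The numbered scripts under `analysis/` run the same stages as standalone
drivers (array combinatorics, head-model scaling, channel quality, full
group analysis) and write their tables to `results/`.

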