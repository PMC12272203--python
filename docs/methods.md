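# Methods

This note records the models, parameter choices and numerical decisions
behind `hddot`, and what the synthetic-data tests do and do not establish
about behaviour on real recordings.

## Array and cap geometry

A tile carries three dual-wavelength LED sources (735/850 nm) and four
photodiode detectors. The exact manufactured layout is proprietary; the
packaged tile places sources at 10 mm radius (azimuths 0/120/240°) and
detectors at the centre plus 10 mm radius (60/180/300°), which reproduces
the two nominal intra-tile source–detector distances exactly: every pair
is at 10 mm (centre and the two adjacent ring detectors) or 20 mm (the
opposite one). Both the tile and the 33-dock cap layout are data files
(`hddot/data/*.yaml`, mm units) so a vendor digitisation can be dropped
in.

Dock poses are spread over a reference scalp sphere (radius 71.6 mm, a
45 cm circumference phantom head) by a Fibonacci spiral above 5°
elevation, giving ~30 mm inter-tile spacing and a continuum of
between-tile separations upward of ~10 mm. This is a template
approximation of the real cap, adequate for testing every pipeline stage;
it does not reproduce the manufactured dock coordinates, so quantities
that depend on them (for example the exact reduced channel list of the
faster acquisition mode) are out of reach.

A *dual-wavelength channel* is one (source position, detector) pair — the
two wavelengths share the channel record — so the full array yields
99 × 132 = 13,068 channels and twice that many per-wavelength
measurements. Separation histograms use half-open 5 mm bins offset so bin
centres land on the label ("30 mm" spans 27.5–32.5 mm).

## Head model, orientation, scaling

The head model is a tetrahedral mesh with per-element tissue labels (ECT,
CSF, GM, WM) and the five cranial landmarks on the scalp. The canonical
pose puts the inion at the origin, the nasion on +y, rotates about y until
the pre-auricular points share a z coordinate, and keeps the vertex on +z
(the last condition resolves the two-fold ambiguity of the equal-z
constraint and makes orientation a true canonicalisation — random rigid
motions land on the same pose).

Scalp measurements are emulated as: circumference = convex-hull perimeter
of the scalp cross-section at the mean axial level of nasion and inion
(the hull approximates a taut tape and is robust to surface dimples);
landmark arcs = shortest path through the vertex on the scalp triangle
graph (Dijkstra with exact edge lengths). Graph shortest paths
overestimate true geodesics by the mesh stretch factor — about 9 % at the
default phantom resolution — which is acceptable because the scaling loop
drives the *measured* (graph) value to the target, and homogeneity under
scaling is exact. Whether the original tape measurements behave like
geodesics or chord-hugging paths is unknowable from the data; geodesics
were chosen.

Participant scaling starts with an isotropic scale by the circumference
ratio, then iterates: the measurement with the greatest absolute
discrepancy drives a rescale of its coordinate pair (Nz-Cz-Iz → y,z;
Ar-Cz-Al → x,z; circumference → x,y — the axial plane determines the
perimeter, the natural completion of the stated pattern) by the factor
target/current, until all three residuals are ≤ 5 mm (max 50 iterations;
ties broken in the fixed order circumference, Nz-Cz-Iz, Ar-Cz-Al). The
factor direction is the one that *reduces* the discrepancy, consistent
with the initial isotropic step. Topology and tissue labels are never
touched.

## Optode registration

Template tile centres are mapped by a least-squares affine between
template and participant landmark sets (≥ 4 non-coplanar pairs required).
The cap's anterior midline dot supplies a participant-specific
correction: pitch (about x) and yaw (about z) equal the elevation and
azimuth differences of the template and measured dot directions about the
pivot. One 3-D offset cannot fix three rotational degrees of freedom; the
roll residual is neither observable nor corrected. The pivot of these
rotations is not observable either; the scalp-surface centroid is used
and is configurable. When no dot measurement exists, the template
placement is used unchanged and the result flagged `template-fallback`.

Tile centres snap to the nearest scalp node; sources and detectors are
laid out at tile-local offsets in the tangent plane (vertex normal from
area-weighted incident faces; local x from the transported dock
orientation re-orthogonalised) and then projected to the closest point on
the scalp surface. On the default phantom the 10/20 mm intra-tile
distances survive registration within ~1 mm (tangent-plane chord error on
a 70 mm sphere is ≪ 1 mm; the residual comes from surface projection).

## Forward model

Continuous-wave diffusion approximation, P1 Lagrange tetrahedral elements:
`-∇·(κ∇Φ) + μa Φ = q` with `κ = 1/(3(μa + μs'))` per element and a Robin
boundary `κ ∂Φ/∂n + Φ/(2A) = 0` on the mesh boundary, `A` from the
standard polynomial fit in the refractive index (n = 1.4 → A ≈ 2.95).
The absorption term is assembled from the P1-interpolated *nodal* μa
field (element tissue values volume-averaged onto nodes). Sources and
detector adjoints are point loads one transport mean free path
`1/(μa+μs')` below the scalp along the inward normal, distributed
barycentrically in the enclosing tetrahedron; identical construction for
both makes source–detector reciprocity exact. The system is factorised
once (sparse LU) per mesh/wavelength and reused for all optodes.

The Jacobian is the exact derivative of this discrete system with respect
to nodal μa: rows expand `Φ_detᵀ (∂K/∂μa_n) Φ_src / I` with the
consistent P1 moment tensor `∫φn φi φj = V/120 × coincidence factor`,
evaluated in closed form and accumulated through a node–element incidence
matrix (so whole-cap Jacobians take seconds, and brute-force finite
differences agree to rounding rather than to discretisation error).
Entries are `∂ΔOD/∂μa_n` in mm (volume-weighted sensitivity) and are
nonnegative up to discrete undershoot, provided the optical decay length
is resolved (see *Numerical scales* below).

CSF is handled with a reduced-scattering floor of 0.3 mm⁻¹: the diffusion
approximation is invalid in truly low-scattering CSF, and the floor keeps
the operator well-posed at the cost of underestimating CSF light piping —
a documented limitation shared by diffusion-based DOT generally.

Coverage: a cortical node counts as covered when any retained channel's
sensitivity there exceeds `ln((100+pthresh)/100) / (Δμa · actvol / V)`
with pthresh = 1 %, actvol = 1000 mm³, Δμa = 10 % of grey-matter μa at
the evaluated wavelength, and V the mean nodal (barycentric-lumped)
volume — i.e. a 10 % absorption change in 1 cm³ must move measured
intensity by more than 1 %. Sensitivity is first mapped to the cortical
surface by the same 3 mm-radius mean used for images, and the two
wavelengths are combined by OR (the permissive choice; which single
wavelength the original analysis thresholded is not recoverable). Group
analyses keep nodes covered in at least 75 % of participants, boundary
inclusive (12 of 16 participants is exactly 75 % and is kept).

## Preprocessing

Stage order is fixed: QC → ΔOD → motion detection → spline → wavelet →
trial validation → block average.

* QC (per measurement row): CoV = std/mean of raw intensity < 8 %, mean
  intensity > 5·10⁻⁵ V, separation < 60 mm. CoV is computed on the
  longest artifact-free stretch found by a motion-detection pre-pass
  (automating the manual choice of a visually clean segment); the whole
  recording is the fallback.
* ΔOD = −ln(I/mean I), exactly invertible given the stored mean.
* Motion detection: within each sliding window of length tMotion = 1 s
  the peak-to-peak ΔOD is compared against AMPthresh = 0.5 and against
  STDEVthresh = 15 × a robust (MAD-derived) channel std — the robust
  scale keeps the threshold meaningful on channels that already contain
  artifacts; windows that trip either limit are flagged and grown by
  tMask = 1 s each side.
* Spline correction: per flagged segment, a natural cubic smoothing
  spline (csaps parameterisation, p = 0.99, λ = (1−p)/p) is fitted and
  subtracted; the residual segment is level-shifted to join the clean
  data on both sides (one-sided at recording edges). Unflagged samples
  are never modified. The Reinsch banded-solve implementation handles all
  channels sharing a segment in one factorisation; it matches
  `scipy.interpolate.make_smoothing_spline` to 10⁻¹³ on single series.
* Wavelet correction: multilevel DWT (Daubechies-2, level =
  ⌊log₂N⌋ − 4), per level and channel zeroing coefficients outside
  [Q1 − 0.8·IQR, Q3 + 0.8·IQR], inverse transform. For Gaussian input
  this zeroes ≈ 7.9 % of coefficients (the normal mass outside the
  fence), the price paid for spike robustness.
* Trials: an experimental trial is valid at looking fraction ≥ 0.60 and
  no preceding alerting sound; participants need ≥ 3 valid trials per
  experimental condition.
* Block average: per epoch, linear interpolation onto the fixed grid
  −2…20 s at 4 Hz (89 samples, endpoints included, 0.25 s step), baseline
  correction by the −2…0 s mean, then the epoch mean. Per-epoch baseline
  subtraction and post-hoc baseline referencing are equivalent for the
  averaged images; per-epoch was chosen. Acquisition rates are treated as
  the exact rationals 25/6 and 25/3 Hz.

## Reconstruction and statistics

Per wavelength, good channels at ≤ 40 mm separation are inverted with
`x = Jᵀ(JJᵀ + λσI)⁻¹y`, λ = 0.01 and σ = max diag(JJᵀ) — the
hyperparameter is *relative* to the sensitivity scale, the common DOT
convention (an absolute-λ mode exists; whether the original 0.01 was
relative or absolute is not recoverable, and the choice is echoed in
output metadata). The Cholesky factor is cached and shared across
participants, conditions and time points. Per-node 2×2 spectral unmixing
converts the two wavelength images to ΔHbO/ΔHbR (µM); the bundled
extinction coefficients are a standard compiled in-vitro haemoglobin
spectrum, recorded with a citation string and treated as configuration.
Surface mapping averages all volume nodes within 3 mm of each cortical
node (all tissues; a GM-only mode exists).

Statistics follow the block-average convention: concentration changes of
all grid samples in the 11–15 s post-stimulus window (17 samples at 4 Hz)
are concatenated across participants into one vector per node
(16 participants → 272 values at fully covered nodes), tested with a
one-sample t-test against zero, Bonferroni-corrected over the tested
(≥ 75 %-covered) nodes; condition contrasts use the paired test on
aligned vectors. Concatenating time samples inflates the nominal degrees
of freedom (reported honestly as vector length − 1); a participant-mean
mode (one value per participant) is available behind a flag for users who
prefer exchangeable units. Zero-variance nodes are excluded from
significance rather than assigned infinite t. Seed regions take the peak
(or peak-negative, for the inverted sensorimotor response) node of the
group window map within a region mask plus all cortical nodes within
5 mm; time-courses are participant means over the seed, summarised as
group mean ± SEM.

## Synthetic cohort: what it emulates

Defaults reproduce the study conditions: 16 participants, the full
33-tile cap, up to 9 trials per experimental condition of 9–12 s
interleaved with 12–14.5 s baselines (≈ 7 min paradigm), 25/3 Hz sampling
with channels recorded to 60 mm, looking fractions Beta(8, 1.5) (median
≈ 0.87, so most trials pass the 60 % rule), 3 % of trials alerted.

* **Response model.** Each focus is a spatial Gaussian (default FWHM
  26 mm — group activations in this paradigm span large portions of a
  lobe, not punctate spots) on the cortex times an onset-locked
  difference-of-gammas kernel.
  The kernel's `peak_time` (default 12 s) is the time of its maximum —
  normalisation and a small time-warp make this exact — so the
  ground-truth peak is directly the configured parameter. An onset-locked
  block-response kernel was chosen over convolving an impulse response
  with the stimulus boxcar: it makes the truth's timing controllable and
  testable, at the cost of ignoring duration-dependent response scaling
  within the 9–12 s range.
* **Default foci** (geometrically picked on the phantom cortex):
  bilateral temporal (right stronger, social-preferring), medial
  occipital (non-social-preferring), and a sensorimotor focus with
  negative ΔHbO/positive ΔHbR during experimental trials — the
  "inverted response" motif. Peak amplitudes are a few µM (3.0/2.4/1.8/
  −1.5 µM ΔHbO, ΔHbR = −0.35×), consistent with the clearly significant
  group activations infant block paradigms evoke; per-participant
  lognormal gain jitter (σ = 0.2) provides between-subject variability.
* **Noise model.** Baseline intensity I₀ = 0.05 V × 10^(−0.055·sep/mm)
  with lognormal channel scatter (σ = 0.45) — five decades of log-linear
  decay across the separation range, so short channels are bright and
  channels beyond ~45 mm sink under the QC intensity floor, reproducing
  the observed good-channel structure. White noise scales as
  √(I_ref/I₀) (shot-noise-like); physiological sines at 2.2 Hz (cardiac,
  aliased at the lower acquisition rate by construction), 0.6 Hz
  (respiratory) and 0.1 Hz (vasomotor, the dominant nuisance at 0.015 OD)
  share phases across channels with per-channel amplitude jitter. Spikes
  (3/min, 0.6–1.5 OD, 0.35 s exponential) and persistent baseline shifts
  (0.15/min — a cap that physically moves and stays moved is a rare
  event) arrive as array-wide events with modest per-channel gain spread
  (σ = 0.15; mechanical cap events couple similarly across the array).
* **Motion–gaze coupling.** Looking fractions are conditioned on the
  motion load of each experimental trial (a shift or ≥ 2 spikes draws
  from a low Beta, one spike from an intermediate one): infants who move
  are infants who have disengaged from the screen, so the 60 %
  looking-time rule removes the most artifact-contaminated epochs —
  exactly the role gaze coding plays in the real analyses. Valid-trial
  counts land in the reported range (median ≈ 7–8 of 9, minimum-trials
  participants occur).
* **Determinism.** Every draw descends from one seed; cohorts regenerate
  bit-identically, and recordings are synthesised lazily from stored
  per-participant seeds so a 16-participant cohort fits in memory.

What passing the synthetic tests does *not* show: performance under real
optode-scalp coupling variation (hair), real head-shape variability
(participants share the phantom anatomy and hence the Jacobian), true CSF
light transport, model mismatch between the reconstruction Jacobian and
the physics that generated the data (both use the same FEM — recovery
tests validate the inverse pipeline, not forward-model fidelity to
tissue), or gaze-coding noise.

## Numerical scales

The desk-scale phantom mesh (hemisphere radius 70 mm, ~6 mm spacing,
≈ 5,000 nodes) resolves the photon decay length only if μeff·h ≲ 0.7;
the simulation optical properties therefore use reduced scattering
(μs' ≈ 0.4 mm⁻¹, μa ≈ 0.01 mm⁻¹ → attenuation length ≈ 10 mm) relative
to literature infant-head values. They are simulation conditions, not
physiological claims; the separate `default_optical_properties()` table
carries literature-typical values for use with adequately fine meshes.
P1 FEM with under-resolved decay oscillates negative and corrupts
sensitivities — the resolvability condition is asserted in tests rather
than hidden.

Green's-function validation uses an octant slab with natural (Neumann)
symmetry planes and the source at the corner — equivalent to an interior
point source in a medium of 8× the volume — which buys a ~1.2 mm mesh
within a ≤ 20k-node budget; agreement with `exp(−μeff r)/(4πκr)` is
within 5 % pointwise for r = 7–13 mm, ≥ 14 mm from the Robin walls.

The cortical surface-mapping radius is resolution-dependent in effect:
3 mm on a millimetre-scale anatomical mesh averages tens of volume nodes,
but on the 6 mm phantom mesh it holds only one or two, degenerating to
nearest-node sampling whose reconstruction noise is several-fold higher
at isolated nodes. The synthetic cohort therefore maps with an 8 mm
radius (`SimulationConfig.surface_radius`), preserving the averaging
operator at the coarser scale; the pipeline default for real
millimetre-scale meshes remains 3 mm.

Other numerical choices: tets from Delaunay of jittered concentric
half-shells (hemisphere) or a Kuhn subdivision (slab, deterministic and
inversion-symmetric); inverted elements rejected everywhere; degenerate
smoothing-spline segments shorter than 3 samples pass through unchanged;
the group-coverage comparison `count/N ≥ 0.75` is evaluated with a 10⁻¹²
guard so the 12/16 boundary is robust to float division.

## Known limitations

* The cap layout is a geometric template, not the manufactured cap; the
  5,544-channel reduced acquisition mode cannot be reproduced.
* Shared-anatomy cohorts cannot probe registration-driven variance in
  group maps (per-participant meshes are supported by the API; the
  default generator does not exercise them).
* The spline stage removes sub-0.5 Hz structure inside flagged segments,
  haemodynamics included — with ~20–35 % of samples flagged at default
  artifact rates this costs a few percent of block-average amplitude;
  inherent to the method, and the recovery tests run through it. Step
  artifacts below the per-channel detection threshold remain uncorrected,
  as in any threshold-based motion pipeline.
* Degrees of freedom in the concatenated t-maps are nominal; temporal
  autocorrelation within the window makes them optimistic. The Bonferroni
  correction over nodes is, conversely, conservative.
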