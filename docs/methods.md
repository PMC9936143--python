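# Methods

This note documents the models, conventions, defaults and numerical
choices behind `dynloc`, and what its synthetic-data tests do and do not
demonstrate about real data.

## Coordinate conventions

Directions live in a right-handed head-fixed frame (x front, y left,
z up). Spherical coordinates use azimuth ∈ [−180°, 180°), positive toward
the listener's left, and elevation ∈ [−90°, 90°], positive up. The
interaural-polar system used by all metrics has
lateral = arcsin(y) ∈ [−90°, 90°] and polar = atan2(z, x) ∈ [−90°, 270°),
with 0° front, 90° overhead, 180° rear; all directions sharing one lateral
angle form one cone of confusion. Neither sign convention is observable in
any metric (precision errors and confusion rates are invariant under
left-right relabeling); the left-positive choice follows the dominant
convention in the sagittal-coordinate literature. Head orientations
compose yaw → pitch → roll about body axes; roll is carried through but
set to zero by every generator, since the task only instructs yaw and
pitch rotations. Great-circle angles are computed as atan2(‖v₁×v₂‖, v₁·v₂)
rather than arccos(v₁·v₂), which cannot resolve angles below ~10⁻⁶ degrees
in double precision.

## Source grid and sessions

The experiment's 41 source directions are not tabulated anywhere as
coordinates, only constrained: 41 unique directions, 11 on the median
plane (tested twice, giving the 52-entry test list), elevations within
the loudspeaker array's −47°…90° coverage, sampling densest around the
median plane and high elevations, and symmetric lateral-angle pairs. The
default layout satisfies every constraint — median-plane polar angles
{−30, 0, 30, 60, 75, 90, 105, 120, 150, 180, 210}° plus five polar samples
{−30, 0, 45, 90, 135}° on each of the ±20°, ±40°, ±60° sagittal planes —
and is a parameterized constructor, since any layout meeting the
constraints exercises the pipeline identically. Session plans draw every
permutation (block order per subject, trial order per block) from one
session seed through numpy's splittable `SeedSequence`, so plans are
bit-reproducible.

## HRTF processing chain

**Minimum phase.** A length-N impulse response's minimum-phase counterpart
is again length N: the z-plane zeros outside the unit circle are reflected
to their conjugate reciprocals. `minimum_phase` computes the zeros via the
companion matrix, but reconstructs the spectrum from the *original* FFT
magnitude (preserved bin-for-bin by construction, errors ~10⁻¹² dB) with
the minimum-phase phase accumulated stably in the log domain; naive
coefficient reconstruction from reflected roots loses up to tens of dB for
random inputs. The cyclic cepstral construction
(`minimum_phase_from_logmag`) is used where only a magnitude spectrum
exists (interpolated or synthesized spectra, which are smooth and hence
safe from cepstral aliasing) and as the fast zero-delay reference inside
`estimate_toa`.

**Delays.** TOAs are inserted as cyclic band-limited phase ramps
e^(−jωD) on the N-point FFT grid, with the Nyquist coefficient forced to
±1. This operator is exactly allpass — a requirement propagated from the
cue-manipulation contracts (flattening with C = 1 and freezing at the
reference direction must reproduce magnitudes to ≤ 10⁻⁹ dB) that a
windowed-sinc FIR delay cannot meet — and is smooth in D, so the dynamic
ITD varies continuously with direction. The cost is circular wrap-around:
impulse-response buffers must be longer than the largest delay plus the
minimum-phase decay (the default 256 samples at 48 kHz leaves ≥160 samples
of decay after the ≤32-sample maximal TOA).

**TOA model.** The rigid-sphere model uses radius 8.75 cm and c = 343 m/s
with ears at azimuth ±90°: τ(γ) = (r/c)(1 − cos γ) on the ear's side and
(r/c)(1 + γ_rad − π/2) in the shadow zone, continuous at γ = 90°, giving a
maximal ITD of (r/c)(1 + π/2) ≈ 0.656 ms.

**Interpolation.** The sparse grid is triangulated as the convex hull of
its unit vectors and subdivided (edge midpoints projected to the sphere,
deduplicated across faces: V → V + E, F → 4F per iteration; an icosahedron
runs 12 → 42 → 162 → 642 → 2562, the 91-direction synthetic grid reaches
5,698 directions after three iterations). Per dense direction, VBAP
solves L·g = p over the enclosing sparse triangle; gains are normalized to
unit Euclidean norm for panning, and to unit *sum* when used as
interpolation weights so that a dense direction coinciding with a sparse
one reproduces it exactly. Magnitudes are blended in the log domain
(spectral cues are level ratios; dB blending avoids comb artifacts of
linear-amplitude mixing of misaligned notches); whether the original
processing blended in dB or linear amplitude is unstated, and the choice
is confined to one function.

**Flattening.** Within the 1–16 kHz band the log-magnitude m is replaced
by p + C·(m − p). The pivot p is the ear's in-band *power* mean expressed
in the log domain, not the mean of the dB values: this makes C = 0
flattening exactly energy-neutral per ear, so the broadband ILD survives
(a dB-mean pivot loses up to ~2 dB on spectra with 20-dB notches). C = 1
is the identity. Phase is rebuilt as minimum phase and the set's stored
TOA re-applied, leaving ITD and dynamic ITD untouched.

**Freezing.** Every direction receives the reference direction's per-ear
magnitude (hence its MSS and ILD) while keeping its own TOA. In the
renderer the reference is chosen per trial as the head-relative source
direction at stimulus onset, so cues are veridical until the head moves.

## Rendering

Stimuli are white-noise bursts band-limited by FFT masking to
20 Hz–20 kHz (clipped to Nyquist) with 5-ms raised-cosine ramps. Dynamic
rendering uses weighted overlap-add: triangular windows, 5-ms hop, 50%
overlap (shifted windows sum exactly to one, so a static trajectory
reduces to plain convolution to machine precision). Per block the
head-relative source direction — with the tracker latency applied to the
orientation lookup — selects the nearest dense-grid HRTF; the 5-ms block
is shorter than the ~6-ms tracking latency such systems report, and
nearest-neighbor selection on a dense grid keeps per-block direction jumps
below the grid spacing. Gating measures rotation about the instructed axis
only (matching the analysis-stage QC definition), finds the first
threshold crossing by linear interpolation between tracker samples
(inclusive at exact samples), and applies a 5-ms cosine ramp to the
*output*, so post-gate energy is identically zero. Free-field playback is
represented by its VBAP loudspeaker gain stage only; no room or
transducer acoustics are modeled.

## Synthetic listeners

**HRTFs.** The parametric listener combines (i) a spectral notch whose
center frequency moves linearly from 6 to 12 kHz as the polar angle goes
from −45° to +90° (rear angles mirrored onto the front, a stylized pinna
cue), 20 dB deep with 1.5 kHz Gaussian width; (ii) a frequency-dependent
head-shadow shelf, ±6 dB × sin(lateral) at Nyquist with √f scaling (ILD
cue); (iii) a small shoulder shelf and a seeded smooth ripple (~1 dB) for
listener idiosyncrasy; and (iv) spherical-head TOAs. The default grid has
91 directions on rings from −47° to +90° elevation, emulating a
full-sphere loudspeaker array truncated below −47°.

**Trajectories.** An instructed rotation is a reaction delay (normal,
150 ± 30 ms, truncated at 50 ms — the observed population range is
100–200 ms) followed by a raised-cosine velocity profile with 20°
excursion. Peak velocities are drawn log-normally with mean ± SD
36.41 ± 23.03°/s (yaw) and 28.54 ± 17.50°/s (pitch) — the published
population values; the log-normal parameterization preserves those means
exactly where a truncated normal would bias them upward. Orthogonal-axis
jitter is Gaussian with 0.5° SD per 90-Hz tracker sample, which makes the
2° off-axis QC rule bite on ~1% of trials, as a realistic screening rate.

**Responses.** Lateral response = target + N(0, σ_lat) (reflected at the
±90° poles); polar response = target + N(0, σ_pol) wrapped to [−90°, 270°);
with probability p_fbc the polar response is mirrored across the frontal
plane (polar → 180° − polar), i.e. a front-back confusion on the same cone
of confusion — this factorization makes FBC and PPE separable exactly as
the analysis assumes. Between-subject effects multiply the σs log-normally
(log-SD 0.15) and shift the confusion log-odds (SD 0.4). Per-cell defaults
encode the study conditions: static free-field performance at the
published aggregate values (σ_lat 9.3°, σ_pol 20.4°, p_fbc 0.154), static
virtual audio slightly worse (12.0°, 25.7°, 0.151), a spectrally flat
condition with large polar scatter and p_fbc 0.40 dropping to 0.15 under
yaw rotations, no confusion benefit from pitch rotations, and essentially
rotation-independent precision. Cell-level scatter beyond the printed
aggregates is not published; these defaults are declared assumptions.

**What the simulator does not emulate.** Response biases (accuracy errors,
as opposed to precision), direction-dependent scatter within a cell,
learning across blocks, cue-weighting mechanisms (responses are drawn from
the cell parameters, not decoded from rendered audio), and any coupling
between rotation kinematics and response quality beyond the QC gate.
Passing tests therefore demonstrate that the *pipeline* — design through
inference — is correct and well calibrated, not that real listeners behave
like the generator.

## Analysis and inference

QC keeps dynamic trials with ≥5° on-axis and ≤2° off-axis rotation (both
boundaries inclusive) and static trials with ≤2° total movement (the
static threshold is not a printed value; it is configurable and recorded
in the QC report). The confusion classifier ignores targets with
|lateral| > 60°; "midline" in the crossing rule is read as the frontal
plane (polar 90°/270°) — the boundary the front/back classification is
about — with a 10° allowance on either side; a Middlebrooks-style preset
(30° lateral limit, no allowance) is available, and swapping classifiers
can change FBC and PPE but never LPE. LPE and PPE are n−1 standard
deviations of signed errors pooled per subject × condition × rotation
about the pooled mean; PPE excludes trials classified as confusions;
targets with no FBC label (ineligible laterals) remain in the PPE sample,
since they carry no label to trigger omission — this choice is flagged in
the QC report. Groups with fewer than two usable trials yield NaN, never
zero.

Precision metrics are modeled at the cell level (one value per
subject × condition × rotation) with a linear mixed model — cell-means
fixed effects (equivalent to condition + rotation + interaction), subject
random intercept, REML, ML fallback on singular fits. Confusions are
modeled at the trial level with a random-intercept logistic regression;
since no installed Python package fits this by maximum likelihood, the
marginal likelihood is maximized directly using adaptive Gauss–Hermite
quadrature (15 nodes centered and scaled at each subject's posterior mode)
over per-subject × cell binomial counts, with covariances from the numeric
Hessian; the fit is cross-checked against `lme4::glmer` in the test suite
(agreement to ~0.02 on cell log-odds). Marginal-mean contrasts are
Tukey-adjusted via the studentized range, one family per grouping level
(all rotation pairs within a cue, or all cue pairs within a rotation),
mirroring the structure of such studies' contrast tables; a two-level
family reduces to the unadjusted test.

## Operating characteristics and recovery

The simulation harness replays the whole chain
(simulate → QC → metrics → models → contrasts) on independent replicates
and tallies per-contrast rejection rates with Wilson confidence intervals.
Problem sizes were chosen to keep a full run at a few minutes on one CPU:
7 subjects, one repetition per session (52 static and 104 dynamic trials
per cell and subject), 200 replicates. Under null parameters the
unadjusted per-contrast type-I error sits near the nominal 5% (Tukey
adjustment is conservative for single contrasts by design); under the
default effects the flat-condition static→yaw confusion drop (0.40→0.15)
is detected with power ≈ 1.0 even after adjustment.

Parameter recovery is verified at 5,000 trials per cell with uniform cells
at the published static free-field aggregates and subject effects off, on
a grid whose targets stay ≥60° from the front/back boundary. That
restriction is a property of the *measure*, not a tuning choice: for
targets near the boundary, ordinary response scatter crosses it and the
classifier's 10° allowance cannot fully distinguish scatter from
confusion, so generating probability and measured rate differ by
construction (and PPE is truncated by the exclusion rule when σ_pol is
large). Away from the boundary the chain recovers σ_lat and σ_pol within
~2% and p_fbc within ~1 percentage point, comfortably inside the 5% / 2 pp
targets.

## Known limitations

* SOFA I/O is implemented directly on HDF5 (netCDF-4's storage layer) and
  covers the `SimpleFreeFieldHRIR` convention only; exotic files
  (spherical-harmonic conventions, per-emitter data) are rejected.
* The cyclic delay operator wraps energy past the buffer end; very short
  impulse responses with large TOAs would alias.
* The renderer's nearest-neighbor HRTF selection is appropriate for dense
  grids; on sparse grids, audible stepping would occur (per-block VBAP
  interpolation on the dense mesh is the supported alternative).
* Wald-type inference in the logistic model relies on moderate counts per
  cell; completely separated cells are flagged, not regularized.
* The free-field condition is represented by its gain stage; no acoustic
  rendering of the loudspeaker array is attempted.
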