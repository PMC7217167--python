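# Methods

## Problem and model

Transmitral flow is hard to measure with planar phase-contrast (PC) MR
because the mitral annulus moves 10–20 mm along the left-ventricular long
axis over the cardiac cycle: a static short-axis slice does not image the
valve in most phases, and even when it does, blood that enters the ventricle
because the annulus itself sweeps over the blood column (the *passive
transfer volume*) is invisible to PC velocities measured in the scanner
frame.  A slice-following acquisition translates the imaging plane each
cardiac phase so it stays on the annulus, and a through-plane motion
correction subtracts the annular velocity from the measured blood
velocities, so flow is expressed relative to the moving valve.

`valvepc` implements the complete off-line chain around such a sequence:

1. **Synthetic acquisition** (`synthetic_cine`) — a cone-phantom scene for
   validating the slice-translation mechanics, and a moving-valve heart
   scene with exactly known ground truth.
2. **Valve motion** (`valve_motion`) — annular insertion-point trajectories
   → displacement along the slice normal → valve velocity → quantized slice
   translation table (the file a scanner would consume).
3. **Flow quantification** (`flow_quant`) — background phase-offset
   correction from static-tissue regions, motion correction, per-phase
   forward/backward/net flow rates over ROIs, stroke volumes, three
   regurgitant-volume estimates, and diastolic E/A.
4. **Method agreement** (`agreement_stats`) — Bland–Altman, ICC(2,1),
   Pearson, paired t, regression, with the five-band ICC interpretation.
5. **Pipelines and I/O** (`io_cli`) — NIfTI + JSON sidecar series storage,
   YAML-configured pipelines, and the `valvepc` CLI.

## Velocity encoding and noise

Pixel phase is proportional to through-plane velocity, wrapping at the
VENC; the wrapped representation is bijective on (−venc, +venc].  Noise is
added on the two underlying complex acquisitions (per-channel SD σ_c) and
propagated through the phase-difference reconstruction, so dim pixels have
proportionally noisier velocities and magnitude images acquire a Rician
character.  For the heart scene the noise level is specified as the
velocity-equivalent SD in unit-magnitude pixels; the default 0.6 cm/s
corresponds to a VENC of 150 cm/s acquired with three bipolar pairs per
phase at typical breath-hold gradient-echo SNR.  The phantom default,
σ_c = 0.005 of the water signal, reflects the very high SNR of
gadolinium-doped water.  If the noise-free peak velocity reaches the VENC
the simulator raises an error unless wrapping is explicitly permitted.

## Cone phantom

The cone has radius r(h) = r_bottom + (r_top − r_bottom)·h/H (defaults
H = 7 cm, top diameter 12 cm, bottom diameter 3 cm) and is rendered dark in
bright water with exact/supersampled partial-volume edge weighting (16×16
sub-pixel sampling on boundary pixels; interior and exterior pixels exact).
The planned (offset-zero) slice sits at the 3.5 cm mid-height bar; the bar
itself occupies a thin axial band and is omitted from rendered slices.  The
programmed schedule moves the slice 1 mm per phase: inferiorly (toward the
apex, negative offsets) for 15 phases including the start, a 3-phase hold,
then superiorly for the remaining phases.  Both 27- and 28-phase variants
are available and the pattern is fully configurable; the protocol's
27-phase preset is the default.

The radius estimator is area-equivalent: r = sqrt(A/π), where A sums
per-pixel foreground fractions.  Foreground/background signal levels are
measured from the eroded interior and the far background, and only a
two-pixel boundary band contributes fractionally; this keeps the estimate
sub-pixel accurate on partial-volume renderings and insensitive to the
Rician noise floor inside the dark region.  On the full simulated
27-phase experiment the mean signed radius error is below 0.01 mm.

Sign convention: for the phantom, slice offsets are along the scanner
axis with negative = inferior (toward the apex, shrinking radius), so the
rendered slice height is `start_height + offset/10`.  For the heart scene,
displacement and offsets are positive-apical and follow the valve directly.
The two conventions never interact numerically.

## Heart scene

The scene is a 2-D annular inflow disk (default radius 19 mm) at the image
centre, a surrounding tissue ring that moves with the annulus, a
time-dependent static-tissue block (chest-wall analogue), and a spatially
smooth background phase offset (default constant 1 cm/s; a planar gradient
is supported).  Default grid: 128×128 at FOV 256 mm (2 mm pixels), 30
phases over a 1000 ms RR-interval.

**Waveform.** The transmitral velocity is a sum of two raised-cosine lobes
(E and A) over fixed diastolic windows, with relative peaks set by
`e_peak`/`a_peak` (default 0.6/0.4 m/s, preserving an E/A of 1.5) and the
overall amplitude normalized so the discrete diastolic forward volume
through the disk equals the configured stroke volume exactly; realized peak
velocities are recorded in the ground truth.  The spatial inflow profile is
flat across the orifice — transmitral flow detaches at the annulus rather
than developing a no-slip tube profile, and the standard clinical model
(SV = annulus area × velocity–time integral) assumes exactly this.  The
regurgitant jet is a systolic raised-cosine lobe with a parabolic
(Poiseuille-like) profile over a central orifice (default 0.7 of the
annulus radius), scaled to the configured regurgitant volume.

**Valve motion.** Displacement rises as a raised cosine to the configured
excursion (default 15 mm) at end systole (default phase index
round(0.38·n)).  The diastolic return is constructed so that the *cyclic
central finite difference* of the sampled displacement — exactly the
derivative the analysis chain later subtracts — is proportional to the
instantaneous inflow: annular recoil tracks filling, and the annulus is at
rest whenever inflow is zero.  Because the central difference couples
alternate phases, the return is built as two interleaved recurrences, each
closed onto the end-diastolic position.  This discrete self-consistency
makes motion correction exact on noise-free scenes (machine-precision
stroke-volume recovery).

**Plane modes.** In `following` mode the lab-frame velocity inside the disk
is transvalvular velocity plus valve velocity, so subtracting the valve
velocity recovers true transvalvular flow; the slice-offset table is the
quantized displacement.  In `static` mode (plane fixed at the end-systolic
valve location) there is no valve-velocity term; instead a single blunt
systolic outflow stream toward the septal side carries
`lvot_sv + regurgitant_volume` — at a static basal plane LV outflow and
regurgitant convergence are physically indistinguishable, which is exactly
why the quantifier refuses to report a direct regurgitant volume there.

**Ground truth.** All volumes are direct discrete sums over the generated
fields: mitral SV and regurgitant volume are exact by normalization, the
aortic SV is mitral SV minus regurgitation, the planimetric SV equals the
mitral SV, and the passive transfer volume is Σ (−v_valve)·A_disk·Δt over
diastole (≈ annulus area × excursion).

**Companion acquisitions.** A separate aortic-root series (VENC 180 cm/s,
64×64 grid) carries a systolic forward lobe and a 3% early-diastolic
backflow normalized so the whole-cycle net volume equals the aortic SV
exactly; a synthetic short-axis stack distributes EDV = SV/EF (default
EF 0.6) over 10 slices with a semi-ellipsoid area profile, summing exactly.

## Quantification choices

* Pixel inclusion is by pixel-centre-in-polygon; ROI vertices are 0-based
  (row, col).  The default scene ROI is a 48-gon whose *inradius* equals
  the annulus radius, i.e. drawn exactly on the annular border: pulling in
  surrounding tissue biases both the forward-flow sum (rectified noise) and
  the motion-correction deficit (clipped tissue velocity).
* The forward/backward split is per-pixel sign within the ROI, so
  simultaneous forward and backward flow is resolved.
* Correction order: background first (scanner-frame error), then motion
  (physiology).  Background correction subtracts the per-phase mean
  velocity of the static-tissue ROI.
* Mitral SV is the diastolic *forward* volume; diastolic backward flow is
  excluded (it reflects ventricular or atrial flow, not transmitral flow).
  Aortic SV is the whole-cycle net volume.  Regurgitant volume is reported
  three ways: planimetric − aortic SV (guidelines), systolic backward
  volume (direct; refused for static planes), and mitral − aortic SV.
* E and A use the *uncorrected* velocities, in analogy with
  echocardiography: per phase the 95th linear-interpolation percentile of
  per-pixel ROI velocities, maximized over the early/late window.  The
  alternative reading (95th percentile of per-phase maxima) is available as
  `mode="phase_maxima"`.  A ≤ 0 flags E/A as undefined (NaN) rather than
  raising.
* End systole and end diastole come from scene ground truth in simulations
  and must be supplied by the user for external data.
* Rounding of slice translations is half-away-from-zero (symmetric for
  inferior/superior motion); quantization error is ≤ half the slice
  spacing.
* ICC is fixed to the two-way random-effects, absolute-agreement,
  single-measures form — the convention for method comparison.  The
  published interpretation bands leave gaps such as (0.30, 0.31)
  undefined; they are closed with half-open intervals cut at the midpoints
  0.305/0.505/0.705/0.905, with negative values mapping to poor.
  Limits of agreement use 1.96 SD.

## Validation cohort and problem sizes

The parameter-recovery study runs 20 seeded scenes spanning stroke volumes
40–120 ml, excursions 0–20 mm and regurgitant volumes 0–30 ml.  Three
anchor scenes pin the extremes (excursion 0; excursion 20 mm; regurgitation
30 ml); the remainder draw a physiologically coupled cohort in which
excursion tracks stroke volume, the annulus radius scales with SV^(1/3) and
regurgitation is capped at 45% of SV.  At these sizes (30 phases, 128×128)
a full scene simulation plus quantification takes well under a second, the
whole cohort a few seconds, and the complete test suite under a minute.
For the excursion-0 anchor the passive volume is zero and the
deficit-vs-passive comparison becomes 0/0; it is checked as an absolute
bound (|deficit| ≤ 0.5 ml) instead.

## What the generator does and does not emulate

Emulated: annular excursion and its velocity, biphasic E/A inflow,
passive volume transfer, regurgitant jets, LVOT contamination of static
planes, VENC-limited encoding with wrapping, complex-channel noise with
magnitude-dependent velocity noise, smooth background offsets,
partial-volume edge rendering (phantom), time-dependent static tissue.

Not emulated: k-space/SSFP physics, eddy currents and Maxwell terms,
in-plane valve translation and oblique annular angulation of the imaging
plane (the annular tilt appears only in the trajectory, not the images),
intravoxel dephasing and turbulence in jets, breathing motion, chest-wall
steady-state artifacts, and within-quantum (±0.5 mm) tracking error of the
slice-following plane.  Passing tests therefore demonstrate correctness of
the *computational chain* — corrections, integration, statistics — under a
faithful signal model, not robustness to every scanner artifact; on real
data, background-correction residuals, profile/turbulence effects and
tracking error would add to the error budget.

## Known limitations

* The forward-only mitral SV retains a small positive noise-rectification
  bias from near-zero-velocity ROI pixels during diastasis (~1% at default
  noise for small hearts); it is inherent to the per-pixel sign split.
* The direct regurgitant-volume estimate inherits the same systolic
  rectification (~+1 ml at default settings).
* Velocity is sampled at pixel centres (no partial-volume mixing of the
  velocity channel); ground truth uses the same convention, so recovery
  statements are about the analysis chain, not sub-pixel velocimetry.
* ICC confidence intervals and repeated-measures Bland–Altman are out of
  scope.
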