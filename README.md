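# valvepc

Slice-following phase-contrast (PC) cardiac MR, from simulation to
quantification.  `valvepc` is for researchers developing or validating
valvular flow methods: it simulates cine-PC acquisitions of a cone
validation phantom and of a moving mitral valve with exactly known ground
truth, converts tracked annular trajectories into the slice-translation
tables a slice-following sequence consumes, quantifies transmitral and
aortic flow with background and through-plane motion correction, and
computes the method-agreement statistics used to compare techniques.

## The problem and the method

The mitral annulus travels 10–20 mm along the LV long axis every heartbeat,
so a static PC slice does not stay on the valve, and blood passively
transferred into the ventricle by the annular sweep is invisible to
scanner-frame velocities.  The method implemented here follows the valve:

1. Track the septal and lateral mitral insertion points in a long-axis
   cine; the valve displacement is the insertion-point midpoint projected
   on the slice normal, d(t), re-zeroed at the first phase.
2. Quantize d(t) to the 1 mm grid of parallel slices and write a plain-text
   translation table — one signed mm value per phase — that the (simulated)
   sequence uses to move the imaging plane in real time.
3. Correct the acquired velocities: subtract the per-phase mean velocity of
   a static-tissue region (background phase offset), then subtract the
   valve velocity v(t) = d′(t) (cyclic central differences), so flow is
   relative to the moving annulus.
4. Integrate over the valve ROI:
   - mitral SV = diastolic forward volume, Σ_diastole Σ_{px: v>0} v·a·Δt
   - aortic SV = whole-cycle net aortic volume
   - regurgitant volume: planimetric − aortic SV (guidelines), systolic
     backward volume (direct; only identifiable on slice-following planes),
     and mitral − aortic SV
   - E, A, E/A from 95th-percentile peak velocities, uncorrected, in
     analogy with echocardiography.
5. Compare methods with Bland–Altman (bias ± 1.96 SD limits), ICC(2,1),
   Pearson r, paired t and linear regression.

The synthetic scenes make every one of those quantities exactly known, so
the whole chain is testable end to end.  See `docs/methods.md` for the
model details and assumptions.

## Worked example

```python
import valvepc as v

params = v.HeartSceneParams(seed=7, true_mitral_sv_ml=80.0,
                            regurgitant_volume_ml=10.0)
report, gt = v.analyze_heart_scene(params, plane_mode="following")
```

This simulates a slice-following acquisition of a valve with an 80 ml
stroke volume, 15 mm annular excursion and 10 ml of regurgitation, then
runs ROI placement, background correction, motion correction, flow
integration and the companion aortic/planimetric measurements.  Printing
the report fields gives:

```
mitral SV (corrected):   80.5 ml   (ground truth 80.0)
mitral SV (uncorrected): 64.0 ml
passive transfer volume: 16.4 ml
aortic SV:               69.9 ml   (ground truth 70.0)
planimetric SV:          80.0 ml
regurgitant volume:      direct 10.7 ml, mitral-aortic 10.6 ml, guideline 10.1 ml
regurgitant fraction:    13.2 % of mitral SV
E = 0.31 m/s, A = 0.21 m/s, E/A = 1.47
```

The corrected stroke volume recovers the ground truth within the noise
floor, while the uncorrected value falls short by almost exactly the
passive transfer volume (16.4 ml) — the blood the moving annulus carries
into the ventricle that scanner-frame PC cannot see.  All three
regurgitant-volume estimates agree with the configured 10 ml.  On a
`plane_mode="static"` scene the direct estimate is refused (reported as
NaN with a note), because systolic backward flow at a fixed basal plane
mixes LV outflow with regurgitation.

## Command line

The same pipelines are available as a CLI:

```sh
valvepc simulate-phantom  --config cfg.yaml --seed 1 --out out/
valvepc validate-phantom  --config cfg.yaml --out out/
valvepc simulate-heart    --config cfg.yaml --seed 1 --out out/
valvepc make-schedule     --config cfg.yaml --out out/
valvepc quantify          --config cfg.yaml --out out/
valvepc agree             --config cfg.yaml --out out/
```

Series are stored as `<stem>_mag.nii.gz` / `<stem>_vel.nii.gz` with a JSON
sidecar (VENC, phase timing, slice offsets, grid); trajectories, flow
curves, ground truth and reports are CSV/JSON; translation tables are plain
text.  Units are fixed: mm, ms, cm/s (velocity maps), m/s (E/A reports),
ml.  Runs are deterministic for a fixed seed.

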