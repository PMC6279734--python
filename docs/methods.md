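# Methods

`gatedpet` is a tested re-implementation of an ECG-gated small-animal
cardiac PET analysis chain: list-mode events are sorted into 16 cardiac
frames per cycle, the left-ventricular (LV) cavity volume is estimated in
every frame, and the 16-point time–volume curve yields the systolic and
diastolic functional indices

- **EDV / ESV** (µL): global max / min of V(t) over one cycle,
- **EF** (%): 100·(EDV − ESV)/EDV,
- **PFR** (EDV/s): max dV/dt over the filling interval (ES → next ED),
  normalised by EDV,
- **1/3MFR** (EDV/s): mean dV/dt over the first third of the filling
  time, computed exactly as the chord slope
  [V(t_ES + T_f/3) − V(t_ES)]/(T_f/3)/EDV,
- **TPFR** (ms): time from ES to the instant of peak filling,
- **HR** (bpm): 60 / mean accepted R-R interval.

Because no animal data are available, every stage is validated by
parameter recovery against a synthetic beating-LV phantom whose ground
truth is known analytically. Two simulated cohorts — Zucker lean (ZL)
controls and Zucker diabetic fatty (ZDF) rats, a type-2-diabetes model
with early diastolic dysfunction at preserved EF — provide the group
comparison; their parameter means and SDs (n = 6 each) are the package's
stated reference world (`gatedpet.phantom.presets`).

## Volume-curve model

V(t) is represented as a trigonometric polynomial of K ≤ 7 harmonics
(default 6) of the cardiac period T. This family is closed under the
analysis chain: 16 uniform gate samples determine a ≤7-harmonic curve
exactly (Nyquist), so noiseless synthesize → sample → fit round trips are
exact and recovery failures always indicate an implementation defect, not
sampling loss. All rate indices are read off the *analytic* derivative of
the fitted curve; discrete frame differences are never used, because the
true dV/dt peak rarely coincides with a frame boundary and discrete
differences bias PFR low. For noisy gated data the default fit order
drops to 4 harmonics (bias/variance trade-off at 16 gates; 6 is used for
noiseless oracle work).

## Curve synthesis (phantom ground truth)

Given targets (EDV, ESV, HR, and optionally PFR, TPFR, 1/3MFR) the
generator constructs coefficients such that the *measured* parameters of
the synthesized curve reproduce the targets within 0.5 % (TPFR within
0.5 % of the period), verified after the fact; an unverifiable spec
raises an infeasibility error naming the constraint, never a silently
wrong curve.

The solver exploits the observation that once the end-systolic phase and
the peak-filling time are fixed, every target is *linear* in the harmonic
coefficients. For each candidate filling-time layout (a short scan of
filling fractions plus a heuristic from the target PFR) the curve is the
solution of a small convex program: equalities V(0)=EDV, V(t_ES)=ESV,
dV/dt(0)=dV/dt(t_ES)=0, dV/dt(t_peak)=PFR·EDV, the 1/3MFR chord;
inequalities enforcing strict ejection (dV/dt < 0) over systole, strict
filling (dV/dt > 0) over diastole, and a peak cap dV/dt ≤ PFR·EDV·(1 −
0.05·((t − t_peak)/T_f)²) whose margin keeps the arg-max well separated
from solver slack (the inequalities hold on a dense grid; between grid
points a 6-harmonic curve can wiggle by ~1e-5 of the peak, so a flat cap
would make TPFR ill-posed). A k⁴-weighted roughness objective (SLSQP)
selects the smoothest member; ED sits at phase 0 by construction.

**Feasibility ceiling of 1/3MFR.** Since ES is a true minimum of a smooth
periodic curve, dV/dt(t_ES) = 0 exactly. The mean of dV/dt over the first
third of filling therefore cannot approach the peak rate arbitrarily
closely at finite bandwidth: a linear program over the harmonic
coefficients bounds the achievable 1/3MFR/PFR ratio at ≈ 0.88 (K = 6,
with the shape constraints above). The ZL reference means put 1/3MFR
within 1 % of PFR — consistent with software that differentiates the
16-point curve *discretely* (frame differences skip the zero-slope point
at ES), but unattainable under this package's analytic-derivative
definition. `synthesize_curve` therefore refuses such specs unless the
target is named in `best_effort`, in which case an LP first finds the
achievable chord value closest to the target and the QP pins it; the
achieved value (≈ 10.6 EDV/s for the ZL set) becomes the subject's ground
truth. Cohort simulations use this mode, and the recovery acceptance
check for the configured ZL 1/3MFR fails by construction — it is kept
failing deliberately, as the honest record of this definitional gap.

## Phantom geometry and list-mode simulation

The LV is a thick-walled prolate half-ellipsoid: cavity semi-axes
(a, a, c) with c = 1.8·a by default, apex at z = −c, base plane at z = 0,
myocardium of constant 2 mm wall thickness, closed at the base by a flat
myocardial lid (cap) of the same thickness so that the cavity is fully
enclosed — the open-mitral-plane variant (`cap_thickness=0`) is kept for
robustness tests. Cavity volume fixes a analytically
(V = (2/3)πa²c), so the stored ground-truth volume is exact and
grid-independent. Voxelization is anti-aliased (sub-voxel occupancy
averaging); scanner resolution is an isotropic Gaussian blur
(FWHM 0.8 mm by default, the regime of a dedicated small-animal PET);
myocardium-to-background activity is 10:1.

List-mode events are an inhomogeneous Poisson process in image space:
the cycle is split into 32 phase bins, each with the activity map of the
instantaneous cavity volume, and counts per (beat, bin) are Poisson with
intensity proportional to the map total. R-R intervals are Gaussian with
configurable jitter, truncated below at half the mean (a controllable
arrhythmia surrogate). Defaults: 5·10⁶ expected events per acquisition —
enough that per-gate Poisson noise does not dominate the volumetry.
Everything is seeded; repeated runs are bitwise identical.

What the phantom does *not* emulate: sinogram formation and
reconstruction (events are deposited directly in image space), attenuation,
scatter, randoms, dead time, decay, respiratory motion, right-ventricular
or atrial activity, wall-motion asymmetry. A green recovery test
therefore establishes the correctness of the gating/volumetry/curve
mathematics under idealised imaging, not robustness to reconstruction
artefacts.

## Gating

Events are assigned a phase linearly within their own beat's R-R
interval (half-open [T_i, T_{i+1}) beats, gate = ⌊16·phase⌋ clamped to
15), matching the per-beat semantics of clinical gated acquisition.
Beats whose R-R deviates more than 30 % from the median R-R are rejected
(switchable off); partial beats at the stream edges are discarded.
Discarded events are counted, never silently dropped — the suite asserts
exact conservation. HR = 60/mean(accepted R-R).

## Segmentation (count-based volumetry)

A QGS-style radial surface detector replaces the unpublished commercial
tool. Images are first magnified 5× (trilinear, counts preserved) —
a rat LV spans only a handful of reconstructed voxels. One LV centre
per study (intensity-weighted centroid of the largest connected
component above half the 99th-percentile intensity of the gate-summed
image) stabilises low-count gates. Along ~500 quasi-uniform rays
(Fibonacci sphere) the myocardial count peak is located by a Gaussian
fit, which also provides the quality gate (R² ≥ 0.8, peak inside the
search range). The endocardial radius is then the inner-edge parameter of
a blurred-slab (erf-pair) fit seeded by the Gaussian. The erf-pair was
chosen over the conventional Gaussian half-maximum offset
μ − σ√(2 ln 2) after quantifying the latter's bias: for a 2 mm wall at
0.8 mm FWHM the wall profile is a flat-topped blurred rectangle, the
fitted Gaussian underestimates the full myocardial amplitude, and radii
land ~0.1 mm inside the truth — alone a +9 % error on an ESV-sized
cavity, busting the 5 % volumetric budget for reasons unrelated to the
pipeline under test. The half-maximum crossing of the measured profile
remains as fallback when the erf fit fails.

Failed rays are imputed with the median of their six nearest valid
neighbours; a gate with fewer than 80 % valid non-basal rays raises an
unreliable-gate error carrying the gate index. Rays within 30° of the
basal long axis are never sampled; the cavity volume is the
solid-angle-weighted cone sum V = Σ (ΔΩ/3)·r³ plus the analytic
cone-to-plane cap (π/3)·h³·tan²θ for the excluded cone, with the base
height h taken as the 98th percentile of the detected wall's basal
extent. With the capped phantom every remaining ray crosses myocardium;
with an open base, basal-side rays that see no wall (configurable cone,
65° default) take the estimated base plane instead. The detector is
intensity-scale free by construction. Verified against analytic radii,
the cone-sum quadrature itself is exact to < 0.1 %; the end-to-end
volumetric error on the noiseless default phantom is −2 % (EDV-sized) to
−3 % (ESV-sized), dominated by residual interpolation smoothing that the
erf blur term does not model exactly.

## Statistics

Classic pooled-variance two-tailed Student's t-tests (df = n₁ + n₂ − 2),
the appropriate choice at n = 6 per group; Welch's form is an option
flag. A summary-statistics entry point reproduces the tests exactly from
group means and SDs, which is how the reference significance pattern is
recomputed (PFR p ≈ 0.0046 and 1/3MFR p ≈ 0.004, both < 0.01; TPFR
p ≈ 0.048 < 0.05; EF and HR not significant). No multiple-testing
correction is applied across the seven parameters, mirroring the original
analysis; every report carries that note in its footer. The paired test
is the one-sample t on differences. Type-I calibration of the
independent test is asserted over 2000 null simulations.

## Numerical choices and degenerate inputs

- Extrema and arg-max refinement: dense grid (≥ 2048/period) plus bounded
  scalar minimisation; inside the synthesis loop a cheaper parabolic
  refinement is used.
- A curve whose peak-to-peak range is below 1 % of its mean volume is
  degenerate (no systole/diastole structure) and raises rather than
  returning meaningless phases.
- Zero-variance t-test inputs: equal means give t = 0, p = 1; unequal
  means raise (the statistic is undefined).
- Gate index ties at beat boundaries follow the half-open convention;
  an event exactly on a trigger belongs to the beat it starts.
- All randomness flows from explicit per-call seeds (`numpy` Generator);
  there is no global random state anywhere.

## Known limitations

- The basal cap height is estimated from the detected wall; with strong
  blur and an open base it is biased slightly low, which propagates ~1–2 %
  into ESV-sized volumes.
- Diastolic indices from *noisy* gated data are high-variance at 16
  gates; with the 4-harmonic default the pipeline recovers volumes and EF
  well but PFR/TPFR carry visible noise at realistic count levels.
- The phantom's radial-only wall motion means the shared-centre design
  decision is untested against translating hearts.
- The 1/3MFR definitional gap against discretely-differentiating software
  is documented above and left visible in the acceptance suite.
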