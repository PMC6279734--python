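# gatedpet

ECG-gated cardiac PET analysis of left-ventricular systolic **and
diastolic** function for small-animal studies, with a fully synthetic
beating-LV phantom for validation.

Diastolic dysfunction — impaired ventricular filling at preserved
ejection fraction — is one of the earliest cardiac signs in type-2
diabetes. Gated ¹⁸F-FDG PET can measure it without extra scans: list-mode
events are sorted into 16 frames per cardiac cycle using the ECG R-wave
triggers, the LV cavity volume is estimated per frame, and the fitted
time–volume curve V(t) yields

| index | definition | units |
|---|---|---|
| EDV, ESV | max / min of V(t) | µL |
| EF | 100·(EDV − ESV)/EDV | % |
| PFR | max dV/dt over filling, / EDV | EDV/s |
| 1/3MFR | mean dV/dt over the first third of filling, / EDV | EDV/s |
| TPFR | time from end-systole to peak filling | ms |
| HR | 60 / mean R-R | bpm |

V(t) is modelled as a ≤7-harmonic Fourier series, which 16 gates
determine exactly, and all rates come from its analytic derivative.

The package contains five pipeline stages — `phantom` (synthetic curves,
4D images, list-mode event/trigger streams, simulated cohorts), `gating`,
`lvseg` (QGS-style radial endocardial detection), `curveanalysis`
(a statsmodels-flavoured `VolumeCurveModel` whose `fit()` returns a
results object), and `stats` (pooled t-tests, cohort reports) — plus a
`gatedpet` command-line tool (`simulate`, `gate`, `segment`, `analyze`,
`compare`, `reproduce`). Two built-in reference cohorts (Zucker lean
controls vs. Zucker diabetic fatty rats, n = 6 each) define the group
comparison the pipeline is built to detect: reduced PFR and 1/3MFR and
prolonged TPFR at preserved EF and HR. See `docs/methods.md` for the
model details and design rationale.

## Worked example

Synthesize a ground-truth curve at the lean-control group means, sample
it at 16 gate midpoints, and run the curve-analysis stage:

```python
from gatedpet.phantom import synthesize_curve, sample_gate_volumes
from gatedpet.phantom.presets import zl_mean_spec
from gatedpet.curveanalysis import VolumeCurveModel

spec = zl_mean_spec()                      # EDV 410.8 µL, ESV 155.1 µL,
curve = synthesize_curve(spec)             # HR 331 bpm, PFR 12.1 EDV/s,
gates = sample_gate_volumes(curve, 16)     # TPFR 35.4 ms
fit = VolumeCurveModel(gates, hr=spec.heart_rate).fit(n_harmonics=6)
print(fit.summary())
```

```
LV time-volume curve analysis
==============================================
gates                                       16
harmonics                                    6
fit RMSE (uL)                            0.000
----------------------------------------------
EDV (uL)                                 410.8
ESV (uL)                                 155.1
Stroke volume (uL)                       255.7
EF (%)                                    62.2
PFR (EDV/s)                              12.10
1/3MFR (EDV/s)                            8.69
TPFR (ms)                                 35.4
HR (bpm)                                 331.0
==============================================
```

Every configured parameter is recovered exactly: the zero fit RMSE
reflects the Nyquist property (16 samples determine a 6-harmonic curve),
and EF = 62.2 % is what EDV/ESV of 410.8/155.1 µL imply. The full
two-cohort experiment,

```sh
gatedpet reproduce --seed 1 --out results/experiment
```

simulates both cohorts through the pipeline and prints the comparison
report; at this seed the diastolic indices separate the groups
(PFR 12.64 ± 0.61 vs 10.35 ± 0.83 EDV/s, p = 0.0003; 1/3MFR p = 0.003)
while EF (p = 0.60) and HR (p = 0.12) do not — the
diastolic-dysfunction-at-preserved-EF pattern the method exists to
detect.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the recovery targets for the curve stage (PFR,
1/3MFR, TPFR, EF against the configured lean-control truths), the
heart-rate estimate from a jitter-free trigger stream, and the
segmentation estimates of EDV and ESV on the noiseless fine-grid phantom,
writing one JSON object with a `value` and problem size `n` per target.
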