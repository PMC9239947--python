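# mdmefit

Quantitative-MRI toolkit for the MDME (multi-dynamic multi-echo)
saturation-recovery sequence: forward signal modeling, voxelwise
T1/T2/M0/B1 mapping by bounded least squares, synthetic phantom studies
with scanner-like Rician noise, and test–retest repeatability statistics.

## The problem

MDME acquisitions image every slice at 2 echo times × 4
saturation-to-acquisition delays, so a single ~6-minute scan yields
quantitative T1 and T2 maps (and synthetic contrast-weighted images) of
the whole brain.  Relaxation times are physical constants of a tissue, so
changing scan-efficiency parameters — echo train length, acquisition
matrix, parallel-imaging acceleration — should not change them; whether
the *fitted* values really are stable under such changes is an empirical
repeatability question.  `mdmefit` reproduces that experiment fully in
software for users who need a controlled testbed: three brain-mimicking
vials (GM, WM, CSF) with known ground truth, twelve published protocol
presets in three parameter families, nine simulated repeats per protocol,
and the coefficient-of-variation (CV) analysis that summarises the result.

## The model

The steady-state magnitude signal of a voxel (T1, T2, proton density PD)
at echo time TE, delay TI, repetition time TR is

    I = A·PD·exp(−TE/T2) · [1 − (1−cos B1θ)·exp(−TI/T1) − cos B1θ·exp(−TR/T1)]
                          / [1 − cos B1α · cos B1θ · exp(−TR/T1)]

with α = 90° excitation, θ = 120° saturation, B1 the relative transmit
field, and A an overall intensity scale (A·PD is fitted as one parameter
M0).  Each voxel's 8 samples are inverted for (T1, T2, M0, B1) by a
bounded Levenberg–Marquardt fit with closed-form staged initialization;
magnitude fold-over of the early, still-negative recovery is handled by
explicit sign-hypothesis enumeration.  ROI means of the fitted maps feed
two statistics: the **intragroup CV** (across the 9 repeats of one
protocol) and the **intergroup CV** (across the 4 per-protocol means of
one family).  See `docs/methods.md` for the full account.

## Worked example

Forward-model a gray-matter-like vial (T1 = 1100 ms, T2 = 139 ms,
PD = 0.8, scale A = 500) under the ETL1 preset, take magnitudes, and
invert:

```python
import numpy as np
from mdmefit import (TissueParams, get_protocol, signal_set,
                     fit_signal, SignalSet)
from mdmefit.signal import SignalSample

p = get_protocol("ETL1")            # TE 18.9/94.4 ms, TR 4000 ms
gm = TissueParams("GM", t1_ms=1100.0, t2_ms=139.0, pd=0.8)

s = signal_set(gm, p, scale=500.0, b1=1.0)
print(np.round(s.intensities, 2).tolist())

mags = SignalSet(tuple(SignalSample(v.te_ms, v.ti_ms, abs(v.intensity))
                       for v in s.samples), p.name)
r = fit_signal(mags, p)
print(f"T1 = {r.t1_ms:.1f} ms   T2 = {r.t2_ms:.1f} ms   "
      f"M0 = {r.m0:.1f}   B1 = {r.b1:.3f}   rms residual = {r.residual_norm:.2e}")
```

Output:

```
[-52.28, 150.28, 274.7, 331.61, -30.37, 87.3, 159.57, 192.63]
T1 = 1100.0 ms   T2 = 139.0 ms   M0 = 400.0   B1 = 1.000   rms residual = 3.64e-14
```

The first four numbers are the signed signals along the four delays at the
first echo — negative at the shortest delay because a 120° saturation
pulse leaves the magnetization inverted — and the fit recovers all four
parameters of the noise-free voxel to machine precision.

The full study is one call (or `mdmefit run-all --seed 1 --out report/`
from the shell):

```python
from mdmefit import run_study
result = run_study(seed=1, grid=96, n_repeats=9)
print(result.report.intergroup.head(3))
print(f"max intergroup CV: {result.report.max_intergroup_cv():.3f}%")
```

```
  family vial quantity  cv_percent
0    ETL   GM       T1    0.016939
1    ETL   GM       T2    0.015906
2    ETL   WM       T1    0.043091
max intergroup CV: 0.458%
```

Every intergroup CV is a fraction of a percent — far below the 3% bound —
i.e. changing ETL, matrix or acceleration does not move the fitted
relaxation times, which is the experiment's conclusion.  A CLI is
included (`mdmefit protocols list`, `simulate`, `study`, `fit`, `report`,
`run-all`); stacks and maps are read and written as NIfTI.

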