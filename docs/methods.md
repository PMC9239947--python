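# Methods

`mdmefit` implements the quantitative core of a multi-dynamic multi-echo
(MDME) phantom repeatability experiment entirely in software: the
steady-state signal model of a saturation-recovery fast-spin-echo
acquisition, its voxelwise least-squares inversion to T1/T2/M0/B1 maps, a
synthetic three-vial phantom with scanner-like noise, and the
coefficient-of-variation (CV) analysis that quantifies how stable the
fitted relaxation times are when scan parameters change.

## Signal model

For a voxel with longitudinal relaxation time T1, transverse relaxation
time T2 and proton density PD, imaged at echo time TE after a
saturation-to-acquisition delay TI inside a repetition time TR, the signal
is

    I = A · PD · exp(−TE/T2)
        · [1 − (1 − cos(B1·θ)) · exp(−TI/T1) − cos(B1·θ) · exp(−TR/T1)]
        / [1 − cos(B1·α) · cos(B1·θ) · exp(−TR/T1)]

with excitation flip angle α = 90°, saturation flip angle θ = 120°, and B1
the relative transmit field that scales both flips.  A is an overall
intensity scale (coil sensitivity, receiver chain, voxel volume); A and PD
are algebraically inseparable, so the package fits their product
M0 = A·PD and makes no claim about PD in physical units.  Angles are
degrees at every interface and converted to radians at exactly one point
(`mdmefit.signal.mdme_signal_arrays`).

Each acquisition samples this model at 2 echo times × 4 delay times,
giving 8 images per slice.  With θ = 120° the recovery factor is negative
at short delays for long-T1 media; magnitude images fold this sign away,
which drives several solver choices below.

## Acquisition protocols

Twelve presets ship in three families of four, varying one parameter each:
echo train length (ETL1–4), acquisition matrix (Matrix1–4), and
parallel-imaging acceleration (Phase1–4, factors 3.0/2.5/2.0/1.0).  Shared
geometry: 240 mm square FOV, 4 mm slices, 1 mm gap.  Timing (TE₁/TE₂/TR),
matrix, bandwidth (25 kHz) and scan times follow the published protocol
tables; scan time is carried as metadata only, never computed.

The vendor sequence allows the four saturation delays to be chosen freely
and their values are not published; the package default is
(0.07, 0.26, 0.52, 0.87) × TR, spanning the early, middle and late
recovery while keeping every delay inside TR.  The delays are an explicit
protocol field and can be overridden in the YAML presets.

ETL deliberately does not enter the per-voxel signal equation — it is a
scan-efficiency parameter, and the experiment's point is whether it leaves
the fitted values unchanged.  It affects only metadata (and, through the
published tables, nothing else).

## Phantom and noise generator

The synthetic phantom places three cylindrical vials (radius 27 mm,
centers on an equilateral triangle of circumradius 60 mm) in the square
FOV, with brain-mimicking relaxation times taken from the mean measured
values of the physical GM/WM/CSF vials: T1/T2 = 1100/139 (GM), 571/135
(WM), 2543/1790 ms (CSF).  Proton densities are not published for these
phantoms; the defaults 0.80/0.65/1.00 are typical relative values for
agarose gels and free water, with overall scale A = 500.  Rasterization is
pixel-center-in-circle; background carries zeros and label 0.

Noise is Rician: the signed voxel signal receives iid Gaussian noise in
both complex channels and the magnitude is taken, so background pixels are
Rayleigh with mean σ·√(π/2).  The standard deviation scales with
acquisition settings as

    σ(p) = σ_ref · (V_ref / V(p)) · √(BW/BW_ref) · √(R/R_ref)

(V voxel volume, BW receiver bandwidth, R acceleration factor), the
textbook SNR dependencies without g-factor spatial structure.  Reference
conditions are those of preset ETL1 (V_ref ≈ 3.571 mm³, 25 kHz, R = 3).

σ_ref is a calibrated default (1.0 intensity units ≈ SNR 500 relative to
A): `scripts/calibrate_noise.py` selects it so that (a) the intragroup CV
of the GM vial's T1 at ETL1 over 9 repeats lands in the sub-1% range and
(b) the mean bias of every fitted parameter stays within ~2% for every
vial at every preset's noise level (the script prints both quantities for
candidate σ_ref values).  Criterion (b) matters because the two-echo T2
estimate of the CSF vial (T2 = 1790 ms sampled at TEs of 18.9/94.4 ms) is
ill-conditioned: its error distribution is strongly right-skewed and its
mean grows with noise, which would contaminate the between-protocol
comparison with noise-dependent estimator bias rather than genuine
scan-parameter effects.

Repeats differ only by fresh noise draws — there is no drift, temperature
or B1-profile variation between scan days, because no such data are
published for the experiment.  Consequences: (i) ROI averaging over
~290–2600 pixels suppresses iid noise by √n, so the synthetic intragroup
CVs (~0.02–0.7% at the defaults) sit an order of magnitude below the
scanner's printed values (0.2–7.8%), whose repeat-to-repeat variation is
dominated by scan-level effects; (ii) the headline *bound* — all
intergroup CVs below 3% — is reproduced, and the qualitative ordering
(CSF-T2 least repeatable) emerges from the conditioning argument above,
but the printed CV magnitudes are not reproduced and passing tests do not
claim they are.  B1 defaults to a constant 1.0; a smooth radial field
(e.g. 0.9–1.1) can be supplied to exercise the B1-fitting path.

Study replication seeds every (family, protocol, repeat) stack via
`numpy.random.SeedSequence((master_seed, family_idx, protocol_idx,
repeat))`, so a full study is bit-reproducible from one integer.

## Inversion

Each voxel's 8 magnitudes are fitted for (T1, T2, M0, B1) by bounded
least squares; bounds are T1 ∈ [50, 10000] ms, T2 ∈ [5, 5000] ms,
B1 ∈ [0.5, 1.5], M0 > 0.  An option fixes B1 = 1 (three-parameter fit).

**Initialization** is staged and closed-form: T2 from the two-echo log
ratio at the longest delay (exact for noise-free data); T1 from an
iterated plateau log-linear fit of the first-echo recovery; M0 from the
longest-delay amplitude corrected for T2 decay and incomplete recovery;
B1 starts at 1.  Degenerate inputs (no measurable echo decay) fall back to
midpoint-of-bounds starts and are flagged.

**Fold handling.**  Because magnitude data lose the recovery sign, the
naive |model| objective is non-smooth and multimodal.  The solver instead
enumerates the admissible *fold hypotheses* — which leading delays were
negative before the magnitude operation; a hypothesis is admissible if
un-folding leaves the first-echo series non-decreasing — and solves one
smooth signed-model problem per hypothesis.  Extra starts come from a
coarse (T1 × T2 × B1) grid scan with M0 solved in closed form (cached per
protocol, so the per-voxel cost is one matrix–vector product); the scan
keeps the best point of each local basin of the per-B1 SSE profile, which
guards against the (T1, B1) trade-off's secondary minima.

The winning hypothesis is chosen by SSE with a *fold-parsimony margin*: an
extra sign flip must improve the SSE by more than 9·σ̂² (σ̂² = best
SSE / 4 residual degrees of freedom).  Without the margin, a wrong fold of
a small-but-positive first sample (the WM vial's case) can win on noise by
a fraction of the noise variance and bias T1 low; genuinely folded signals
(GM and CSF early delays) are unaffected because their correct fold wins
by far more than the margin.  The noise-free case is untouched (σ̂² = 0).

**Optimizer.**  Each smooth subproblem is solved by a damped Gauss–Newton
(Levenberg–Marquardt) iteration with the analytic Jacobian,
column-scaled parameters, projection onto the bounds with an active-set
reduction, and tolerance 1e−10 on steps/objective; at most 200
iterations.  Noise-free signal sets are recovered to ~1e−15 relative.
Tests cross-check the solver against an independent hierarchical
grid-search minimizer (coarse scan plus basin-wise zoom refinement, M0
closed-form) on random noise-free draws.

`fit_maps` applies the fit above a background mask (mean-intensity
threshold, 25% of the image maximum by default); background voxels stay
NaN and outside `converged_mask`.  Fits that touch a bound are flagged.

## Repeatability analysis

ROI means use a circle of 18.0 cm² (radius ≈ 23.9 mm) centred in each
vial, pixel-center-in-circle inclusion, no partial-area weighting.  All
standard deviations are sample SDs (n−1).  CV = 100·SD/mean.

* intragroup CV: over the n_repeats ROI means at one protocol setting;
* intergroup CV: over the 4 per-protocol mean values within one family,
  each mean taken over all of that protocol's repeats;
* group means ± SD: over all 4 × n_repeats values of a family.

`summarize_study` requires the complete (family × protocol × repeat ×
vial × quantity) grid and reports missing cells explicitly.  Report CSVs
have a fixed column order (family, protocol, vial, quantity, cv_percent,
repeat_n) so diffs are stable.

## Problem sizes and defaults

The full synthetic study (3 families × 4 protocols × 9 repeats) runs at a
96 × 96 single-slice raster by default, which leaves ~290 pixels inside
each ROI and completes in a few minutes on one CPU; the phantom geometry
and ROI logic are resolution-independent and the same study runs at
288 × 288 unchanged.  Simulation is single-slice: the multi-slice
interleaving that realizes the delays on a scanner does not change the
per-voxel model.

## Synthetic contrast weighting

`synthesize_weighted_image` renders conventional spin-echo contrast
S = M0·(1 − exp(−TR_syn/T1))·exp(−TE_syn/T2) from fitted maps.  This
synthesis equation is this package's own convention for visualisation
(vendor synthesis equations are proprietary); long TE_syn reproduces the
fluid-bright T2-weighted appearance, TE_syn → 0 with long TR_syn
approaches the M0 map.  Inversion-prepared contrasts (FLAIR etc.) are out
of scope.

## Known limitations

* No scan-level variation between repeats (drift, B1-profile changes,
  eddy currents), hence intragroup CVs far below scanner reality; see
  above.
* Magnitude-Gaussian least squares, not a Rician likelihood; at the
  calibrated SNR the Rician floor is negligible inside the vials.
* No k-space simulation: FSE blurring vs ETL, parallel-imaging artifacts
  and g-factor maps, B0/motion effects are all absent, so the generator
  cannot reveal scan-parameter effects that act through those mechanisms.
* Mono-exponential relaxation per voxel; no partial-volume or
  multi-compartment modeling.
* The (T1, B1) pair is weakly identified from 4 delays at low SNR; bounds
  plus the B1 = 1 start decide the branch and bound-hitting fits are
  flagged rather than suppressed.
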