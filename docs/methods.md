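# Methods

This note documents the models implemented in `livert1`, the defaults and
why they were chosen, the numerical strategies, and what the synthetic
validation does and does not demonstrate.

## Signal models

**SPGR.** `spgr_signal` is the ideal-spoiling Ernst steady state. Its
independent oracle, `spgr_bloch_recursion`, iterates the longitudinal
recursion Mz(n+1) = Mz(n)·cosα·E1 + M0(1−E1) to convergence; the two agree
to 1e−8 relative across the tested parameter space. All times are in ms,
frequencies in Hz and angles in degrees at API boundaries; radians are
internal.

**Inversion recovery.** The three-parameter magnitude model
S(TI) = A − B·exp(−TI/T1) absorbs imperfect inversion into B/A < 2.
Polarity restoration tries both sign patterns around the minimum-magnitude
TI and keeps the lower residual.

**Slice profiles.** Selective excitation is Bloch-integrated sample by
sample (Rodrigues rotations, half-area refocusing lobe). The default pulse
is a Hanning-windowed sinc with time-bandwidth 8 sampled at 256 points —
the vendor's product excitation is unpublished, so the descriptor is
configurable and the small-tip profile is cross-checked against the scaled
Fourier transform of the envelope (agreement < 2 % at 5°). The achieved
flip α(z) = atan2(|Mxy|, Mz) is valid through 180°, which the 130° DAM
acquisition needs at B1+ > 1.3.

**Fat.** The default fat spectrum is a six-peak liver triglyceride model
(Hamilton-type amplitudes; main peak −3.4 ppm ≈ −434 Hz at 3 T), with a
single-peak variant selectable. Fat T1 defaults to 350 ms, a typical liver
triglyceride value at 3 T. Both choices are configuration, not physics the
pipeline depends on: they only matter for simulation studies of fat bias.

## EPG incomplete-spoiling correction

RF-spoiled SPGR with a quadratic phase schedule φ_n = φ_inc·n(n+1)/2 and
one fully-dephasing gradient per TR is simulated with the standard
configuration-state (F+, F−, Z) recursion, k_max = 60 states, convergence
when the demodulated |F0| changes < 1e−8 per pulse. The independent oracle
is a 2000-isochromat Bloch simulation with uniform per-TR gradient
dephasing; EPG and oracle agree to < 0.2 % over the (α, T1, T2) grid.

The correction factor c(α, T1) = S_EPG/S_ideal is tabulated on α ∈ [1°, 25°]
× T1 ∈ [300, 2000] ms and bilinearly interpolated inside the NLLS fit
(queries outside the grid clamp with a warning). Defaults: φ_inc = 50°
(Siemens product convention — not stated in the protocol, configurable),
T2 = 34 ms for in-vivo liver and 45 ms for the agar phantom (the phantom
value is stated; the in-vivo one is a literature-typical choice and
configurable). Diffusion is ignored. The correction is interpolated at the
current T1 iterate rather than iterating fit↔table to a joint fixed point;
the difference is far below the fit tolerance because c varies slowly in T1.

## Field maps

**B0** is angle(echo2·conj(echo1))/(2π·ΔTE) with per-slice 2D phase
unwrapping (scikit-image's quality-guided implementation) inside a
magnitude mask (default threshold 5× the background noise SD, estimated
from the lowest-magnitude decile unless given).

**EPI unwarp** is a native 1-D pixel-shift resampling along the
phase-encode axis: shift = Δf × (effective echo spacing × PE lines), linear
interpolation, voxels flagged when the shift exceeds FOV/4.

**2D DAM B1+.** Per voxel the measured 130°/65° EPI signal ratio is
inverted through a precomputed lookup

    R(b1; Gz) = |∫ sin α₂(z) w(z) dz| / |∫ sin α₁(z) w(z) dz|,
    w(z) = exp(i·2π·Gz·z·TE),

with α_i(z) from the Bloch slice profiles and Gz the through-slice B0
gradient estimated by central finite differences across slice centers
(constant within a slice). The dephasing weight w(z) is an independent but
faithful implementation of through-slice dropout at the EPI echo time; the
exact estimator used with the reference B1+ method is described elsewhere
and not reproduced. R is strictly decreasing in b1 up to the point where
2α crosses 180° (b1 ≈ 1.37 for the default pulse); the lookup keeps the
maximal monotone prefix and refuses to build if that prefix ends below
b1 = 1.3. Interleaved-slice T1 saturation over the 10 s TR is neglected
(< 1 % at these T1s).

**Resampling** of B1+ to the SPGR grid is trilinear in physical
coordinates via the NIfTI affines; the validity mask propagates
conservatively (a target voxel is valid only if all contributing source
voxels are).

## Dixon separation and T1 fitting

Complex inputs: after removing the B0 phase at each echo time and
referencing the in-phase echo's phase, W = |S_ip + S_op|/2 and
F = |S_ip − S_op|/2. Magnitude inputs fall back to (|S_ip| ± |S_op|)/2
under the water-dominant assumption, flagging voxels with F > W. Both
paths exist because vendor water images may come from either processing
chain.

The VFA fit minimizes Σ_j (S_j − c(α_j, T1)·S_Ernst(T1, M0, α_j))² with
α_j = b1 × nominal, repeated flip angles entering as separate
observations. Because M0 is linear in the model it is projected out
(variable projection), reducing each voxel to a 1-D problem in T1 solved
by a 96-point log-grid search plus golden-section refinement to 1e−8
relative, vectorized over voxels (≈ 50k voxels/5 s on one core). This is
algebraically the same optimum a Levenberg–Marquardt solver finds on the
separable model — a spot check against `scipy.optimize.least_squares`
agrees to 1e−5 — while being robust to the local-minimum and step-size
tuning a per-voxel LM would need. Bounds are T1 ∈ [100, 5000] ms;
bound-touching voxels are flagged non-converged. The two-point DESPOT1
log-linearization is provided as an initializer/diagnostic.

The IR-SE gold-standard fit uses the same variable-projection strategy
with (A, B) solved linearly at each T1 candidate.

## MOLLI forward model

The 5(1)1(1)1 scheme (TIs 100 + k·RR for k = 0..4, then 180 and 260 ms
after re-inversions; RR = 1000 ms; bSSFP readout 35°, TR/TE 2.6/1.05 ms,
72 lines) is time-stepped per TR. Choices, all configurable:

- Inversion is instantaneous with efficiency 0.96 on the free pool — the
  vendor's adiabatic pulse shape is private — and saturates the bound pool.
- The bSSFP block applies an α/2 preparation then phase-alternated ±α
  pulses; the k-space-center (TE) signal at the central TR is recorded.
- Iron: T2* adds echo-time decay and Lorentzian intravoxel dephasing,
  implemented as Cauchy-quantile isochromats of width R2' = 1/T2* − 1/T2.
- Fat: each spectral peak is a parallel pool at its frequency offset,
  summed with weight PDFF.
- Magnetization transfer: a two-pool longitudinal Bloch–McConnell model
  (bound fraction 0.07, exchange 40 s⁻¹, literature-typical liver values)
  with pulsed bound-pool saturation during readout TRs.

Samples are fitted to the three-parameter IR model on the first five TIs
(the single-inversion train) and Look–Locker-corrected:
T1 = T1*(B/A − 1). With readout flip → 0 and perfect inversion the
recovered T1 is exact (< 0.1 %); at protocol settings the model
underestimates (e.g. 822 ms → 641 ms with volunteer-like confounders),
matching the known MOLLI behavior in liver. Because the vendor pulse and
exact MT parameters are unavailable, published forward-simulated values
serve as plausibility anchors, not equality targets.

## ROI statistics

Weights are w = N_pixels/σ² per ROI (inverse squared standard error of the
ROI mean). The subject-level weighted mean/SD use pixel-level sums with
denominator Σ N·w; the ROI-level homogeneity SD uses ROI means with
denominator Σ w — the two printed forms differ and both are implemented
exactly as defined, each verified against independent brute-force
summation to 1e−12 relative. On noiseless synthetic data σ = 0 can occur:
such weights are capped at the 99th percentile of the finite weights (or
all weights become equal if none is finite), with a warning.

The B1+-sensitivity CI uses Student's t with N−2 degrees of freedom (the
statistically standard choice for a two-parameter regression); a printed
variant quoting 2 degrees of freedom can be forced through the `dof`
argument rather than being silently resolved. Repeatability: σ_within is
the residual mean square of a one-way ANOVA with subjects as groups, which
for two runs equals ½·mean((a−b)²) (asserted as an algebraic identity);
RC = 1.96·√2·σ_within. Bland–Altman limits of agreement are reported as
the half-width 1.96·SD of the differences. All tests are two-sided at
α = 0.05.

## Digital phantoms

The vial layout mimics a 14-vial agar T1 phantom (T1 367–1699 ms in ≈100 ms
steps, T2 = 45 ms, no fat); the abdomen layout is an ellipse with uniform
T1 (default 950 ms), optional uniform PDFF, a 2D-Gaussian B1+ depression
reaching its minimum in one corner (emulating the transmit-field pattern
seen across a liver), and a smooth B0 field with optional through-slice
gradient. VFA signals use the EPG simulation per unique (T1, flip) pair;
DAM-EPI signals integrate the Bloch slice profiles with through-slice
dephasing and are forward-distorted along the PE axis so the pipeline's
unwarp step is exercised; noise is seeded complex-Gaussian (Rician on
magnitude). Default geometry is 64×64×6 (tests use 48×48×4) so closed-loop
runs take seconds; the full 320×260×48 acquisition matrix is reachable by
overriding `shape`, at proportionally higher cost.

What passing the synthetic closed loop shows: the pipeline's stages invert
the physics they assume, at realistic noise, fields and spoiling. What it
does not show: robustness to motion between breath-holds, coil-sensitivity
(B1−) variation, eddy currents, partial-volume effects at liver
boundaries, or fat-model mismatch with real tissue — the generator shares
its signal models with the fitting code (slice profiles, fat spectrum), so
model error against real acquisitions is out of scope by construction.

## Known limitations

- Two-echo Dixon cannot separate water and fat at PDFF ≈ 50 % (flagged),
  and residual spectral leakage grows with PDFF; ≥3-echo methods are out
  of scope. In our simulations the residual water-T1 error at PDFF 10 %
  is 0.2–1 % depending on fat model and processing path — smaller than
  the ≈3 % sometimes quoted for this configuration, whose generating
  conditions are not fully specified in the literature we follow.
- The spoiling correction is computed for the water pool only, at a fixed
  assumed T2.
- Phase unwrapping is 2D per slice; heavily wrapped 3D fields at tissue
  boundaries can leak errors into the through-slice B0 gradient and hence
  the B1+ map.
- The MOLLI model's MT and inversion parameters are literature defaults,
  not vendor-calibrated values.
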