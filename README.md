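# livert1

Accurate and precise 3D liver T1 mapping at 3 T from scanner-agnostic
sequences: variable-flip-angle (VFA) spoiled gradient-recalled echo (SPGR)
with two-echo Dixon water/fat separation, double-angle-method (DAM) B1+
mapping with slice-profile and through-slice-B0 corrections, dual-echo B0
mapping with a native EPI unwarp, and an extended-phase-graph (EPG)
correction for incomplete spoiling — plus the statistics needed to validate
such a method (weighted ROI summaries, B1+-sensitivity regression, one-way
ANOVA repeatability coefficient, Bland–Altman agreement) and a Bloch-
simulated MOLLI forward model for comparing VFA T1 against single-slice
MOLLI maps.

It is written for quantitative-MRI researchers who want a tested,
end-to-end reference implementation of this pipeline, exercised on digital
phantoms with known ground truth.

## The method

The ideal-spoiling SPGR steady state is the Ernst equation

    S(α) = M0 · sin α · (1 − E1) / (1 − E1 · cos α),   E1 = exp(−TR/T1).

Sampling S at two or more flip angles (the protocol uses nominal
2°, 2°, 15°, 15° at TR = 4.1 ms) and solving for (T1, M0) by non-linear
least squares gives a 3D T1 map — but only if the *true* flip angles are
known. At 3 T the transmit field varies strongly across the abdomen; in the
small-angle regime the fractional T1 error equals B1+² − 1, so a B1+ factor
of 0.6 produces a −64 % T1 error. The pipeline therefore:

1. maps B0 from a dual-echo GRE phase difference (ΔTE = 2.39 ms) with 2D
   per-slice phase unwrapping;
2. unwarps the GRE-EPI DAM images with a 1-D pixel-shift correction along
   the phase-encode axis (shift = Δf × echo-spacing × PE lines);
3. computes B1+ from the 65°/130° DAM ratio by inverting a Bloch-simulated
   lookup R(b1; Gz) that accounts for the selective pulse's slice profile
   and through-slice B0-gradient dephasing;
4. resamples B1+ to the SPGR grid and multiplies the nominal flip angles;
5. separates water and fat from the 1.23/2.46 ms echoes (two-echo Dixon);
6. fits the water signal with the Ernst model times an EPG-derived
   incomplete-spoiling correction factor c(α, T1) = S_EPG/S_ideal.

A digital-phantom module generates every acquisition the pipeline consumes
(a 14-vial T1 phantom, 367–1699 ms, T2 = 45 ms, and an abdomen-like volume
with smooth B1+/B0 fields and fat), with seeded Rician noise and ground
truth alongside, so the whole chain closes the loop against known answers.

## Worked example

Forward-simulate the MOLLI T1 that a 5(1)1(1)1 acquisition would report
for a liver voxel whose water T1 is 822 ms (PDFF 1.5 %, T2* 14.2 ms):

```
$ livert1 simulate-molli --t1 822 --pdff 0.015 --t2star 14.2
{... "t1_star": 551.4, "t1_ll": 641.5}
```

The apparent (readout-perturbed) T1* of 551 ms is Look–Locker-corrected to
T1 = T1*(B/A − 1) = 641 ms: MOLLI underestimates the true 822 ms because of
readout perturbation, magnetization transfer, T2* and fat — which is why
VFA T1 can only be compared to MOLLI through this forward simulation.

Run the full pipeline on a digital vial phantom:

```
$ livert1 simulate-phantom --out phantom --seed 1
$ cat > cfg.yaml <<EOF
input_dir: phantom
output_dir: out
spoiling_t2: 45.0
EOF
$ livert1 run --config cfg.yaml
{"b0map": {"masked_out": 10878}, "b1map": {"masked_out": 10878},
 "resample": {"masked_out": 10878}, "dixon": {"fat_dominant_flags": 0},
 "fit-t1": {"fitted": 13698, "non_converged": 0}}
```

`out/t1_map.nii.gz` then matches the phantom's ground-truth vial T1s to
within 0.5 % per vial (the masked-out counts are background voxels below
the noise threshold).

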