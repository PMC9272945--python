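# srrmri

Super-resolution reconstruction (SRR) for diffusion MRI from rotated
thick-slice acquisitions, with the accuracy and precision analysis that
motivates it.

Diffusion MRI at high resolution and strong diffusion weighting runs
out of signal: the magnitude of complex Gaussian noise is Rice
distributed, and at low SNR its *rectified noise floor* biases the
signal upward, corrupting exactly the high-b measurements that probe
restricted diffusion. Sampling with thick slices (aspect factor
`α` = through-plane/in-plane voxel size) raises SNR in proportion to
voxel volume; acquiring `N_R ≥ ⌈π/2·α⌉` slice stacks rotated about the
phase-encode axis and solving a regularized linear inverse problem then
recovers the isotropic resolution. This package implements that
pipeline and the analysis machinery around it, validated entirely on
digital phantoms and closed-form limits:

- **Sampling model** — exact (polygon-clipped) linear operators
  `y_k = A_k x` mapping a high-resolution plane to rotated thick-slice
  stacks with a box slice profile.
- **Reconstruction** — the intensity-normalized Tikhonov closed form
  `x̂′ = ((1−λ′)AᵀA + λ′·N_R·α·I)⁻¹ Aᵀy = C y`, with `λ′ ∈ [0, 1]`.
- **Accuracy** — Rician expected magnitude
  `M = √(S² + (σ√(π/2))²)`, the signal-to-noise-floor ratio
  `SNFR = S̄(0)/(σ√(π/2))`, the biased mono-exponential fit, and the
  threshold attenuation `β_thr = log(SNFR·√(f²−1))` bounding the usable
  b-range.
- **Precision** — the noise propagation factor
  `κ = mean_i ‖C_{i,:}‖₂` and the SNR efficiency
  `ρ = (κ_D/κ)·[(1−e^{−TR_SRR/T1})/(1−e^{−TR_D/T1})]·√(TR_D/(N_R·TR_SRR))`,
  including matching of λ′ to Gaussian smoothing kernels for
  equal-effective-resolution comparisons.
- **Dot fractions** — the high-b spherical-encoding estimator
  `f_dot ≈ S(b_high)/S(0)` with its two-compartment forward model.
- **Phantoms** — Shepp-Logan and water-cylinder generators plus
  simulated noisy low-resolution acquisitions.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

How much diffusion weighting can be trusted before the noise floor
bites, as a function of slice thickness (`examples/noise_floor_accuracy.py`):

```
 alpha     snr    snfr  sigma_hat  d_hat  b_thr
     1  72.783  58.073      0.014  2.203  1.329
     2 148.581 118.551      0.013  2.202  1.653
     4 302.532 241.386      0.013  2.200  1.976
     6 452.994 361.437      0.013  2.200  2.160
```

Each row simulates water (S0 = 1, D = 2.2 μm²/ms, σ = 0.014) at one
aspect factor: 10⁴ rectified complex-Gaussian draws per b-value
(0–3 ms/μm² in steps of 0.3), a least-squares fit of the noise-floor-
aware decay model, and the resulting SNR, SNFR and 5%-bias threshold
`b_thr`. SNFR grows linearly with voxel volume, so 6-fold thicker
slices extend the usable b-range from ≈1.33 to ≈2.16 ms/μm² — the
accuracy argument for super-resolution sampling.

Whether the reconstruction also buys *precision*
(`examples/snr_efficiency.py`, matched 0.47-voxel effective resolution):

```
 alpha  n_rotations  lambda_prime  kappa  rho_norelax  rho_t1
     2            4        0.1224 0.4522       1.0943  0.9046
     4            7        0.0267 0.4428       1.1946  0.6775
     8           13        0.0098 0.3522       1.5586  0.5272
```

`rho_norelax` is the SNR efficiency in the long-TR limit: above 1,
thick-slice sampling beats direct sampling at equal scan time and
effective resolution. `rho_t1` repeats the comparison with TR_D = 5 s,
T1 = 1.6 s and the minimal TR_SRR = TR_D/α: incomplete T1 recovery at
short TR flips the gain into a loss at high aspect factors.

Other examples: `examples/reconstruct_phantom.py` (simulate +
reconstruct a water cylinder, report RMSE and κ) and
`examples/dot_fraction.py` (dot-fraction estimation as an upper bound).

A thin CLI wraps the same pipelines for shell use:

```sh
srrmri simulate --phantom cylinder --alpha 3 --grid 64 --out runs/sim
srrmri reconstruct --in runs/sim --lambda-prime 0.02 --out runs/rec
srrmri accuracy --alphas 1,2,4,6 --out runs/acc
srrmri efficiency --alphas 2,4,8 --t1 1.6 --tr-d 5 --out runs/eff
srrmri match-reg --alpha 3 --kernel-sigma 0.47
```

Volumes travel as NIfTI with a JSON geometry sidecar; every run writes
its resolved configuration for auditability.

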