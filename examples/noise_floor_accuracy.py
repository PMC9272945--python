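"""How thick slices extend the usable b-value range.

Simulates the water experiment (S0=1, D=2.2 um^2/ms, sigma=0.014):
rectified complex-Gaussian noise biases the magnitude at high b, and
larger aspect factors push that bias threshold to higher b-values.
"""

from srrmri.pipelines import single_voxel_accuracy

table = single_voxel_accuracy(alphas=(1, 2, 4, 6), n_draws=10_000, seed=0)
print(table[["alpha", "snr", "snfr", "sigma_hat", "d_hat", "b_thr"]]
      .round(3).to_string(index=False))
print()
print("snfr: signal-to-noise-floor ratio, the largest accurately measurable")
print("attenuation factor; b_thr: b-value (ms/um^2) where the noise-floor")
print("bias reaches 5%. Both scale linearly with the aspect factor, so")
print("6-fold thicker slices roughly sextuple SNFR and extend b_thr by ~60%.")
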