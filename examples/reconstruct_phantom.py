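"""Reconstruct a water cylinder from rotated thick-slice stacks.

Builds an aspect-factor-3 protocol (5 rotations), samples the phantom
with Rician noise, solves the regularized inverse problem, and reports
reconstruction error and noise amplification.
"""

import numpy as np

from srrmri import (
    AcquisitionGeometry,
    ReconOperator,
    RicianNoiseModel,
    cylinder_phantom,
    noise_propagation,
    simulate_lowres_acquisition,
)

n, alpha, lam = 64, 3, 0.02
geometry = AcquisitionGeometry.protocol(alpha, n)
phantom = cylinder_phantom(n, radius_fraction=0.6)
acq = simulate_lowres_acquisition(
    phantom, geometry, b_values=[0.0], noise=RicianNoiseModel(sigma=0.014), seed=0)

recon = ReconOperator(acq.sampling, lambda_prime=lam)
image = recon.reconstruct(acq.data[0, 0])
mask = geometry.interior_mask()
rmse = np.sqrt(np.mean((image - phantom.image)[mask] ** 2))
kappa = noise_propagation(recon)

print(f"protocol: alpha={alpha}, N_R={geometry.n_rotations}, lambda'={lam}")
print(f"interior RMSE vs ground truth: {rmse:.4f} (fraction of S0)")
print(f"noise propagation factor kappa: {kappa:.4f}")
print("kappa < 1: the reconstruction is less noisy than one low-res stack;")
print("the RMSE is dominated by ringing at the cylinder's sharp rim.")
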