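"""Does super-resolution sampling buy precision, not just accuracy?

For each aspect factor, the regularization weight is matched to a
0.47-voxel Gaussian kernel (equal effective resolution), the noise
propagation factor computed from the reconstruction operator, and the
SNR efficiency reported with and without T1-relaxation effects.
"""

from srrmri.pipelines import efficiency_sweep

table = efficiency_sweep(
    alphas=(2, 4, 8),
    kernel_sigmas={"moderate": 0.47},
    texture_size=64,
    seed=0,
    t1_seconds=1.6,       # gray matter at 3T
    tr_direct_seconds=5.0,
)
cols = ["alpha", "n_rotations", "lambda_prime", "kappa", "rho_norelax", "rho_t1"]
print(table[cols].round(4).to_string(index=False))
print()
print("rho_norelax > 1: thick-slice sampling beats direct sampling at equal")
print("scan time and effective resolution when TR >> T1. rho_t1 shows the")
print("penalty of incomplete T1 recovery at the minimal TR_SRR = TR_D/alpha:")
print("at high aspect factors the efficiency gain flips into a loss.")
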