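"""How measurement noise and spatial smoothness affect the estimates.

Doubling the measurement-noise standard deviation (variance 1 -> 4) is
absorbed by the noise component: the effect-component posteriors barely
move, because noise is just another covariance component of known shape.
Spatial smoothing, by contrast, cannot bias the estimates but reduces the
effective number of independent voxels (the spatial degrees of freedom), so
credible intervals widen.
"""

import numpy as np

from vrsa import default_hyperprior, fit_vl, reduce_to_second_order
from vrsa.simulate import SimulationConfig, design_components, simulate_dataset

prior = default_hyperprior(4)


def fit_subject(noise_sd, smooth_sd, seed=21):
    cfg = SimulationConfig(n_subjects=1, noise_sd=noise_sd,
                           smooth_sd_voxels=smooth_sd, seed=seed)
    d = simulate_dataset(cfg)[0]
    so = reduce_to_second_order(d, centre_rows=True)
    return fit_vl(so, design_components().with_noise(so.Ce), prior), so


print("Noise doubling (smoothness fixed at 1/8 voxel):")
for sd in (1.0, 2.0):
    fit, so = fit_subject(noise_sd=sd, smooth_sd=0.125)
    v = np.exp(fit.posterior.mean)
    print(f"  noise sd {sd}: effects = {v[0]:.2f}, {v[1]:.2f}; "
          f"noise variance = {v[-1]:.2f}")
print("  -> the noise estimate tracks 1 -> 4; the effects stay put.\n")

print("Smoothing (noise sd fixed at 1):")
for smooth in (0.125, 1.0):
    fit, so = fit_subject(noise_sd=1.0, smooth_sd=smooth)
    sd_eff = np.sqrt(np.diag(fit.posterior.cov))[:2]
    print(f"  kernel sd {smooth} voxels: upsilon = {so.upsilon:5.1f} of 64, "
          f"posterior sd of effect log-scales = {sd_eff[0]:.3f}, {sd_eff[1]:.3f}")
print("  -> smoothing shrinks the spatial degrees of freedom and widens")
print("     the posterior over every effect's contribution.")
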