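"""Rate-distortion: the KL weight beta trades reconstruction for sparsity.

Trains small models across a beta grid on the synthetic fixture and places
each on the reconstruction-sparsity landscape (R^2 from deterministic
rate decoding; sparsity from the sampled spikes).  Higher beta pushes the
population toward more zeros (a cheaper code); at this small scale the
cleaner codes can improve rate-decoded R^2 as well.  The distance-to-optimum
column scores each operating point against the ideal (R^2 = 1 with all-zero
latents).
"""

import numpy as np

from ipvae import LandscapePoint, LatentConfig, SyntheticSpec, evaluate_model, landscape, synth_patches
from ipvae.learning import TrainConfig, fit

ds, phi_star, _ = synth_patches(SyntheticSpec(seed=0, n_patches=6000))
Xtr, Xte = ds.X[:-256], ds.X[-256:]

points = []
for beta in [0.25, 0.5, 1.0, 2.0]:
    latent = LatentConfig(K=16, family="poisson", beta=beta)
    cfg = TrainConfig(T_train=16, beta=beta, epochs=15, batch_size=256,
                      lr=1e-2, eta=0.1, seed=0)
    model = fit(Xtr, latent, cfg)
    _, final = evaluate_model(model, Xte, T_test=200, seed=0, eta=0.1, decode="mean")
    points.append(LandscapePoint(f"beta={beta}", 16, beta, final["r2"], final["sparsity"]))

print(landscape(points).to_string(index=False))
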