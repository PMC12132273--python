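"""Contrast-dependent response latency, a V1-like property.

Drives a grating-tuned model with static gratings of increasing contrast and
reports how many inference steps the population rate needs to reach half of
its final plateau.  Stronger stimuli should be represented sooner (latency
decreasing with contrast), an emergent consequence of the multiplicative
inference dynamics.
"""

import numpy as np

from ipvae import LatentConfig, TrainedModel, contrast_latency, drifting_grating

# dictionary of grating phases: a stand-in for a model trained on gratings
frames = drifting_grating(8, 0.25, 0.1, 1.0, 10)
phi = frames[:5].T / np.linalg.norm(frames[:5].T, axis=0, keepdims=True)
model = TrainedModel(phi=phi, u_init=np.full(5, np.log(0.1)),
                     latent=LatentConfig(K=5, family="poisson", beta=1.0))

spec = {"patch_size": 8, "spatial_freq": 0.25, "temporal_freq": 0.0, "eta": 0.05}
for contrast, latency in contrast_latency(model, [0.0, 0.25, 0.5, 1.0], spec,
                                          T=300, plateau_window=50, seed=0):
    shown = "never reaches threshold" if latency is None else f"{latency} steps"
    print(f"contrast {contrast:4.2f}: latency {shown}")
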