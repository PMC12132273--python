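"""The additive membrane update equals a multiplicative rate update.

One online step in membrane-potential space, exponentiated, coincides exactly
with a divisive-normalization update in firing-rate space: each neuron's rate
is multiplied by its feedforward drive and divided by the pooled, spike-
weighted activity of similarly tuned neurons.  The printed error is float
round-off only.
"""

import numpy as np

from ipvae import (
    DynamicsConfig,
    InferenceState,
    LatentConfig,
    lateral_weights,
    online_step,
    rate_space_step,
)

rng = np.random.default_rng(0)
phi = rng.standard_normal((16, 6)) * 0.4
x = rng.standard_normal(16)
u = rng.uniform(-1, 1, 6)

cfg = LatentConfig(K=6, u_clamp=(-30, 30))
dyn = DynamicsConfig(mode="online", eta=1.0, T=1)
state = InferenceState(0, u.copy(), u.copy())
new = online_step(state, x, phi, cfg, dyn, np.random.default_rng(1))

r_mult = rate_space_step(np.exp(u), x, phi, new.z, dyn)
err = np.max(np.abs(r_mult - np.exp(new.u)) / np.exp(new.u))
print("max relative discrepancy (additive vs multiplicative form):", err)

W = lateral_weights(phi)
print("\nlateral weights W = Phi^T Phi; diagonal (self-suppression strengths):")
print(np.round(np.diag(W), 3))
print("spikes drawn this step:", new.z.astype(int))
print("suppression factor exp(-W z) per neuron:", np.round(np.exp(-W @ new.z), 4))
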