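"""Dictionary learning by backpropagation through the inference trajectory.

Training runs ``T_train`` online (rolling-prior) inference steps per batch
element, accumulates the free energy of every step,

    L = (1/B) sum_b sum_{t=1..T_train} [ 1/2 ||x_b - Phi z_{b,t}||^2
                                         + beta * KL(u_{b,t} || u_{b,t-1}) ],

and applies a single parameter update per batch from the exact gradient of
this unrolled objective with respect to the dictionary ``Phi`` and the
initial (prior) membrane potentials ``u_init``.  The sampling step is
handled by the straight-through surrogate ``z ~ z_detached + (r - r_detached)``,
whose pathwise Jacobian is ``dz/du = diag(r)`` for the Poisson family (the
rate Jacobian), the identity for the Gaussian family, and the rectifier mask
for gaussian_relu.  The backward pass below is the reverse-mode sweep of this
surrogate computation graph, written out by hand.

Also provides the LCA (locally competitive algorithm) sparse-coding baseline,
a deterministic non-spiking precursor of the same dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .generative import LatentConfig

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "unrolled_loss",
    "fit",
    "lca_baseline",
    "AdamState",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    T_train is the number of unrolled inference steps per batch (the
    effective model depth); the loss is the SUM of per-step free energies,
    so beta values comparable across T_train should scale with it.
    """

    T_train: int = 16
    beta: float = 1.0
    epochs: int = 30
    batch_size: int = 128
    lr: float = 1e-2
    eta: float = 1.0
    cosine_decay: bool = True
    normalize_dict: bool = True
    learn_u_init: bool = True
    sample_latents: bool = True  # False -> deterministic mean-field unrolling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T_train < 1 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("T_train, batch_size and epochs must be >= 1")
        if self.beta < 0 or self.lr < 0 or self.eta <= 0:
            raise ValueError("beta/lr must be >= 0 and eta > 0")


@dataclass
class TrainedModel:
    """Learned dictionary, initial potentials, and training history."""

    phi: np.ndarray
    u_init: np.ndarray
    latent: LatentConfig
    history: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return self.phi.shape[0]

    @property
    def K(self) -> int:
        return self.phi.shape[1]

    def save(self, path: str) -> None:
        import json
        from dataclasses import asdict
        from pathlib import Path

        p = Path(path)
        np.savez(p.with_suffix(".npz"), phi=self.phi, u_init=self.u_init,
                 **{f"history_{k}": np.asarray(v) for k, v in self.history.items()})
        p.with_suffix(".json").write_text(json.dumps({"latent": asdict(self.latent)}, indent=2))

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        import json
        from pathlib import Path

        p = Path(path)
        with np.load(p.with_suffix(".npz")) as data:
            phi = data["phi"]
            u_init = data["u_init"]
            history = {k[len("history_"):]: data[k] for k in data.files if k.startswith("history_")}
        meta = json.loads(p.with_suffix(".json").read_text())
        lat = meta["latent"]
        lat["u_clamp"] = tuple(lat["u_clamp"])
        return cls(phi=phi, u_init=u_init, latent=LatentConfig(**lat), history=history)


def _family_draw(u, cfg: LatentConfig, rng, sample: bool):
    """Sample z (or its mean) and the surrogate Jacobian diagonal s = dz/du."""
    if cfg.family == "poisson":
        r = np.exp(u)
        z = rng.poisson(r).astype(float) if sample else r
        return z, r
    if cfg.family == "gaussian":
        z = u + rng.standard_normal(u.shape) if sample else u.copy()
        return z, np.ones_like(u)
    # gaussian_relu: rectify after sampling; gradient passes where pre-activation > 0
    g = u + rng.standard_normal(u.shape) if sample else u
    return np.maximum(0.0, g), (g > 0).astype(float)


def _kl_terms(u, p, cfg: LatentConfig):
    """Per-row KL value and its gradients wrt posterior u and prior p."""
    if cfg.family == "poisson":
        r, r0 = np.exp(u), np.exp(p)
        val = np.sum(r * (u - p) - r + r0, axis=-1)
        return val, r * (u - p), r0 - r
    d = u - p
    return 0.5 * np.sum(d * d, axis=-1), d, -d


def unrolled_loss(
    batch_x: np.ndarray,
    phi: np.ndarray,
    u_init: np.ndarray,
    latent: LatentConfig,
    T_train: int,
    rng: np.random.Generator,
    eta: float = 1.0,
    sample: bool = True,
):
    """Accumulated free energy over T_train online steps, with its gradients.

    Returns ``(loss, parts, grads)`` where ``parts`` has the batch-mean
    "recon" and "kl" components summed over steps and ``grads`` holds
    ``d_phi`` and ``d_u_init`` for the exact unrolled objective (under the
    straight-through sampling surrogate).
    """
    x = np.atleast_2d(np.asarray(batch_x, dtype=float))
    phi = np.asarray(phi, dtype=float)
    B, M = x.shape
    K = phi.shape[1]
    if phi.shape[0] != M:
        raise ValueError(f"batch has M={M} but phi is {phi.shape}")
    lo, hi = latent.u_clamp
    beta = latent.beta
    W = phi.T @ phi
    xphi = x @ phi  # feedforward drive, constant across steps

    # ---- forward sweep, caching per-step states -------------------------
    u_init = np.asarray(u_init, dtype=float)
    u1 = np.clip(u_init, lo, hi)
    mask_init = ((u_init > lo) & (u_init < hi)).astype(float)
    us = [np.broadcast_to(u1, (B, K)).copy()]          # u_t, t = 1..T
    priors = [np.broadcast_to(u1, (B, K)).copy()]      # p_t (p_1 = u_init)
    zs, ss, es, masks = [], [], [], []
    recon_sum = np.zeros(B)
    kl_sum = np.zeros(B)
    for t in range(T_train):
        u = us[-1]
        z, s = _family_draw(u, latent, rng, sample)
        e = x - z @ phi.T
        kl_val, _, _ = _kl_terms(u, priors[-1], latent)
        recon_sum += 0.5 * np.sum(e * e, axis=-1)
        kl_sum += kl_val
        zs.append(z)
        ss.append(s)
        es.append(e)
        if t < T_train - 1:
            pre = u + eta * (xphi - z @ W)
            if not np.all(np.isfinite(pre)):
                raise FloatingPointError(f"non-finite potentials at unroll step {t + 1}")
            masks.append(((pre > lo) & (pre < hi)).astype(float))
            us.append(np.clip(pre, lo, hi))
            priors.append(u.copy())

    loss = float(np.mean(recon_sum + beta * kl_sum))
    parts = {"recon": float(np.mean(recon_sum)), "kl": float(np.mean(kl_sum))}

    # ---- reverse sweep --------------------------------------------------
    d_phi = np.zeros_like(phi)
    g_next = np.zeros((B, K))  # dL/du_{t+1} (unnormalized by B)
    for t in reversed(range(T_train)):
        u, z, s, e = us[t], zs[t], ss[t], es[t]
        _, dkl_du, _ = _kl_terms(u, priors[t], latent)
        if t < T_train - 1:
            a = masks[t] * g_next                       # through the clip
            _, _, dkl_dp = _kl_terms(us[t + 1], u, latent)
        else:
            a = np.zeros((B, K))
            dkl_dp = 0.0
        dz = -e @ phi - eta * a @ W
        g = s * dz + beta * dkl_du + beta * dkl_dp + a
        # dictionary gradient: reconstruction at step t + drive into step t+1
        d_phi += -e.T @ z + eta * (e.T @ a - phi @ (a.T @ z))
        g_next = g

    d_u_init = mask_init * np.sum(g_next, axis=0) / B
    d_phi /= B
    return loss, parts, {"d_phi": d_phi, "d_u_init": d_u_init}


@dataclass
class AdamState:
    """Adaptive-moment gradient descent (standard bias-corrected form)."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def like(cls, param: np.ndarray) -> "AdamState":
        return cls(m=np.zeros_like(param), v=np.zeros_like(param))

    def step(self, param, grad, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.t += 1
        self.m = beta1 * self.m + (1 - beta1) * grad
        self.v = beta2 * self.v + (1 - beta2) * grad * grad
        mhat = self.m / (1 - beta1**self.t)
        vhat = self.v / (1 - beta2**self.t)
        return param - lr * mhat / (np.sqrt(vhat) + eps)


def fit(
    dataset: np.ndarray,
    latent: LatentConfig,
    cfg: TrainConfig,
    phi_init: np.ndarray | None = None,
) -> TrainedModel:
    """Learn the dictionary (and u_init) on a patch dataset.

    One Adam update per batch from :func:`unrolled_loss`; dictionary columns
    re-normalized to unit norm after every update when ``normalize_dict`` is
    set (keeps W_ii = 1 and makes beta comparable across runs).  Deterministic
    given ``cfg.seed``.
    """
    X = np.asarray(dataset, dtype=float)
    n, M = X.shape
    rng = np.random.default_rng(cfg.seed)
    if phi_init is None:
        phi = rng.standard_normal((M, latent.K))
        phi /= np.linalg.norm(phi, axis=0, keepdims=True)
    else:
        phi = np.array(phi_init, dtype=float)
    u_init = np.full(latent.K, np.log(0.5))  # r ~ 0.5 spikes/step at rest

    adam_phi = AdamState.like(phi)
    adam_u = AdamState.like(u_init)
    n_batches = max(1, n // cfg.batch_size)
    total_updates = cfg.epochs * n_batches
    history = {"loss": [], "recon": [], "kl": []}

    upd = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep = {"loss": 0.0, "recon": 0.0, "kl": 0.0}
        for b in range(n_batches):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            loss, parts, grads = unrolled_loss(
                X[idx], phi, u_init, latent, cfg.T_train, rng,
                eta=cfg.eta, sample=cfg.sample_latents,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}, batch {b}")
            lr = cfg.lr
            if cfg.cosine_decay:
                lr = cfg.lr * 0.5 * (1 + np.cos(np.pi * upd / max(1, total_updates)))
            d_phi = grads["d_phi"]
            if cfg.normalize_dict:
                # optimize on the product of unit spheres: remove the radial
                # component per column before the adaptive step, then retract.
                # Keeps the stochastic variance-penalty pull (radial by
                # construction) from being rotated into the tangent space by
                # Adam's per-coordinate rescaling.
                d_phi = d_phi - phi * np.sum(phi * d_phi, axis=0, keepdims=True)
            phi = adam_phi.step(phi, d_phi, lr)
            if cfg.normalize_dict:
                phi /= np.maximum(np.linalg.norm(phi, axis=0, keepdims=True), 1e-12)
            if cfg.learn_u_init:
                u_init = adam_u.step(u_init, grads["d_u_init"], lr)
            upd += 1
            ep["loss"] += loss
            ep["recon"] += parts["recon"]
            ep["kl"] += parts["kl"]
        for k in history:
            history[k].append(ep[k] / n_batches)

    return TrainedModel(phi=phi, u_init=u_init, latent=latent, history=history)


def soft_threshold(m: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise soft threshold: sign(m) * max(|m| - lam, 0)."""
    return np.sign(m) * np.maximum(np.abs(m) - lam, 0.0)


def lca_baseline(
    x: np.ndarray,
    phi: np.ndarray,
    lambda_thresh: float,
    T: int = 500,
    eta: float = 0.1,
):
    """Locally competitive algorithm: deterministic sparse-coding dynamics.

    Membrane update ``m <- m + eta [ Phi^T x - (Phi^T Phi - I) s - m ]`` with
    the code ``s = soft_threshold(m, lambda)``.  Returns the final code and
    its reconstruction ``Phi s``.
    """
    if lambda_thresh < 0:
        raise ValueError("lambda_thresh must be >= 0")
    x = np.asarray(x, dtype=float)
    phi = np.asarray(phi, dtype=float)
    W = phi.T @ phi
    b = x @ phi
    m = np.zeros(b.shape)
    for t in range(T):
        s = soft_threshold(m, lambda_thresh)
        m = m + eta * (b - s @ (W - np.eye(W.shape[0])) - m)
        if not np.all(np.isfinite(m)):
            raise FloatingPointError(f"LCA diverged at step {t + 1}")
    s = soft_threshold(m, lambda_thresh)
    return s, s @ phi.T
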