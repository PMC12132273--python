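"""Membrane-potential inference dynamics.

Two discrete-time update rules, both derived from natural gradient descent on
variational free energy with Fisher preconditioning (the elementwise ``e^u``
factor cancels against the inverse Fisher, leaving the bracketed drive):

* static-prior step (prior ``u0`` fixed throughout inference):

      u <- clamp( u + eta * [ Phi^T x - Phi^T Phi z - beta (u - u0) ] )

* online step (rolling prior: each step's posterior becomes the next prior;
  the KL leak term vanishes in the single-update-per-time-point limit):

      u_{t+1} = clamp( u_t + eta * [ Phi^T x - Phi^T Phi z_t ] ),   u0 <- u_t

The online update has an exactly equivalent multiplicative form in rate space
(for eta = 1), exhibiting divisive normalization through the lateral weights
W = Phi^T Phi: co-active neurons suppress each other proportionally to their
spike output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .generative import (
    FreeEnergyBreakdown,
    LatentConfig,
    clamp_potentials,
    free_energy,
    kl_divergence,
    posterior_mean,
    reconstruction_term,
    sample_posterior,
)

__all__ = [
    "DynamicsConfig",
    "InferenceState",
    "InferenceTrace",
    "lateral_weights",
    "static_prior_step",
    "online_step",
    "rate_space_step",
    "run_inference",
]

# optional test hook: a sampler(mean, family, rng) -> z replacing the posterior draw
Sampler = Callable[[np.ndarray, str, np.random.Generator], np.ndarray]


@dataclass(frozen=True)
class DynamicsConfig:
    """Inference-dynamics settings.

    eta is the Euler step size (the discrete update is printed with an
    implicit eta = 1; smaller values help when ||Phi^T x|| is large).
    T is the number of iterations; record_every=0 records the final state only.
    """

    mode: Literal["static_prior", "online"] = "online"
    eta: float = 1.0
    T: int = 1000
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("static_prior", "online"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.eta <= 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if self.record_every < 0:
            raise ValueError("record_every must be >= 0")


@dataclass
class InferenceState:
    """Current posterior/prior potentials and the most recent spike draw."""

    t: int
    u: np.ndarray
    u0: np.ndarray
    z: np.ndarray | None = None


@dataclass
class InferenceTrace:
    """Per-step record of an inference run.

    Arrays are stacked along the first axis (one row per recorded step).
    ``update_norms`` holds ||u_{t+1} - u_t|| / eta, the discrete proxy for
    the natural-gradient norm ||G^{-1} grad_u F||.
    """

    steps: np.ndarray
    u: np.ndarray
    z: np.ndarray
    r: np.ndarray
    recon: np.ndarray
    kl: np.ndarray
    total: np.ndarray
    update_norms: np.ndarray
    meta: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        """Serialize arrays to ``<path>.npz`` plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        p = Path(path)
        np.savez(
            p.with_suffix(".npz"),
            steps=self.steps,
            u=self.u,
            z=self.z,
            r=self.r,
            recon=self.recon,
            kl=self.kl,
            total=self.total,
            update_norms=self.update_norms,
        )
        p.with_suffix(".json").write_text(json.dumps(self.meta, indent=2))


def lateral_weights(phi: np.ndarray) -> np.ndarray:
    """Recurrent/lateral connectivity W = Phi^T Phi (symmetric PSD).

    Diagonal entries are the squared column norms, so strongly spiking
    neurons self-suppress; off-diagonals couple similarly tuned neurons.
    """
    phi = np.asarray(phi, dtype=float)
    W = phi.T @ phi
    return 0.5 * (W + W.T)  # exact symmetry despite float round-off


def _draw(mean, family, rng, sampler: Sampler | None):
    if sampler is not None:
        return np.asarray(sampler(mean, family, rng), dtype=float)
    return sample_posterior(mean, family, rng)


def static_prior_step(
    state: InferenceState,
    x: np.ndarray,
    phi: np.ndarray,
    cfg: LatentConfig,
    dyncfg: DynamicsConfig,
    rng: np.random.Generator,
    sampler: Sampler | None = None,
) -> InferenceState:
    """One natural-gradient step with a fixed prior (homeostatic leak active)."""
    u, u0 = state.u, state.u0
    z = _draw(posterior_mean(u, cfg), cfg.family, rng, sampler)
    drive = x @ phi - z @ (phi.T @ phi) - cfg.beta * (u - u0)
    u_new = clamp_potentials(u + dyncfg.eta * drive, cfg)
    return InferenceState(t=state.t + 1, u=u_new, u0=u0, z=z)


def online_step(
    state: InferenceState,
    x: np.ndarray,
    phi: np.ndarray,
    cfg: LatentConfig,
    dyncfg: DynamicsConfig,
    rng: np.random.Generator,
    sampler: Sampler | None = None,
) -> InferenceState:
    """One rolling-prior step: u_{t+1} = u_t + eta [Phi^T x - W z_t].

    The returned state's prior is the old posterior (each step's posterior
    becomes the next step's prior), and no leak term appears.
    """
    u = state.u
    z = _draw(posterior_mean(u, cfg), cfg.family, rng, sampler)
    drive = x @ phi - z @ (phi.T @ phi)
    u_new = clamp_potentials(u + dyncfg.eta * drive, cfg)
    return InferenceState(t=state.t + 1, u=u_new, u0=u.copy(), z=z)


def rate_space_step(
    r_t: np.ndarray,
    x: np.ndarray,
    phi: np.ndarray,
    z_t: np.ndarray,
    dyncfg: DynamicsConfig,
) -> np.ndarray:
    """Multiplicative (divisive-normalization) form of the online update.

    r_{t+1,i} = r_{t,i} * exp([Phi^T x]_i) / ( exp(W_ii z_i) * prod_{j!=i} exp(W_ij z_j) )

    Algebraically identical to exponentiating the potential update; only
    defined for the unit step size eta = 1.  No clamping is applied here —
    this is the raw algebraic form.
    """
    if dyncfg.eta != 1.0:
        raise ValueError("rate_space_step is derived for eta = 1 only")
    r_t = np.asarray(r_t, dtype=float)
    W = lateral_weights(phi)
    drive = np.exp(x @ phi)
    suppression = np.exp(np.asarray(z_t, dtype=float) @ W)
    return r_t * drive / suppression


def run_inference(
    x: np.ndarray,
    phi: np.ndarray,
    cfg: LatentConfig,
    dyncfg: DynamicsConfig,
    rng: np.random.Generator,
    u_init: np.ndarray | None = None,
    sampler: Sampler | None = None,
) -> InferenceTrace:
    """Iterate the configured step T times from u = u0 = u_init.

    ``x`` may be a single input (shape ``(M,)`` or ``(B, M)``) held fixed
    across steps, or a per-step stimulus sequence of shape ``(T, M)`` (e.g.
    drifting-grating frames), in which case frame t drives step t.

    Raises a FloatingPointError naming the step index if potentials become
    non-finite (divergence guard: instability should surface, not be hidden).
    """
    phi = np.asarray(phi, dtype=float)
    M, K = phi.shape
    x = np.asarray(x, dtype=float)
    sequence = x.ndim == 2 and x.shape == (dyncfg.T, M)
    if u_init is None:
        u_init = np.full(K, np.log(0.5))
    u = clamp_potentials(np.asarray(u_init, dtype=float), cfg)
    if x.ndim == 2 and not sequence and u.ndim == 1:
        u = np.broadcast_to(u, (x.shape[0], K)).copy()  # batched inputs
    state = InferenceState(t=0, u=u, u0=u.copy())

    step = online_step if dyncfg.mode == "online" else static_prior_step
    rec: dict[str, list] = {k: [] for k in ("steps", "u", "z", "r", "recon", "kl", "total", "norm")}

    for t in range(dyncfg.T):
        x_t = x[t] if sequence else x
        prev_u = state.u
        state = step(state, x_t, phi, cfg, dyncfg, rng, sampler=sampler)
        if not np.all(np.isfinite(state.u)):
            raise FloatingPointError(f"non-finite membrane potentials at step {t + 1}")
        last = t == dyncfg.T - 1
        if last or (dyncfg.record_every and (t + 1) % dyncfg.record_every == 0):
            r = posterior_mean(state.u, cfg)
            recon = reconstruction_term(x_t, phi, state.z)
            kl = kl_divergence(state.u, state.u0, cfg)
            rec["steps"].append(t + 1)
            rec["u"].append(state.u.copy())
            rec["z"].append(state.z.copy())
            rec["r"].append(r)
            rec["recon"].append(recon)
            rec["kl"].append(kl)
            rec["total"].append(recon + cfg.beta * kl)
            rec["norm"].append(float(np.linalg.norm(state.u - prev_u) / dyncfg.eta))

    return InferenceTrace(
        steps=np.asarray(rec["steps"]),
        u=np.stack(rec["u"]),
        z=np.stack(rec["z"]),
        r=np.stack(rec["r"]),
        recon=np.asarray(rec["recon"]),
        kl=np.asarray(rec["kl"]),
        total=np.asarray(rec["total"]),
        update_norms=np.asarray(rec["norm"]),
        meta={"mode": dyncfg.mode, "eta": dyncfg.eta, "T": dyncfg.T,
              "family": cfg.family, "beta": cfg.beta, "K": cfg.K},
    )
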