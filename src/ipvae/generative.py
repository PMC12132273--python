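"""Latent families, free-energy terms, gradients, and the Fisher preconditioner.

The generative model is a linear-Gaussian likelihood ``p(x|z) = N(Phi z, I)``
over image patches ``x`` (flat pixel vectors of length M), with a K-dimensional
latent spike count ``z``.  The variational posterior is parameterized by
real-valued membrane potentials ``u``:

* ``poisson``       -- q(z) = Poisson(r) with firing rates r = exp(u); z is a
                       non-negative integer spike count.
* ``gaussian``      -- q(z) = N(u, I); z is real-valued.
* ``gaussian_relu`` -- z = max(0, g) with g ~ N(u, I); z has an atom at zero.

Variational free energy (negative ELBO) for a single Monte-Carlo sample:

    F(x; Phi, u0, u) = 1/2 ||x - Phi z||^2 + beta * KL(q_u || p_{u0})

with the Poisson KL given in closed form by
``sum_i [ e^{u_i} (u_i - u0_i) - e^{u_i} + e^{u0_i} ]`` and the Gaussian KL by
``1/2 ||u - u0||^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "LatentConfig",
    "FreeEnergyBreakdown",
    "rates_from_potentials",
    "sample_posterior",
    "posterior_mean",
    "poisson_kl",
    "gaussian_kl",
    "kl_divergence",
    "reconstruction_term",
    "free_energy",
    "fisher_preconditioner",
    "free_energy_gradient",
]

Family = Literal["poisson", "gaussian", "gaussian_relu"]
_FAMILIES = ("poisson", "gaussian", "gaussian_relu")


@dataclass(frozen=True)
class LatentConfig:
    """Configuration of the latent family.

    Parameters
    ----------
    K : int
        Latent dimensionality (number of neurons).
    family : {"poisson", "gaussian", "gaussian_relu"}
        Posterior/prior family.
    beta : float
        Non-negative KL weight (rate-distortion trade-off).
    u_clamp : (float, float)
        Bounds applied to membrane potentials before exponentiation; the
        default ``(-8, 8)`` caps rates at ``e^8 ~ 2981`` spikes per step,
        far beyond physiological range, and prevents overflow.
    """

    K: int
    family: Family = "poisson"
    beta: float = 1.0
    u_clamp: tuple[float, float] = (-8.0, 8.0)

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        lo, hi = self.u_clamp
        if not lo < hi:
            raise ValueError(f"u_clamp must satisfy lo < hi, got {self.u_clamp}")


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """Single-sample free energy split into its two terms.

    ``total = recon + beta * kl``; ``z`` is the latent sample that produced
    the reconstruction term (kept for trace recording).
    """

    recon: float
    kl: float
    beta: float
    total: float
    z: np.ndarray = field(repr=False, default=None)


def _check_finite(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    return a


def clamp_potentials(u: np.ndarray, cfg: LatentConfig) -> np.ndarray:
    """Clip membrane potentials to the configured bounds."""
    lo, hi = cfg.u_clamp
    return np.clip(np.asarray(u, dtype=float), lo, hi)


def rates_from_potentials(u: np.ndarray, cfg: LatentConfig) -> np.ndarray:
    """Firing rates r = exp(clamp(u)); strictly positive."""
    u = _check_finite(u, "u")
    return np.exp(clamp_potentials(u, cfg))


def sample_posterior(
    r: np.ndarray,
    family: Family,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one latent sample from the posterior.

    ``r`` is the posterior parameter on its natural scale: the Poisson rate
    for the Poisson family, the mean ``u`` for the Gaussian families.
    Gaussian draws have unit variance; ``gaussian_relu`` rectifies after
    sampling, so exact zeros occur with positive probability.
    """
    r = np.asarray(r, dtype=float)
    if family == "poisson":
        if np.any(r <= 0):
            raise ValueError("Poisson rates must be strictly positive")
        return rng.poisson(r).astype(float)
    if family == "gaussian":
        return r + rng.standard_normal(r.shape)
    if family == "gaussian_relu":
        return np.maximum(0.0, r + rng.standard_normal(r.shape))
    raise ValueError(f"unknown family {family!r}; expected one of {_FAMILIES}")


def posterior_mean(u: np.ndarray, cfg: LatentConfig) -> np.ndarray:
    """Posterior mean of z: exp(u) for Poisson, u for Gaussian families.

    For ``gaussian_relu`` we return the pre-rectification mean ``u`` (the
    dynamics and gradients are defined on the Gaussian variable; rectification
    is applied to samples only).
    """
    if cfg.family == "poisson":
        return rates_from_potentials(u, cfg)
    return clamp_potentials(u, cfg)


def poisson_kl(u: np.ndarray, u0: np.ndarray) -> float:
    """KL( Poisson(e^u) || Poisson(e^{u0}) ), summed over units.

    Closed form: ``sum_i e^{u_i}(u_i - u0_i) - e^{u_i} + e^{u0_i}``.
    Non-negative, zero iff u == u0.
    """
    u = np.asarray(u, dtype=float)
    u0 = np.asarray(u0, dtype=float)
    if u.shape != u0.shape:
        raise ValueError(f"shape mismatch: u {u.shape} vs u0 {u0.shape}")
    r, r0 = np.exp(u), np.exp(u0)
    return float(np.sum(r * (u - u0) - r + r0))


def gaussian_kl(u: np.ndarray, u0: np.ndarray) -> float:
    """KL( N(u, I) || N(u0, I) ) = 0.5 * ||u - u0||^2."""
    u = np.asarray(u, dtype=float)
    u0 = np.asarray(u0, dtype=float)
    if u.shape != u0.shape:
        raise ValueError(f"shape mismatch: u {u.shape} vs u0 {u0.shape}")
    return float(0.5 * np.sum((u - u0) ** 2))


def kl_divergence(u: np.ndarray, u0: np.ndarray, cfg: LatentConfig) -> float:
    """Family-dispatching posterior-prior KL."""
    if cfg.family == "poisson":
        return poisson_kl(u, u0)
    return gaussian_kl(u, u0)


def reconstruction_term(x: np.ndarray, phi: np.ndarray, z: np.ndarray) -> float:
    """Single-sample reconstruction term 1/2 ||x - Phi z||^2."""
    x = np.asarray(x, dtype=float)
    phi = np.asarray(phi, dtype=float)
    z = np.asarray(z, dtype=float)
    if phi.ndim != 2:
        raise ValueError("phi must be a 2-D dictionary (M x K)")
    if x.shape[-1] != phi.shape[0] or z.shape[-1] != phi.shape[1]:
        raise ValueError(
            f"dimension mismatch: x has M={x.shape[-1]}, z has K={z.shape[-1]}, "
            f"phi is {phi.shape[0]}x{phi.shape[1]}"
        )
    resid = x - z @ phi.T
    return float(0.5 * np.sum(resid**2))


def free_energy(
    x: np.ndarray,
    phi: np.ndarray,
    u: np.ndarray,
    u0: np.ndarray,
    cfg: LatentConfig,
    rng: np.random.Generator,
) -> FreeEnergyBreakdown:
    """Single-sample variational free energy ``recon + beta * kl``.

    Draws one z from the posterior at ``u`` and returns the breakdown
    together with that z.
    """
    u = clamp_potentials(u, cfg)
    u0 = clamp_potentials(u0, cfg)
    mean = posterior_mean(u, cfg)
    z = sample_posterior(mean, cfg.family, rng)
    recon = reconstruction_term(x, phi, z)
    kl = kl_divergence(u, u0, cfg)
    return FreeEnergyBreakdown(
        recon=recon, kl=kl, beta=cfg.beta, total=recon + cfg.beta * kl, z=z
    )


def fisher_preconditioner(u: np.ndarray, cfg: LatentConfig) -> np.ndarray:
    """Diagonal of the Fisher information matrix of the posterior.

    Poisson in canonical (log-rate) form: G(u) = diag(exp(u)).  Gaussian
    families with unit variance: the identity.
    """
    u = _check_finite(u, "u")
    if cfg.family == "poisson":
        return np.exp(clamp_potentials(u, cfg))
    return np.ones_like(np.asarray(u, dtype=float))


def free_energy_gradient(
    x: np.ndarray,
    phi: np.ndarray,
    u: np.ndarray,
    u0: np.ndarray,
    z: np.ndarray,
    cfg: LatentConfig,
) -> np.ndarray:
    """Straight-through gradient of F with respect to u at the drawn z.

    Poisson: ``e^u ⊙ [ -Phi^T (x - Phi z) + beta (u - u0) ]`` — the sampling
    step is treated as identity (dz/dr = I) and the rate Jacobian dr/du = e^u
    appears as an elementwise factor.  Gaussian families: the same bracket
    without the e^u factor (dz/du = I, unit-variance KL).
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    u0 = np.asarray(u0, dtype=float)
    z = np.asarray(z, dtype=float)
    if u.shape != u0.shape or z.shape[-1] != u.shape[-1]:
        raise ValueError("u, u0 and z must share the latent dimension K")
    if x.shape[-1] != phi.shape[0] or u.shape[-1] != phi.shape[1]:
        raise ValueError("x/u dimensions inconsistent with phi")
    bracket = -(x - z @ phi.T) @ phi + cfg.beta * (u - u0)
    if cfg.family == "poisson":
        return np.exp(clamp_potentials(u, cfg)) * bracket
    return bracket
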