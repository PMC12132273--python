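"""Evaluation metrics and analyses.

Reconstruction fidelity is measured by the coefficient of determination R^2
between a patch and its reconstruction ``Phi z``; coding cost by the
proportion of exact zeros in the sampled latents (a hardware-relevant proxy
for spike sparsity); proximity to the inference attractor by the norm of the
applied membrane-potential update.  Models are placed on the
reconstruction-sparsity landscape and scored by their Euclidean distance to
the unachievable optimum (R^2 = 1, sparsity = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .dynamics import DynamicsConfig, run_inference
from .generative import LatentConfig

__all__ = [
    "r2_reconstruction",
    "sparsity_fraction",
    "update_norm",
    "convergence_time",
    "LandscapePoint",
    "distance_to_optimum",
    "landscape",
    "dictionary_recovery_score",
    "evaluate_model",
    "contrast_latency",
]


def r2_reconstruction(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (SS_tot about mean x).

    Returns 1.0 for a perfect reconstruction, 0.0 for predicting the mean,
    and can be negative for worse-than-mean reconstructions.  Raises on a
    constant input (SS_tot = 0), where the metric is undefined.
    """
    x = np.asarray(x, dtype=float).ravel()
    x_hat = np.asarray(x_hat, dtype=float).ravel()
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for a constant input (zero total variance)")
    ss_res = float(np.sum((x - x_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def sparsity_fraction(z: np.ndarray) -> float:
    """Fraction of latent entries exactly equal to zero."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z contains non-finite entries")
    return float(np.mean(z == 0))


def update_norm(u_trace: np.ndarray, eta: float = 1.0) -> np.ndarray:
    """Per-step Euclidean norm of the applied update, ||u_{t+1} - u_t|| / eta.

    The discrete proxy for the natural-gradient norm ||G^{-1} grad_u F||.
    Input is the stacked potentials (T, K) including the initial state.
    """
    u_trace = np.asarray(u_trace, dtype=float)
    return np.linalg.norm(np.diff(u_trace, axis=0), axis=-1) / eta


def convergence_time(
    r2_trace: np.ndarray,
    window: int = 50,
    tol: float = 1e-3,
    smooth: int = 1,
) -> int | None:
    """First step after which the (smoothed) R^2 trace stays flat for good.

    Returns the smallest t such that every window [t', t'+window] with
    t' >= t has range (max - min) below tol; ``None`` if the trace never
    stabilizes.  ``smooth`` > 1 applies a centered moving average first.
    """
    r2 = np.asarray(r2_trace, dtype=float)
    if r2.size < 2 * window:
        raise ValueError(f"trace of length {r2.size} too short for window {window}")
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        r2 = np.convolve(r2, kernel, mode="valid")
    n = r2.size - window
    # rolling range over [t, t+window], then require it stays < tol for all later t
    from numpy.lib.stride_tricks import sliding_window_view

    wins = sliding_window_view(r2, window + 1)
    ranges = wins.max(axis=1) - wins.min(axis=1)
    ok = ranges < tol
    # suffix-and: flat from t onwards
    flat_from = np.flip(np.logical_and.accumulate(np.flip(ok)))
    idx = np.nonzero(flat_from)[0]
    if idx.size == 0:
        return None
    return int(idx[0])


@dataclass(frozen=True)
class LandscapePoint:
    """A model's operating point on the reconstruction-sparsity plane."""

    model_id: str
    T_train: int
    beta: float
    r2: float
    sparsity: float

    @property
    def distance(self) -> float:
        return distance_to_optimum(self.r2, self.sparsity)


def distance_to_optimum(r2: float, sparsity: float) -> float:
    """Euclidean distance to the ideal point (R^2 = 1, sparsity = 1).

    Negative R^2 values are clipped to 0 (with a warning) so the distance
    stays on the unit square.
    """
    if r2 < 0:
        warnings.warn("negative R^2 clipped to 0 for the landscape", stacklevel=2)
        r2 = 0.0
    if not 0 <= sparsity <= 1:
        raise ValueError(f"sparsity must lie in [0, 1], got {sparsity}")
    return float(np.hypot(1.0 - r2, 1.0 - sparsity))


def landscape(points: list[LandscapePoint]) -> pd.DataFrame:
    """Sorted table of landscape points (best, i.e. smallest distance, first)."""
    rows = [
        {
            "model_id": p.model_id,
            "T_train": p.T_train,
            "beta": p.beta,
            "r2": p.r2,
            "sparsity": p.sparsity,
            "distance_to_optimum": p.distance,
        }
        for p in points
    ]
    return pd.DataFrame(rows).sort_values("distance_to_optimum").reset_index(drop=True)


def plot_landscape(table: pd.DataFrame, path: str | None = None):
    """Scatter models on the reconstruction-sparsity plane.

    The ideal operating point (R^2 = 1, sparsity = 1) is marked with a gold
    star; smaller distance to it is better.  ``table`` is the output of
    :func:`landscape`.  Saves to ``path`` (SVG/PNG by extension) if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    r2 = table["r2"].clip(lower=0)
    ax.scatter(table["sparsity"], r2, c=table["distance_to_optimum"],
               cmap="viridis_r", s=60, edgecolor="k", linewidth=0.5)
    for _, row in table.iterrows():
        ax.annotate(str(row["model_id"]), (row["sparsity"], max(row["r2"], 0)),
                    fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.plot(1.0, 1.0, marker="*", color="gold", markersize=18,
            markeredgecolor="k", zorder=5)
    ax.set_xlim(-0.05, 1.1)
    ax.set_ylim(-0.05, 1.1)
    ax.set_xlabel("sparsity (fraction of zero spikes)")
    ax.set_ylabel(r"reconstruction $R^2$")
    ax.set_title("reconstruction-sparsity landscape")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def dictionary_recovery_score(phi_hat: np.ndarray, phi_star: np.ndarray) -> float:
    """Mean best-match |cosine| between learned and true dictionary columns.

    Columns are matched one-to-one by the Hungarian algorithm maximizing the
    total absolute cosine similarity, so the score is invariant to column
    permutation and sign flips.  1.0 means perfect recovery; random unit
    vectors in high dimension score near E|cos| ~ sqrt(2 / (pi M)).
    """
    phi_hat = np.asarray(phi_hat, dtype=float)
    phi_star = np.asarray(phi_star, dtype=float)
    if phi_hat.shape[0] != phi_star.shape[0]:
        raise ValueError("dictionaries must share the pixel dimension M")
    if phi_hat.shape[1] < phi_star.shape[1]:
        raise ValueError(
            f"need K_hat >= K_true, got {phi_hat.shape[1]} < {phi_star.shape[1]}"
        )
    a = phi_hat / np.maximum(np.linalg.norm(phi_hat, axis=0, keepdims=True), 1e-12)
    b = phi_star / np.maximum(np.linalg.norm(phi_star, axis=0, keepdims=True), 1e-12)
    sim = np.abs(a.T @ b)  # (K_hat, K_true)
    rows, cols = linear_sum_assignment(-sim)
    return float(sim[rows, cols].mean())


def evaluate_model(
    model,
    X_test: np.ndarray,
    T_test: int = 1000,
    seed: int = 0,
    record_every: int = 1,
    eta: float = 1.0,
    decode: str = "sample",
):
    """Run T_test-step online inference on a test batch and trace the metrics.

    Returns a DataFrame with per-recorded-step mean R^2 (per patch, then
    averaged), sparsity fraction, and mean update norm, plus the final-state
    summary dict.  ``decode="sample"`` reconstructs from the drawn spikes
    (the stochastic representation); ``decode="mean"`` reconstructs from the
    posterior rates (deterministic/MAP-style decoding, useful at small patch
    scale where single-sample spike noise dominates the pixel variance).
    Sparsity is always measured on the sampled spikes.  Patches with
    (near-)zero variance are skipped in the R^2 average.
    """
    if decode not in ("sample", "mean"):
        raise ValueError(f"unknown decode mode {decode!r}")
    X = np.atleast_2d(np.asarray(X_test, dtype=float))
    rng = np.random.default_rng(seed)
    dyncfg = DynamicsConfig(mode="online", eta=eta, T=T_test, record_every=record_every)
    trace = run_inference(X, model.phi, model.latent, dyncfg, rng, u_init=model.u_init)

    ss_tot = np.sum((X - X.mean(axis=1, keepdims=True)) ** 2, axis=1)
    valid = ss_tot > 1e-12 * X.shape[1]
    rows = []
    for i, step in enumerate(trace.steps):
        z = trace.z[i]  # (B, K)
        code = z if decode == "sample" else trace.r[i]
        xh = code @ model.phi.T
        ss_res = np.sum((X - xh) ** 2, axis=1)
        r2s = 1.0 - ss_res[valid] / ss_tot[valid]
        rows.append(
            {
                "step": int(step),
                "r2": float(np.mean(r2s)),
                "sparsity": sparsity_fraction(z),
                "update_norm": float(np.mean(np.linalg.norm(trace.u[i] - (trace.u[i - 1] if i else np.broadcast_to(model.u_init, trace.u[i].shape)), axis=-1)) / eta) if record_every == 1 else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    final = {
        "r2": df["r2"].iloc[-1],
        "sparsity": df["sparsity"].iloc[-1],
        "T_test": T_test,
    }
    return df, final


def contrast_latency(
    model,
    contrasts,
    grating_spec: dict,
    T: int = 200,
    threshold_frac: float = 0.5,
    plateau_window: int = 20,
    seed: int = 0,
):
    """Population response latency as a function of stimulus contrast.

    For each contrast, drives the model with a drifting-grating frame
    sequence and finds the first step at which the population rate (summed
    posterior rates) exceeds ``threshold_frac`` of its final plateau (mean
    over the last ``plateau_window`` steps, after subtracting the baseline
    rate at step 1).  Returns a list of (contrast, latency-or-None) pairs;
    ``None`` flags a contrast that never reaches the threshold.
    """
    from .datasets import drifting_grating

    results = []
    for c in contrasts:
        frames = drifting_grating(
            patch_size=grating_spec["patch_size"],
            spatial_freq=grating_spec["spatial_freq"],
            temporal_freq=grating_spec["temporal_freq"],
            contrast=float(c),
            T=T,
        )
        rng = np.random.default_rng(seed)
        dyncfg = DynamicsConfig(mode="online", eta=grating_spec.get("eta", 1.0), T=T, record_every=1)
        trace = run_inference(frames, model.phi, model.latent, dyncfg, rng, u_init=model.u_init)
        pop = trace.r.sum(axis=-1)  # population rate per step
        baseline = pop[0]
        plateau = pop[-plateau_window:].mean()
        if plateau <= baseline:
            results.append((float(c), None))
            continue
        thresh = baseline + threshold_frac * (plateau - baseline)
        above = np.nonzero(pop >= thresh)[0]
        results.append((float(c), int(above[0]) if above.size else None))
    return results
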