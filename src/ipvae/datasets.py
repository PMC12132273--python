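"""Synthetic fixtures, stimulus generators, and dataset readers.

The synthetic generator inverts the model's own generative assumptions: a
ground-truth dictionary ``Phi*`` with unit-norm columns, sparse non-negative
codes ``a`` (Bernoulli gate x Exponential amplitude), and additive Gaussian
pixel noise,

    x = Phi* a + eps,   eps ~ N(0, sigma^2 I).

Defaults (M=64 i.e. 8x8 pixels, K_true=16, density 0.125, scale 2.0,
sigma=0.05) give on average two active generators per patch — sparse enough
to be identifiable, small enough for minutes-scale CPU training — and are
the fixture that drives the dictionary-recovery benchmark.

Also here: whitened natural-image patch extraction (Olshausen-Field style
frequency-domain whitening), a bit-exact IDX (MNIST) reader/writer, and a
drifting-grating stimulus generator for the contrast-latency probe.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SyntheticSpec",
    "PatchDataset",
    "make_ground_truth_dictionary",
    "sample_sparse_codes",
    "synth_patches",
    "extract_whitened_patches",
    "read_mnist_idx",
    "write_mnist_idx",
    "drifting_grating",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the sparse linear generative fixture."""

    M: int = 64
    K_true: int = 16
    code_density: float = 0.125
    code_scale: float = 2.0
    noise_sigma: float = 0.05
    n_patches: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.code_density <= 1:
            raise ValueError("code_density must be in (0, 1]")
        if self.noise_sigma < 0 or self.code_scale < 0:
            raise ValueError("noise_sigma and code_scale must be >= 0")
        if self.M < 1 or self.K_true < 1 or self.n_patches < 1:
            raise ValueError("M, K_true, n_patches must be >= 1")


@dataclass
class PatchDataset:
    """A stack of flat pixel vectors with provenance metadata."""

    X: np.ndarray  # (n, M)
    source: str = "synthetic"
    meta: dict | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def M(self) -> int:
        return self.X.shape[1]


def make_ground_truth_dictionary(
    M: int, K_true: int, kind: str = "random_unit", seed: int = 0
) -> np.ndarray:
    """Ground-truth dictionary with unit-norm columns.

    ``random_unit``: i.i.d. Gaussian columns normalized to unit norm.
    ``gabor``: Gabor patches on the sqrt(M) x sqrt(M) grid with randomized
    orientation, frequency, phase and center.
    """
    rng = np.random.default_rng(seed)
    if kind == "random_unit":
        phi = rng.standard_normal((M, K_true))
    elif kind == "gabor":
        side = int(round(np.sqrt(M)))
        if side * side != M:
            raise ValueError(f"gabor dictionary needs a square patch; M={M} is not a perfect square")
        yy, xx = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        cols = []
        for _ in range(K_true):
            theta = rng.uniform(0, np.pi)
            freq = rng.uniform(0.1, 0.4)           # cycles / pixel
            phase = rng.uniform(0, 2 * np.pi)
            cy, cx = rng.uniform(side * 0.25, side * 0.75, size=2)
            sigma = rng.uniform(side * 0.15, side * 0.3)
            xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
            env = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
            cols.append((env * np.cos(2 * np.pi * freq * xr + phase)).ravel())
        phi = np.stack(cols, axis=1)
    else:
        raise ValueError(f"unknown dictionary kind {kind!r}")
    return phi / np.linalg.norm(phi, axis=0, keepdims=True)


def sample_sparse_codes(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Non-negative sparse codes: Bernoulli(density) gate x Exp(scale) amplitude."""
    gate = rng.random((n, spec.K_true)) < spec.code_density
    amp = rng.exponential(spec.code_scale, size=(n, spec.K_true)) if spec.code_scale > 0 \
        else np.zeros((n, spec.K_true))
    return gate * amp


def synth_patches(spec: SyntheticSpec):
    """Generate ``x = Phi* a + eps`` patches plus the generating objects.

    Returns ``(dataset, phi_star, codes)`` so that recovery tests can compare
    the learned dictionary against the truth.  Pure function of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    phi_star = make_ground_truth_dictionary(spec.M, spec.K_true, "random_unit", seed=spec.seed)
    codes = sample_sparse_codes(spec, spec.n_patches, rng)
    X = codes @ phi_star.T
    if spec.noise_sigma > 0:
        X = X + spec.noise_sigma * rng.standard_normal(X.shape)
    ds = PatchDataset(X=X, source="synthetic", meta={"spec": spec.__dict__.copy()})
    return ds, phi_star, codes


def _whitening_filter(side: int, f0_frac: float = 0.8) -> np.ndarray:
    """Radial frequency filter |f| * exp(-(|f|/f0)^4), f0 = f0_frac * Nyquist."""
    f = np.fft.fftfreq(side)
    fy, fx = np.meshgrid(f, f, indexing="ij")
    rho = np.hypot(fy, fx)
    f0 = f0_frac * 0.5
    return rho * np.exp(-((rho / f0) ** 4))


def extract_whitened_patches(
    images: np.ndarray,
    patch_size: int,
    n_patches: int,
    seed: int = 0,
    whiten: bool = True,
) -> PatchDataset:
    """Random zero-mean patches from whitened images.

    Each square image is whitened in the frequency domain by the standard
    ramp filter ``|f| exp(-(|f|/f0)^4)`` with ``f0 = 0.8 * Nyquist`` (the
    classic sparse-coding preprocessing for natural images), patches are
    random crops, each patch has its mean removed, and the dataset is scaled
    to unit pixel variance overall (per dataset, not per patch).
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    n_img, H, Wd = images.shape
    if patch_size > H or patch_size > Wd:
        raise ValueError(f"patch_size {patch_size} exceeds image shape {(H, Wd)}")
    work = []
    for im in images:
        if whiten:
            side = min(H, Wd)
            im = im[:side, :side]
            F = np.fft.fft2(im)
            im = np.real(np.fft.ifft2(F * _whitening_filter(side)))
        work.append(im)
    rng = np.random.default_rng(seed)
    patches = np.empty((n_patches, patch_size * patch_size))
    for i in range(n_patches):
        im = work[rng.integers(len(work))]
        r = rng.integers(im.shape[0] - patch_size + 1)
        c = rng.integers(im.shape[1] - patch_size + 1)
        p = im[r : r + patch_size, c : c + patch_size].ravel()
        patches[i] = p - p.mean()
    sd = patches.std()
    if sd > 0:
        patches /= sd
    return PatchDataset(X=patches, source="vanhateren",
                        meta={"patch_size": patch_size, "whitened": whiten, "seed": seed})


_IDX_IMAGE_MAGIC = 2051
_IDX_LABEL_MAGIC = 2049


def read_mnist_idx(path_images: str, path_labels: str):
    """Parse the big-endian IDX format; pixels scaled to [0, 1], M = 784 flat.

    Returns ``(PatchDataset, labels)``.  Raises ValueError naming the
    observed magic number on malformed files.
    """
    with open(path_images, "rb") as fh:
        magic, n, rows, cols = struct.unpack(">iiii", fh.read(16))
        if magic != _IDX_IMAGE_MAGIC:
            raise ValueError(f"bad IDX image magic: got {magic}, expected {_IDX_IMAGE_MAGIC}")
        raw = np.frombuffer(fh.read(n * rows * cols), dtype=np.uint8)
    X = raw.reshape(n, rows * cols).astype(float) / 255.0
    with open(path_labels, "rb") as fh:
        magic, n_lab = struct.unpack(">ii", fh.read(8))
        if magic != _IDX_LABEL_MAGIC:
            raise ValueError(f"bad IDX label magic: got {magic}, expected {_IDX_LABEL_MAGIC}")
        labels = np.frombuffer(fh.read(n_lab), dtype=np.uint8).astype(int)
    if labels.size and (labels.min() < 0 or labels.max() > 9):
        raise ValueError(f"label values outside 0-9 (max observed {labels.max()})")
    if n != n_lab:
        raise ValueError(f"image/label count mismatch: {n} vs {n_lab}")
    ds = PatchDataset(X=X, source="mnist", meta={"rows": rows, "cols": cols})
    return ds, labels


def write_mnist_idx(path_images: str, path_labels: str, images: np.ndarray, labels: np.ndarray) -> None:
    """Write uint8 images (n, rows, cols) and labels in bit-exact IDX format."""
    images = np.asarray(images, dtype=np.uint8)
    labels = np.asarray(labels, dtype=np.uint8)
    n, rows, cols = images.shape
    with open(path_images, "wb") as fh:
        fh.write(struct.pack(">iiii", _IDX_IMAGE_MAGIC, n, rows, cols))
        fh.write(images.tobytes())
    with open(path_labels, "wb") as fh:
        fh.write(struct.pack(">ii", _IDX_LABEL_MAGIC, labels.size))
        fh.write(labels.tobytes())


def drifting_grating(
    patch_size: int,
    spatial_freq: float,
    temporal_freq: float,
    contrast: float,
    T: int,
    orientation: float = 0.0,
) -> np.ndarray:
    """Drifting sinusoidal grating frames, shape (T, patch_size**2).

    ``x_t(p) = contrast * sin(2 pi f <k, p> - 2 pi tf t)`` with spatial
    frequency in cycles/pixel and temporal frequency in cycles/frame; frames
    are mean-zero by construction of the full-period sinusoid only when an
    integer number of cycles fits, so the mean is removed explicitly.
    """
    if not 0 <= contrast <= 1:
        raise ValueError("contrast must be in [0, 1]")
    yy, xx = np.meshgrid(np.arange(patch_size), np.arange(patch_size), indexing="ij")
    proj = xx * np.cos(orientation) + yy * np.sin(orientation)
    t = np.arange(T)[:, None, None]
    frames = contrast * np.sin(2 * np.pi * spatial_freq * proj[None] - 2 * np.pi * temporal_freq * t)
    frames = frames - frames.mean(axis=(1, 2), keepdims=True)
    return frames.reshape(T, -1)
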