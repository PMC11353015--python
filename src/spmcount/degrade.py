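"""Image degradation: disk blur and additive Gaussian noise at a target SNR.

The degradation pipeline is blur -> noise, so the requested SNR is exact
with respect to the blurred (output-side) signal.  SNR follows the usual dB
convention ``SNR = 10*log10(P_signal / P_noise)``; the signal power is the
variance of the clean image about its mean, so the flat plasmonic background
does not inflate the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "NOISE_FREE",
    "NoiseSpec",
    "disk_kernel",
    "blur",
    "add_noise",
    "degrade",
    "measure_snr",
]

#: Sentinel SNR meaning "no noise injected" (infinitely clean).
NOISE_FREE = math.inf

# supersampling factor for the reference disk-kernel construction
_DISK_SUPERSAMPLE = 256


@dataclass(frozen=True)
class NoiseSpec:
    """Degradation condition: target SNR (dB, or NOISE_FREE), blur radius, seed.

    ``signal_power`` optionally overrides the clean-image variance used to
    scale the noise; it is required for constant (e.g. particle-free) images
    whose own variance is zero.
    """

    snr_db: float = NOISE_FREE
    blur_radius: float = 1.0
    boundary_mode: str = "replicate"
    seed: int = 0
    signal_power: float | None = None

    def __post_init__(self) -> None:
        if self.blur_radius < 0:
            raise ValueError(f"blur_radius must be >= 0, got {self.blur_radius}")
        if self.snr_db != NOISE_FREE and not math.isfinite(self.snr_db):
            raise ValueError(f"snr_db must be finite or NOISE_FREE, got {self.snr_db}")
        if self.boundary_mode != "replicate":
            raise ValueError(f"unsupported boundary mode {self.boundary_mode!r}")

    @property
    def noise_free(self) -> bool:
        return self.snr_db == NOISE_FREE


def disk_kernel(radius: float) -> np.ndarray:
    """Normalized disk (pillbox) blur kernel of the given pixel radius.

    Entry (i, j) is proportional to the area of overlap between the disk and
    pixel (i, j)'s unit square (computed by 256x sub-pixel supersampling);
    entries sum to 1.  Radius 0 degenerates to the identity kernel [[1]].
    This reproduces the classic radius-r disk ("pillbox") averaging filter.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if radius == 0:
        return np.ones((1, 1))
    half = math.ceil(radius)
    side = 2 * half + 1
    s = _DISK_SUPERSAMPLE
    # sub-pixel sample offsets at cell centres, relative to the kernel centre
    u = (np.arange(side * s) + 0.5) / s - half - 0.5
    xx, yy = np.meshgrid(u, u)
    inside = (xx**2 + yy**2 <= radius**2).astype(float)
    k = inside.reshape(side, s, side, s).sum(axis=(1, 3))
    return k / k.sum()


def blur(image: np.ndarray, kernel: np.ndarray, boundary: str = "replicate") -> np.ndarray:
    """2-D correlation of ``image`` with ``kernel`` under replicate padding.

    Edge pixels are extended outward, so a constant image is an exact fixed
    point.  Output has the shape of the input.
    """
    image = np.asarray(image, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if boundary != "replicate":
        raise ValueError(f"unsupported boundary {boundary!r}")
    if kernel.shape[0] > image.shape[0] or kernel.shape[1] > image.shape[1]:
        raise ValueError(
            f"kernel {kernel.shape} larger than image {image.shape}"
        )
    return ndimage.correlate(image, kernel, mode="nearest")


def add_noise(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise scaled to the target SNR.

    Noise variance is ``P_s / 10**(snr_db/10)`` with ``P_s`` the variance of
    the clean image (or ``spec.signal_power`` when set).  The output is not
    clipped.  A constant image with finite SNR and no signal-power override
    has undefined signal power and raises.
    """
    image = np.asarray(image, dtype=float)
    if spec.noise_free:
        return image.copy()
    p_s = float(np.var(image)) if spec.signal_power is None else float(spec.signal_power)
    if p_s <= 0:
        raise ValueError(
            "signal power is zero (constant image): finite-SNR noise is "
            "undefined; pass NoiseSpec.signal_power to override"
        )
    sigma = math.sqrt(p_s / 10.0 ** (spec.snr_db / 10.0))
    rng = np.random.default_rng(spec.seed)
    return image + rng.normal(0.0, sigma, size=image.shape)


def degrade(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Full degradation: disk blur then Gaussian noise (SNR w.r.t. blurred signal)."""
    out = blur(image, disk_kernel(spec.blur_radius), spec.boundary_mode)
    return add_noise(out, spec)


def measure_snr(clean: np.ndarray, degraded: np.ndarray) -> float:
    """Empirical SNR in dB: ``10*log10(var(clean) / mean((degraded-clean)**2))``.

    Returns ``math.inf`` when the residual is identically zero.
    """
    clean = np.asarray(clean, dtype=float)
    degraded = np.asarray(degraded, dtype=float)
    if clean.shape != degraded.shape:
        raise ValueError(f"shape mismatch {clean.shape} vs {degraded.shape}")
    mse = float(np.mean((degraded - clean) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(float(np.var(clean)) / mse)
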