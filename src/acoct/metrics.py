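"""Image-quality metrics: high-frequency ratio, bead/background
segmentation, speckle statistics, contrast, CNR and FWHM."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HFMaskSpec",
    "r_hf",
    "segment_beads",
    "std_reduction_curve",
    "relative_std",
    "contrast",
    "cnr_db",
    "fwhm",
]


@dataclass(frozen=True)
class HFMaskSpec:
    """Geometry of the excluded low-frequency block of the centred spectrum.

    Fractions are of the full spectrum width/height; defaults are the
    midpoints of the 1-3/100 (width) and 4-6/100 (height) working ranges.
    """

    width_fraction: float = 0.02
    height_fraction: float = 0.05
    axis_mode: str = "both-axes"  # "both-axes" | "horizontal-only"

    def __post_init__(self) -> None:
        if not (0.0 < self.width_fraction < 0.5 and 0.0 < self.height_fraction < 0.5):
            raise ValueError("mask fractions must lie in (0, 0.5)")
        if self.axis_mode not in ("both-axes", "horizontal-only"):
            raise ValueError("axis_mode must be 'both-axes' or 'horizontal-only'")


def _central_block(n: int, fraction: float) -> slice:
    half = max(1, int(round(n * fraction / 2.0)))
    c = n // 2
    return slice(max(c - half, 0), min(c + half + 1, n))


def r_hf(image, spec: HFMaskSpec | None = None) -> float:
    """Ratio of high-frequency to total spectral magnitude of an image.

    ``both-axes`` removes a small central block from the centred 2-D
    spectrum; ``horizontal-only`` transforms each depth row and removes the
    central columns only.  Invariant to intensity scaling; strictly reduced
    by blurring.
    """
    spec = spec or HFMaskSpec()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.any(img):
        raise ValueError("all-zero image has undefined spectral ratio")
    if spec.axis_mode == "horizontal-only":
        ft = np.abs(np.fft.fftshift(np.fft.fft(img, axis=1), axes=1))
        total = ft.sum()
        low = ft[:, _central_block(img.shape[1], spec.width_fraction)].sum()
    else:
        ft = np.abs(np.fft.fftshift(np.fft.fft2(img)))
        total = ft.sum()
        low = ft[_central_block(img.shape[0], spec.height_fraction),
                 _central_block(img.shape[1], spec.width_fraction)].sum()
    return float((total - low) / total)


def segment_beads(image, top_fraction: float = 0.10):
    """Depth-resolved bright/background split.

    Per depth row the threshold is the weakest intensity among the row's top
    ``top_fraction`` brightest pixels; pixels at or above it are signal.
    Rows narrower than ``1/top_fraction`` pixels fall back to the global
    threshold.  Returns ``(signal_mask, background_mask)``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D (rows indexed by depth)")
    n_v, n_u = img.shape
    k_global = max(1, int(np.ceil(top_fraction * img.size)))
    thr_global = np.sort(img, axis=None)[-k_global]
    if n_u * top_fraction < 1.0:
        thr = np.full(n_v, thr_global)
    else:
        k = max(1, int(np.ceil(top_fraction * n_u)))
        thr = np.sort(img, axis=1)[:, -k]
    signal = img >= thr[:, None]
    return signal, ~signal


def std_reduction_curve(angular_images, region=None) -> np.ndarray:
    """Background STD of the running k-angle composite, k = 1..N,
    normalized to the single-image value."""
    imgs = [np.asarray(im, dtype=float) for im in angular_images]
    if len(imgs) < 2:
        raise ValueError("need at least two angular images")
    if region is not None:
        imgs = [im[region] for im in imgs]
    run = np.zeros_like(imgs[0])
    stds = []
    for k, im in enumerate(imgs, start=1):
        run = run + im
        stds.append(np.std(run / k))
    stds = np.asarray(stds)
    return stds / stds[0]


def relative_std(image, mask=None) -> float:
    """STD/mean of the (masked) image values; scale-invariant."""
    img = np.asarray(image, dtype=float)
    vals = img[mask] if mask is not None else img.ravel()
    if vals.size == 0:
        raise ValueError("masked region is empty")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("mean must be positive for a relative STD")
    return float(vals.std() / mean)


def contrast(signal_mean: float, background_mean: float) -> float:
    """``signal/background - 1``."""
    if background_mean <= 0:
        raise ValueError("background mean must be positive")
    return float(signal_mean / background_mean - 1.0)


def cnr_db(signal_mean: float, background_mean: float, background_std: float) -> float:
    """``20*log10((signal - background) / background_std)`` in dB;
    -inf when the feature is not brighter than the background."""
    if background_std <= 0:
        raise ValueError("background std must be positive")
    diff = signal_mean - background_mean
    if diff <= 0:
        return float("-inf")
    return float(20.0 * np.log10(diff / background_std))


def fwhm(profile, pitch: float = 1.0) -> float:
    """Full width at half maximum of a single-peaked 1-D profile.

    The baseline is the median of the outer quartiles; crossings of
    ``baseline + (max-baseline)/2`` are located by linear interpolation on
    both flanks of the (unique) maximum.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size < 5:
        raise ValueError("profile must be 1-D with at least 5 samples")
    n = p.size
    q = max(1, n // 4)
    baseline = np.median(np.concatenate([p[:q], p[-q:]]))
    peak_idx = int(np.argmax(p))
    peak = p[peak_idx]
    if peak <= baseline:
        raise ValueError("profile has no peak above baseline")
    half = baseline + 0.5 * (peak - baseline)

    def cross(idx_range, reverse):
        prev_i = peak_idx
        for i in idx_range:
            if p[i] < half:
                # linear interpolation between i and the neighbour closer to peak
                j = i + 1 if reverse else i - 1
                frac = (p[j] - half) / (p[j] - p[i])
                return abs(j - peak_idx) + frac
            prev_i = i
        return abs(prev_i - peak_idx) + 0.5  # ran off the edge

    left = cross(range(peak_idx - 1, -1, -1), reverse=True)
    right = cross(range(peak_idx + 1, n), reverse=False)
    return float((left + right) * pitch)
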