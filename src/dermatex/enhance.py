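"""Wavelet-fusion image enhancement (ICTEF).

Three denoising/contrast arms are run on the same grayscale raster:

* arm G — a double-stage Gaussian low-pass (the same 3x3, sigma=1
  kernel applied twice),
* arm W — a 3x3 locally adaptive Wiener filter (noise power estimated
  as the mean of the local variances),
* arm M — contrast-limited adaptive histogram equalization followed by
  a 3x3 median filter.

Each arm is decomposed with a multilevel 2-D discrete wavelet
transform (db2, 3 levels, periodized boundaries), the three
decompositions are fused coefficient-wise by the arithmetic mean in
every subband (approximation and all detail levels), and the fused
coefficients are inverse-transformed and clipped back to [0, 1].
Averaging in the wavelet domain suppresses arm-specific artifacts
while the detail subbands retain edges each arm preserved.

RGB input is enhanced channel by channel so the output stays a valid
3-channel image for the downstream 2-D convolutional branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy.ndimage import median_filter, uniform_filter
from scipy.signal import convolve2d
from skimage.exposure import equalize_adapthist

__all__ = [
    "GaussianSpec",
    "SubbandSet",
    "gaussian_kernel",
    "gaussian_filter",
    "wiener_filter",
    "clahe",
    "filter_arms",
    "dwt_decompose",
    "mean_fuse",
    "idwt_reconstruct",
    "ictef_enhance",
]


@dataclass(frozen=True)
class GaussianSpec:
    """Isotropic Gaussian kernel: standard deviation and odd window side."""

    sigma: float = 1.0
    window: int = 3

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")


@dataclass(frozen=True)
class SubbandSet:
    """Multilevel 2-D DWT coefficients.

    ``approximation`` is the coarsest-level A raster; ``details[j]``
    holds the ``(H, V, D)`` rasters of level ``j+1`` ordered from
    coarsest to finest, matching ``pywt.wavedec2`` layout.
    """

    approximation: np.ndarray
    details: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]
    wavelet: str
    levels: int

    @property
    def coeff_list(self):
        return [self.approximation] + [tuple(d) for d in self.details]

    def map(self, fn) -> "SubbandSet":
        """Apply ``fn`` to every coefficient raster."""
        return replace(
            self,
            approximation=fn(self.approximation),
            details=tuple(tuple(fn(c) for c in lvl) for lvl in self.details),
        )


def gaussian_kernel(spec: GaussianSpec) -> np.ndarray:
    """Normalized discrete Gaussian on the window grid (sums to 1)."""
    r = spec.window // 2
    x = np.arange(-r, r + 1)
    xx, yy = np.meshgrid(x, x)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * spec.sigma**2))
    k /= 2.0 * np.pi * spec.sigma**2
    return k / k.sum()


def gaussian_filter(image: np.ndarray, spec: GaussianSpec = GaussianSpec()) -> np.ndarray:
    """Low-pass filter by correlation with the normalized Gaussian kernel."""
    image = np.asarray(image, dtype=float)
    return convolve2d(image, gaussian_kernel(spec), mode="same", boundary="symm")


def wiener_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Locally adaptive Wiener filter.

    Local mean and variance come from a ``window x window`` box on
    reflective boundaries; the noise power is estimated as the mean of
    the local variances.  Where the local variance falls below the
    noise estimate the output is the local mean (pure smoothing);
    elsewhere the signal deviation is attenuated by
    ``(var - noise) / var``.
    """
    x = np.asarray(image, dtype=float)
    mu = uniform_filter(x, window, mode="reflect")
    var = uniform_filter(x * x, window, mode="reflect") - mu * mu
    var = np.maximum(var, 0.0)
    noise = var.mean()
    gain = np.where(var > noise, (var - noise) / np.maximum(var, 1e-30), 0.0)
    return mu + gain * (x - mu)


def clahe(image: np.ndarray, clip_limit: float = 0.01,
          tiles: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on [0, 1] input.

    A zero-dynamic-range image has no contrast to redistribute and is
    returned unchanged (equalization is ill-defined there).
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) < 1e-12:
        return image.copy()
    kernel = (max(image.shape[0] // tiles, 1), max(image.shape[1] // tiles, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return equalize_adapthist(np.clip(image, 0.0, 1.0),
                                  kernel_size=kernel, clip_limit=clip_limit)


def filter_arms(image: np.ndarray, gaussian: GaussianSpec = GaussianSpec(),
                clip_limit: float = 0.01):
    """The three enhancement arms: (double Gaussian, Wiener, CLAHE+median)."""
    image = np.asarray(image, dtype=float)
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    arm_g = gaussian_filter(gaussian_filter(image, gaussian), gaussian)
    arm_w = wiener_filter(image, window=gaussian.window)
    arm_m = median_filter(clahe(image, clip_limit=clip_limit), size=3,
                          mode="nearest")
    clip = lambda a: np.clip(a, 0.0, 1.0)
    return clip(arm_g), clip(arm_w), clip(arm_m)


def dwt_decompose(image: np.ndarray, wavelet: str = "db2",
                  levels: int = 3) -> SubbandSet:
    """Multilevel 2-D DWT with periodized boundaries."""
    image = np.asarray(image, dtype=float)
    if min(image.shape) < 2**levels:
        raise ValueError(f"image too small for {levels}-level DWT")
    try:
        coeffs = pywt.wavedec2(image, wavelet, mode="periodization",
                               level=levels)
    except ValueError as e:
        raise ValueError(f"unsupported wavelet {wavelet!r}: {e}") from e
    return SubbandSet(approximation=coeffs[0],
                      details=tuple(tuple(lvl) for lvl in coeffs[1:]),
                      wavelet=wavelet, levels=levels)


def _check_compatible(a: SubbandSet, b: SubbandSet):
    if (a.wavelet, a.levels) != (b.wavelet, b.levels):
        raise ValueError("subband sets differ in wavelet or level count")
    if a.approximation.shape != b.approximation.shape:
        raise ValueError("subband sets differ in approximation shape")
    for la, lb in zip(a.details, b.details):
        for ca, cb in zip(la, lb):
            if ca.shape != cb.shape:
                raise ValueError("subband sets differ in detail shapes")


def mean_fuse(sb_g: SubbandSet, sb_w: SubbandSet, sb_m: SubbandSet) -> SubbandSet:
    """Coefficient-wise arithmetic mean of three decompositions.

    The mean is taken in every subband at every level; this is the only
    fusion consistent with reconstructing a full multilevel transform.
    """
    _check_compatible(sb_g, sb_w)
    _check_compatible(sb_g, sb_m)
    approx = (sb_g.approximation + sb_w.approximation + sb_m.approximation) / 3.0
    details = tuple(
        tuple((cg + cw + cm) / 3.0 for cg, cw, cm in zip(lg, lw, lm))
        for lg, lw, lm in zip(sb_g.details, sb_w.details, sb_m.details)
    )
    return SubbandSet(approximation=approx, details=details,
                      wavelet=sb_g.wavelet, levels=sb_g.levels)


def idwt_reconstruct(subbands: SubbandSet, clip: bool = True) -> np.ndarray:
    """Inverse multilevel DWT; output clipped to [0, 1] unless disabled."""
    out = pywt.waverec2(subbands.coeff_list, subbands.wavelet,
                        mode="periodization")
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out


def _enhance_channel(channel: np.ndarray, gaussian: GaussianSpec,
                     wavelet: str, levels: int, clip_limit: float) -> np.ndarray:
    arms = filter_arms(channel, gaussian=gaussian, clip_limit=clip_limit)
    subs = [dwt_decompose(a, wavelet, levels) for a in arms]
    fused = mean_fuse(*subs)
    out = idwt_reconstruct(fused)
    # periodization keeps sizes at ceil(n / 2**levels) * 2**levels
    return out[: channel.shape[0], : channel.shape[1]]


def ictef_enhance(image: np.ndarray, gaussian: GaussianSpec = GaussianSpec(),
                  wavelet: str = "db2", levels: int = 3,
                  clip_limit: float = 0.01) -> np.ndarray:
    """Full enhancement: per channel, arms -> DWT -> mean fusion -> IDWT."""
    image = np.asarray(image, dtype=float)
    if image.shape[0] < 8 or image.shape[1] < 8:
        raise ValueError("image must be at least 8x8")
    if image.ndim == 2:
        return _enhance_channel(image, gaussian, wavelet, levels, clip_limit)
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[:, :, c] = _enhance_channel(image[:, :, c], gaussian, wavelet,
                                        levels, clip_limit)
    return out
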