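"""Gray-level co-occurrence matrix (GLCM) texture statistics.

The GLCM ``P`` is the normalized joint frequency of quantized
gray-level pairs ``(i, j)`` observed at a fixed spatial offset.  Six
Haralick-style statistics are derived from it:

* contrast        ``CT = sum (i - j)^2 P_ij``
* correlation     ``CR = sum P_ij (i - mu_i)(j - mu_j) / (s_i s_j)``
* energy          ``EN = sum P_ij^2``
* homogeneity     ``HM = sum P_ij / (1 + |i - j|)``
* autocorrelation ``AC = sum P_ij * i * j``
* entropy         ``ET = sum -P_ij ln P_ij``  (0 ln 0 := 0)

Correlation uses the row/column standard deviations ``s_i s_j`` in the
denominator, which keeps CR in [-1, 1] for asymmetric matrices and
coincides with the single-variance form on symmetric ones.  A matrix
with zero marginal variance (a constant image) is perfectly
self-similar; CR is reported as 1.0 with a warning rather than raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

__all__ = ["GLCMMatrix", "GLCMFeatures", "quantize", "compute_glcm",
           "glcm_features", "FEATURE_NAMES"]

FEATURE_NAMES = ("contrast", "correlation", "energy", "homogeneity",
                 "autocorrelation", "entropy")


@dataclass(frozen=True)
class GLCMMatrix:
    """Normalized co-occurrence probabilities at one offset."""

    P: np.ndarray
    levels: int
    distance: int
    angle: float
    symmetric: bool

    def __post_init__(self):
        P = self.P
        if P.shape != (self.levels, self.levels):
            raise ValueError("P must be levels x levels")
        if (P < 0).any() or abs(P.sum() - 1.0) > 1e-9:
            raise ValueError("P must be a probability matrix")


@dataclass(frozen=True)
class GLCMFeatures:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    autocorrelation: float
    entropy: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize a [0, 1] raster to integers {0..levels-1}."""
    image = np.asarray(image, dtype=float)
    q = np.floor(np.clip(image, 0.0, 1.0) * levels).astype(np.uint8)
    return np.minimum(q, levels - 1)


def compute_glcm(image: np.ndarray, levels: int = 8, distance: int = 1,
                 angle: float = 0.0, symmetric: bool = True) -> GLCMMatrix:
    """Quantize, count co-occurring pairs at the offset, normalize.

    ``angle`` follows the usual convention: 0 pairs each pixel with its
    right neighbour at ``distance``, pi/2 with the one above.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = quantize(image, levels)
    if q.ndim != 2 or min(q.shape) == 0:
        raise ValueError("image must be a nonempty 2-D raster")
    span = int(np.ceil(distance))
    if q.shape[0] <= span and q.shape[1] <= span:
        raise ValueError("image smaller than the requested offset span")
    glcm = graycomatrix(q, distances=[distance], angles=[angle],
                        levels=levels, symmetric=symmetric, normed=False)
    counts = glcm[:, :, 0, 0].astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no pixel pairs at the requested offset")
    return GLCMMatrix(P=counts / total, levels=levels, distance=distance,
                      angle=angle, symmetric=symmetric)


def glcm_features(glcm: GLCMMatrix) -> GLCMFeatures:
    """Evaluate the six texture statistics of a normalized GLCM."""
    P = glcm.P
    n = glcm.levels
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]

    ct = float(((i - j) ** 2 * P).sum())
    en = float((P ** 2).sum())
    hm = float((P / (1.0 + np.abs(i - j))).sum())
    ac = float((P * (i * j)).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log(P), 0.0)
    et = float(-(P * logP).sum())

    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float((np.arange(n) * pi).sum())
    mu_j = float((np.arange(n) * pj).sum())
    var_i = float(((np.arange(n) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(n) - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        warnings.warn("degenerate GLCM (zero marginal variance); "
                      "correlation reported as 1.0", stacklevel=2)
        cr = 1.0
    else:
        cov = float((P * (i - mu_i) * (j - mu_j)).sum())
        cr = cov / np.sqrt(var_i * var_j)

    return GLCMFeatures(contrast=ct, correlation=cr, energy=en,
                        homogeneity=hm, autocorrelation=ac, entropy=et)
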