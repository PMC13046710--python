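"""Histogram of oriented gradients (HOG) shape descriptor.

Gradients come from the centered difference kernels [-1 0 1] and its
transpose on replicate-padded borders.  Per-cell orientation
histograms (9 bins over the unsigned range [0, 180) degrees,
magnitude-weighted with linear interpolation between adjacent bins)
are grouped into 2x2-cell blocks advancing one cell at a time (50%
overlap) and L2-normalized per block.  With the default 8-px cells on
a 256x256 image this yields a 31x31 block grid of 36 values each:
34,596 features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HOGConfig", "GradientField", "gradients", "hog_features",
           "hog_length"]


@dataclass(frozen=True)
class HOGConfig:
    cell: int = 8          # pixels per cell side
    block: int = 2         # cells per block side
    stride: int = 1        # cells between block origins
    bins: int = 9
    signed: bool = False   # False: orientations folded to [0, 180)
    eps: float = 1e-6

    def __post_init__(self):
        if min(self.cell, self.block, self.stride, self.bins) < 1:
            raise ValueError("cell, block, stride and bins must be positive")
        if self.stride > self.block:
            raise ValueError("stride must not exceed the block size")


@dataclass(frozen=True)
class GradientField:
    ix: np.ndarray
    iy: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray  # degrees


def gradients(image: np.ndarray, signed: bool = False) -> GradientField:
    """Centered-difference gradients, magnitude and orientation.

    Orientation is in degrees: [0, 360) signed, folded to [0, 180)
    unsigned.  Zero-magnitude pixels get orientation 0 (their weight
    in any histogram is zero).
    """
    im = np.asarray(image, dtype=float)
    if im.ndim != 2 or im.shape[0] < 3 or im.shape[1] < 3:
        raise ValueError("image must be a 2-D raster of at least 3x3")
    pad = np.pad(im, 1, mode="edge")
    ix = pad[1:-1, 2:] - pad[1:-1, :-2]
    iy = pad[2:, 1:-1] - pad[:-2, 1:-1]
    mag = np.hypot(ix, iy)
    theta = np.degrees(np.arctan2(iy, ix))
    theta = np.where(mag > 0, theta, 0.0)
    theta = theta % (360.0 if signed else 180.0)
    return GradientField(ix=ix, iy=iy, magnitude=mag, orientation=theta)


def hog_length(shape: tuple[int, int], config: HOGConfig = HOGConfig()) -> int:
    """Feature count for an image shape under a config."""
    cy, cx = shape[0] // config.cell, shape[1] // config.cell
    by = (cy - config.block) // config.stride + 1
    bx = (cx - config.block) // config.stride + 1
    if by < 1 or bx < 1:
        raise ValueError("image smaller than one block")
    return by * bx * config.block ** 2 * config.bins


def _cell_histograms(field: GradientField, cell: int, bins: int,
                     signed: bool) -> np.ndarray:
    """Magnitude-weighted orientation histograms per cell, with linear
    interpolation of each vote between the two nearest bin centers."""
    h, w = field.magnitude.shape
    cy, cx = h // cell, w // cell
    mag = field.magnitude[: cy * cell, : cx * cell]
    theta = field.orientation[: cy * cell, : cx * cell]
    span = 360.0 if signed else 180.0
    width = span / bins

    # fractional bin position; bin centers at (b + 0.5) * width
    pos = theta / width - 0.5
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    lo_wrapped = lo % bins
    hi_wrapped = (lo + 1) % bins

    cells = np.zeros((cy, cx, bins))
    yy = np.repeat(np.arange(cy), cell)[:, None] * np.ones((1, cx * cell), int)
    xx = np.ones((cy * cell, 1), int) * np.repeat(np.arange(cx), cell)[None, :]
    np.add.at(cells, (yy.ravel(), xx.ravel(), lo_wrapped.ravel()),
              (mag * (1.0 - frac)).ravel())
    np.add.at(cells, (yy.ravel(), xx.ravel(), hi_wrapped.ravel()),
              (mag * frac).ravel())
    return cells


def hog_features(image: np.ndarray, config: HOGConfig = HOGConfig()) -> np.ndarray:
    """Block-normalized HOG feature vector (row-major block order)."""
    n = hog_length(np.asarray(image).shape, config)  # validates geometry
    field = gradients(image, signed=config.signed)
    cells = _cell_histograms(field, config.cell, config.bins, config.signed)
    cy, cx, bins = cells.shape
    b, s = config.block, config.stride

    blocks = []
    for y0 in range(0, cy - b + 1, s):
        for x0 in range(0, cx - b + 1, s):
            v = cells[y0:y0 + b, x0:x0 + b, :].ravel()
            blocks.append(v / np.sqrt((v * v).sum() + config.eps ** 2))
    out = np.concatenate(blocks)
    assert out.size == n
    return out
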