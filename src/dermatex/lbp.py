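"""Local binary patterns: the conventional 8-bit operator and the
four-directional reduced variant (ILBP).

For each interior pixel the 3x3 neighbourhood is labelled

    p1 p2 p3
    p4  c p5
    p6 p7 p8

and every neighbour is thresholded *strictly* against the center
(``p > c -> 1``, ties -> 0).  The conventional operator packs all
eight bits (p1 as the most significant) into a byte, giving a 256-bin
histogram.  The directional variant packs three bits per direction --
top (p1,p2,p3), bottom (p6,p7,p8), left (p1,p4,p6), right (p3,p5,p8),
first-listed neighbour most significant -- giving four code rasters in
{0..7} and four 8-bin histograms, concatenated as [U, B, L, R] into 32
features: an 8-fold reduction over the conventional histogram.

Codes are computed on interior pixels only (no padding), so every
histogram sums to ``(H-2) * (W-2)``.  Strict comparisons make all
codes invariant to adding a constant to, or positively rescaling,
the image.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lbp_map", "lbp_histogram", "ilbp_maps", "ilbp_features",
           "ILBP_DIRECTIONS"]

# direction -> neighbour positions in MSB-to-LSB order
ILBP_DIRECTIONS = {
    "U": ("p1", "p2", "p3"),
    "B": ("p6", "p7", "p8"),
    "L": ("p1", "p4", "p6"),
    "R": ("p3", "p5", "p8"),
}


def _neighbours(image: np.ndarray):
    """Neighbour rasters over the interior, keyed p1..p8, plus center."""
    im = np.asarray(image, dtype=float)
    if im.ndim != 2 or im.shape[0] < 3 or im.shape[1] < 3:
        raise ValueError("image must be a 2-D raster of at least 3x3")
    c = im[1:-1, 1:-1]
    p = {
        "p1": im[:-2, :-2], "p2": im[:-2, 1:-1], "p3": im[:-2, 2:],
        "p4": im[1:-1, :-2], "p5": im[1:-1, 2:],
        "p6": im[2:, :-2], "p7": im[2:, 1:-1], "p8": im[2:, 2:],
    }
    return p, c


def lbp_map(image: np.ndarray) -> np.ndarray:
    """Conventional 8-bit LBP codes over interior pixels (p1 -> MSB)."""
    p, c = _neighbours(image)
    code = np.zeros(c.shape, dtype=np.uint8)
    for k, name in enumerate(("p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8")):
        code |= ((p[name] > c).astype(np.uint8) << (7 - k))
    return code


def lbp_histogram(image: np.ndarray, block_size: int | None = None) -> np.ndarray:
    """256-bin histogram of conventional LBP codes.

    With ``block_size`` the code raster is cut into a grid of blocks
    and per-block histograms are concatenated.
    """
    codes = lbp_map(image)
    if block_size is None:
        return np.bincount(codes.ravel(), minlength=256)
    h, w = codes.shape
    hists = []
    for y0 in range(0, h - block_size + 1, block_size):
        for x0 in range(0, w - block_size + 1, block_size):
            blk = codes[y0:y0 + block_size, x0:x0 + block_size]
            hists.append(np.bincount(blk.ravel(), minlength=256))
    return np.concatenate(hists)


def ilbp_maps(image: np.ndarray) -> dict[str, np.ndarray]:
    """Four directional 3-bit code rasters keyed 'U', 'B', 'L', 'R'."""
    p, c = _neighbours(image)
    maps = {}
    for q, names in ILBP_DIRECTIONS.items():
        code = np.zeros(c.shape, dtype=np.uint8)
        for k, name in enumerate(names):
            code |= ((p[name] > c).astype(np.uint8) << (2 - k))
        maps[q] = code
    return maps


def ilbp_features(image: np.ndarray, normalize: bool = False) -> np.ndarray:
    """32-value descriptor: concatenated 8-bin histograms of U, B, L, R.

    Histograms are raw interior-pixel counts unless ``normalize``.
    """
    maps = ilbp_maps(image)
    hists = [np.bincount(maps[q].ravel(), minlength=8).astype(float)
             for q in ("U", "B", "L", "R")]
    feat = np.concatenate(hists)
    if normalize:
        feat = feat / feat.sum()
    return feat
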