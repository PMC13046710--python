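"""Small image utilities shared across the package.

All images are numpy arrays in [0, 1]: grayscale rasters are 2-D
``(H, W)`` and RGB images are ``(H, W, 3)``, float64 unless noted.
"""

from __future__ import annotations

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

#: Rec. 601 luma weights, the conventional RGB -> gray projection.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Project an RGB image onto luma; pass 2-D images through unchanged."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected (H, W) or (H, W, 3) image, got {image.shape}")
    return image @ LUMA_WEIGHTS


def resize_image(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to ``size = (height, width)``, preserving range."""
    if image.shape[:2] == tuple(size):
        return np.asarray(image, dtype=float)
    out = _sk_resize(np.asarray(image, dtype=float), size, order=1,
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def save_png(image: np.ndarray, path) -> None:
    """Write an image in [0, 1] as an 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    arr8 = np.round(arr * 255.0).astype(np.uint8)
    Image.fromarray(arr8).save(path, format="PNG")


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG file into a float array in [0, 1] (RGB or gray)."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        arr = np.asarray(im, dtype=float) / 255.0
    return arr
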