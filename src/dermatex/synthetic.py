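"""Seeded generator of class-separable textured image datasets.

The generator stands in for a dermatology photo collection organised
one-directory-per-class.  Each class is a filtered Gaussian random
field: white noise smoothed at a class-specific correlation length,
rescaled to a class-specific texture amplitude and shifted to a base
gray level.  The amplitude directly controls the co-occurrence
contrast a texture descriptor measures, and the correlation length
controls neighbour correlation, so classes can be laid out with any
desired ordering of their texture statistics.  An optional elliptical
"lesion" with a sinusoidally perturbed boundary adds a localized shape
cue for gradient-based descriptors and for saliency checks.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; the same spec, size and seed always
reproduce the bit-identical image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter as _nd_gaussian

from .image import save_png

__all__ = [
    "LesionSpec",
    "ClassTextureSpec",
    "SyntheticDatasetSpec",
    "default_class_specs",
    "generate_image",
    "generate_dataset",
]


@dataclass(frozen=True)
class LesionSpec:
    """Elliptical lesion with an irregular (radially perturbed) boundary.

    Center and axes are fractions of the image side so the same spec
    scales to any resolution.  ``irregularity`` is the relative
    amplitude of the sinusoidal radial perturbation; ``intensity``
    is added inside the lesion (negative values darken it).
    """

    center: tuple[float, float] = (0.5, 0.5)
    axes: tuple[float, float] = (0.2, 0.15)
    irregularity: float = 0.15
    intensity: float = -0.2
    n_lobes: int = 5

    def __post_init__(self):
        for a in self.axes:
            if not 0.0 < a <= 0.5:
                raise ValueError("lesion axes fractions must lie in (0, 0.5]")
        if self.irregularity < 0:
            raise ValueError("irregularity must be >= 0")


@dataclass(frozen=True)
class ClassTextureSpec:
    """Texture parameters of one synthetic class."""

    class_name: str
    base_gray: float = 0.5
    texture_amplitude: float = 0.15
    correlation_length: float = 2.0
    lesion: LesionSpec | None = None

    def __post_init__(self):
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be >= 0")
        if self.correlation_length < 1:
            raise ValueError("correlation_length must be >= 1 pixel")
        if not 0.0 <= self.base_gray <= 1.0:
            raise ValueError("base_gray must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """A full dataset: class specs, per-class counts and degradations."""

    specs: tuple[ClassTextureSpec, ...] = ()
    counts: int = 40
    image_size: tuple[int, int] = (256, 256)
    noise_sigma: float = 0.0
    blur_sigma: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.counts < 1:
            raise ValueError("counts must be >= 1")
        if min(self.image_size) < 16:
            raise ValueError("image_size must be at least 16x16")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not self.specs:
            object.__setattr__(self, "specs", tuple(default_class_specs()))


def default_class_specs() -> list[ClassTextureSpec]:
    """The five default classes, named after common skin conditions.

    Texture amplitudes and correlation lengths are laid out so that
    co-occurrence statistics order the classes the way coarse clinical
    texture intuition suggests: the viral/malignant classes are the
    most contrasted and least spatially correlated, while hives are
    smooth and strongly correlated.  The melanoma class carries a
    pronounced dark irregular lesion; lupus a milder one.
    """
    return [
        ClassTextureSpec("acne", base_gray=0.60, texture_amplitude=0.16,
                         correlation_length=2.0),
        ClassTextureSpec("lupus", base_gray=0.55, texture_amplitude=0.22,
                         correlation_length=1.6,
                         lesion=LesionSpec(center=(0.45, 0.55),
                                           axes=(0.25, 0.2),
                                           irregularity=0.2,
                                           intensity=-0.10)),
        ClassTextureSpec("melanoma", base_gray=0.55, texture_amplitude=0.26,
                         correlation_length=1.4,
                         lesion=LesionSpec(center=(0.5, 0.5),
                                           axes=(0.22, 0.18),
                                           irregularity=0.25,
                                           intensity=-0.25)),
        ClassTextureSpec("urticaria_hives", base_gray=0.65,
                         texture_amplitude=0.08, correlation_length=6.0),
        ClassTextureSpec("herpes_hpv", base_gray=0.50, texture_amplitude=0.30,
                         correlation_length=1.2),
    ]


def _lesion_mask(lesion: LesionSpec, size: tuple[int, int],
                 rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of the perturbed ellipse.  Consumes one phase draw."""
    h, w = size
    cy, cx = lesion.center[0] * h, lesion.center[1] * w
    ay, ax = lesion.axes[0] * h, lesion.axes[1] * w
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = (yy - cy) / ay, (xx - cx) / ax
    r = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    boundary = 1.0 + lesion.irregularity * np.sin(lesion.n_lobes * phi + phase)
    return r <= boundary


def generate_image(spec: ClassTextureSpec,
                   size: tuple[int, int] = (256, 256),
                   noise_sigma: float = 0.0,
                   blur_sigma: float | None = None,
                   seed: int = 0,
                   return_mask: bool = False):
    """Render one RGB image in [0, 1] for a class spec.

    The luminance field is ``base_gray + amplitude * F`` where ``F`` is
    unit-variance smoothed white noise; the three channels share it up
    to small seeded chromatic offsets.  Degradations (additive Gaussian
    noise, then optional blur) are applied last and never change the
    label.  With ``return_mask=True`` also returns the boolean lesion
    mask (all-False when the spec has no lesion).
    """
    h, w = size
    if h < 16 or w < 16:
        raise ValueError("image size must be at least 16x16")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if blur_sigma is not None and blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")

    rng = np.random.default_rng(seed)
    # Smoothed Gaussian random field, normalised to unit sample std so
    # texture_amplitude is the field's actual standard deviation.
    white = rng.standard_normal((h, w))
    if spec.texture_amplitude > 0:
        fld = _nd_gaussian(white, sigma=spec.correlation_length, mode="wrap")
        sd = fld.std()
        if sd > 0:
            fld = fld / sd
        luma = spec.base_gray + spec.texture_amplitude * fld
    else:
        luma = np.full((h, w), spec.base_gray)

    mask = np.zeros((h, w), dtype=bool)
    if spec.lesion is not None:
        mask = _lesion_mask(spec.lesion, size, rng)
        luma = luma + spec.lesion.intensity * mask

    # Shared-luminance RGB with small seeded chromatic offsets.
    chroma = rng.uniform(-0.03, 0.03, size=3)
    img = luma[:, :, None] + chroma[None, None, :]

    if noise_sigma > 0:
        img = img + noise_sigma * rng.standard_normal(img.shape)
    if blur_sigma:
        img = _nd_gaussian(img, sigma=(blur_sigma, blur_sigma, 0.0))

    img = np.clip(img, 0.0, 1.0)
    if return_mask:
        return img, mask
    return img


def generate_dataset(dataset_spec: SyntheticDatasetSpec,
                     out_dir: str | Path | None = None):
    """Generate a labelled image collection and its manifest.

    Returns ``(images, labels, manifest)`` where ``images`` is a list of
    ``(H, W, 3)`` arrays, ``labels`` integer class indices in spec
    order, and ``manifest`` a DataFrame with one row per image (path,
    label, class name, per-image seed).  When ``out_dir`` is given the
    images are written as 8-bit PNG under ``out_dir/<class_name>/`` and
    the manifest as ``manifest.csv``.
    """
    ds = dataset_spec
    # Per-image seeds derived from the dataset seed; independent of
    # whether images are written to disk.
    ss = np.random.SeedSequence(ds.seed)
    child_seeds = ss.generate_state(len(ds.specs) * ds.counts) % (2**31)

    images, labels, rows = [], [], []
    k = 0
    for label, spec in enumerate(ds.specs):
        for i in range(ds.counts):
            seed_i = int(child_seeds[k]); k += 1
            img = generate_image(spec, ds.image_size, ds.noise_sigma,
                                 ds.blur_sigma, seed_i)
            rel = f"{spec.class_name}/{i:04d}.png"
            images.append(img)
            labels.append(label)
            rows.append({"path": rel, "label": label,
                         "class_name": spec.class_name, "seed": seed_i})

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        root = Path(out_dir)
        try:
            root.mkdir(parents=True, exist_ok=True)
            for img, row in zip(images, rows):
                p = root / row["path"]
                p.parent.mkdir(exist_ok=True)
                save_png(img, p)
            manifest.to_csv(root / "manifest.csv", index=False)
        except OSError as e:
            raise OSError(f"cannot write dataset under {root}: {e}") from e
    return images, np.asarray(labels), manifest
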