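"""End-to-end orchestration: enhance -> features -> train -> evaluate.

The handcrafted feature vector is the fixed-order concatenation
``[GLCM (6) | directional LBP (32) | HOG]`` computed on the luma of
the (optionally enhanced) image; at the nominal 256x256 working
resolution its length is 6 + 32 + 34,596 = 34,634.  A manifest records
segment offsets and a configuration hash so models refuse feature
matrices produced under a different configuration.

Because the three segments live on very different scales (GLCM ~1,
LBP histograms ~1e4, HOG ~1), features are z-scored per dimension
before the 1-D branch, with statistics fit on the training split only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import enhance as _enh
from . import glcm as _glcm
from . import hog as _hog
from . import lbp as _lbp
from .evaluation import confusion, metrics
from .image import resize_image, to_grayscale
from .nn.model import (SDNetConfig, TrainingConfig, build_model, predict,
                       train)
from .synthetic import SyntheticDatasetSpec, generate_dataset

__all__ = ["FeatureConfig", "PipelineConfig", "extract_features",
           "FittedPipeline", "fit_pipeline", "run_experiment"]


@dataclass(frozen=True)
class FeatureConfig:
    """Which descriptor segments to compute, and their parameters."""

    glcm: bool = True
    ilbp: bool = True
    hog: bool = True
    glcm_levels: int = 8
    glcm_distance: int = 1
    glcm_angle: float = 0.0
    hog_config: _hog.HOGConfig = field(default_factory=_hog.HOGConfig)
    image_size: tuple[int, int] = (256, 256)

    def __post_init__(self):
        if not (self.glcm or self.ilbp or self.hog):
            raise ValueError("at least one feature segment must be enabled")

    def segment_lengths(self) -> dict[str, int]:
        lengths = {}
        if self.glcm:
            lengths["glcm"] = 6
        if self.ilbp:
            lengths["ilbp"] = 32
        if self.hog:
            lengths["hog"] = _hog.hog_length(self.image_size, self.hog_config)
        return lengths

    @property
    def total_length(self) -> int:
        return sum(self.segment_lengths().values())

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _single_vector(gray: np.ndarray, config: FeatureConfig) -> np.ndarray:
    parts = []
    if config.glcm:
        g = _glcm.compute_glcm(gray, levels=config.glcm_levels,
                               distance=config.glcm_distance,
                               angle=config.glcm_angle)
        parts.append(_glcm.glcm_features(g).as_array())
    if config.ilbp:
        parts.append(_lbp.ilbp_features(gray))
    if config.hog:
        parts.append(_hog.hog_features(gray, config.hog_config))
    return np.concatenate(parts)


def extract_features(images, config: FeatureConfig = FeatureConfig()):
    """Handcrafted feature matrix plus a manifest of segment offsets.

    Each image is converted to luma and resized to the working
    resolution before the descriptors run.  Returns ``(X, manifest)``
    with ``X`` of shape ``(n_images, total_length)``.
    """
    rows = []
    for img in images:
        gray = resize_image(to_grayscale(img), config.image_size)
        rows.append(_single_vector(gray, config))
    X = np.vstack(rows) if rows else np.zeros((0, config.total_length))
    offsets, pos = {}, 0
    for name, ln in config.segment_lengths().items():
        offsets[name] = (pos, pos + ln)
        pos += ln
    manifest = {"segments": offsets, "total_length": pos,
                "config_hash": config.config_hash()}
    return X, manifest


@dataclass
class FittedPipeline:
    """A trained classifier with its preprocessing state."""

    model: object
    feature_config: FeatureConfig
    feature_hash: str
    mean: np.ndarray | None
    std: np.ndarray | None
    preprocess: bool

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            return X
        return (X - self.mean) / self.std

    def predict(self, images, X, manifest: dict | None = None):
        if manifest is not None:
            self.check_manifest(manifest)
        labels, probs = predict(self.model, images, self.transform(X))
        return labels, probs

    def check_manifest(self, manifest: dict):
        """Refuse feature matrices built under a different configuration."""
        if manifest.get("config_hash") != self.feature_hash:
            raise ValueError(
                "feature manifest hash does not match the configuration "
                "this pipeline was fitted with")


@dataclass(frozen=True)
class PipelineConfig:
    """One experiment: data, preprocessing arms and model variants."""

    dataset: SyntheticDatasetSpec = field(default_factory=SyntheticDatasetSpec)
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    model_config: SDNetConfig = field(default_factory=SDNetConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    preprocessing_arms: tuple[bool, ...] = (False, True)
    variants: tuple[str, ...] = ("sdnet", "2d", "1d")
    standardize: bool = True
    seed: int = 0


def _prepare_inputs(images, pipe_cfg: PipelineConfig, preprocess: bool):
    """Resize; optionally enhance the CNN image input.

    Handcrafted descriptors are always computed on the original
    (un-enhanced) grayscale: they characterize the physical texture of
    the lesion, and contrast renormalization inside the enhancement
    would distort the calibrated magnitudes they rely on.  Enhancement
    conditions only what the 2-D branch sees.
    """
    size = pipe_cfg.feature_config.image_size
    resized = [resize_image(img, size) for img in images]
    X, manifest = extract_features(resized, pipe_cfg.feature_config)
    if preprocess:
        resized = [_enh.ictef_enhance(img) for img in resized]
    imgs = np.stack(resized).astype(np.float32)
    return imgs, X, manifest


def fit_pipeline(images, labels, pipe_cfg: PipelineConfig,
                 preprocess: bool = True, variant: str = "sdnet"):
    """Train one model variant; returns the fitted pipeline + report.

    ``variant`` selects both branches ("sdnet") or a single-branch
    ablation ("2d" / "1d").
    """
    imgs, X, manifest = _prepare_inputs(images, pipe_cfg, preprocess)
    branch = {"sdnet": "both", "2d": "2d", "1d": "1d"}[variant]
    model_cfg = dataclasses.replace(
        pipe_cfg.model_config, branch=branch,
        input_image_size=pipe_cfg.feature_config.image_size,
        input_vector_length=X.shape[1],
        num_classes=int(np.max(labels)) + 1)
    model = build_model(model_cfg, seed=pipe_cfg.seed)

    tc = dataclasses.replace(pipe_cfg.training, seed=pipe_cfg.seed)
    labels = np.asarray(labels)

    # standardization statistics from the training split only
    from .nn.model import _stratified_split
    tr_idx, te_idx = _stratified_split(labels, tc.split, tc.seed)
    if pipe_cfg.standardize:
        mean = X[tr_idx].mean(axis=0)
        std = X[tr_idx].std(axis=0)
        std = np.where(std > 0, std, 1.0)
        Xs = (X - mean) / std
    else:
        mean = std = None
        Xs = X

    result = train(model, imgs, Xs, labels, tc)
    fitted = FittedPipeline(model=model, feature_config=pipe_cfg.feature_config,
                            feature_hash=manifest["config_hash"],
                            mean=mean, std=std, preprocess=preprocess)
    y_pred, _ = predict(model, imgs[result.test_idx], Xs[result.test_idx])
    rep = metrics(confusion(labels[result.test_idx], y_pred,
                            model_cfg.num_classes))
    report = {
        "variant": variant,
        "preprocess": preprocess,
        "test_metrics": rep.as_dict(),
        "confusion_matrix": confusion(labels[result.test_idx], y_pred,
                                      model_cfg.num_classes).matrix.tolist(),
        "final_train_loss": result.history[-1]["train_loss"],
        "final_train_accuracy": result.history[-1]["train_accuracy"],
        "n_train": int(result.train_idx.size),
        "n_test": int(result.test_idx.size),
    }
    return fitted, result, report


def run_experiment(pipe_cfg: PipelineConfig) -> dict:
    """Run all requested preprocessing arms x model variants.

    Returns a JSON-serializable report with one metric block per
    (arm, variant) pair and the configuration snapshot; identical
    configurations and seeds reproduce identical reports.
    """
    images, labels, _ = generate_dataset(pipe_cfg.dataset)
    blocks = []
    for preprocess in pipe_cfg.preprocessing_arms:
        for variant in pipe_cfg.variants:
            _, _, report = fit_pipeline(images, labels, pipe_cfg,
                                        preprocess=preprocess,
                                        variant=variant)
            blocks.append(report)
    snapshot = json.loads(json.dumps(dataclasses.asdict(pipe_cfg),
                                     default=str))
    return {"config": snapshot, "blocks": blocks}
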