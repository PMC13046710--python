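"""Shared fixtures.

The expensive end-to-end trainings (parameter recovery on the clean
5-class synthetic dataset, and the enhancement comparison on its
noise-degraded variant) are session-scoped so several tests can share
one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from dermatex.hog import HOGConfig
from dermatex.nn.model import SDNetConfig, TrainingConfig
from dermatex.pipeline import FeatureConfig, PipelineConfig, fit_pipeline
from dermatex.synthetic import SyntheticDatasetSpec, generate_dataset

# Scaled-down study conditions: 128 px working resolution, 16-px HOG
# cells, (8, 16, 32) filters, 40 epochs with the x0.5 step decay
# rescaled to every 15 epochs.
RECOVERY_SIZE = (128, 128)
RECOVERY_SEED = 7


def recovery_config(noise_sigma: float = 0.0, seed: int = RECOVERY_SEED,
                    **training_kw) -> PipelineConfig:
    return PipelineConfig(
        dataset=SyntheticDatasetSpec(counts=40, image_size=RECOVERY_SIZE,
                                     noise_sigma=noise_sigma, seed=seed),
        feature_config=FeatureConfig(image_size=RECOVERY_SIZE,
                                     hog_config=HOGConfig(cell=16)),
        model_config=SDNetConfig(conv2d_filters=(8, 16, 32),
                                 conv1d_filters=(8, 16, 32),
                                 input_image_size=RECOVERY_SIZE),
        training=TrainingConfig(epochs=40, decay_every=15, seed=seed),
        seed=seed)


@pytest.fixture(scope="session")
def recovery_run():
    """SDNet trained on the clean, well-separated 5-class dataset."""
    cfg = recovery_config()
    images, labels, manifest = generate_dataset(cfg.dataset)
    fitted, result, report = fit_pipeline(images, labels, cfg,
                                          preprocess=False, variant="sdnet")
    return {"config": cfg, "images": images, "labels": labels,
            "manifest": manifest, "fitted": fitted, "result": result,
            "report": report}


@pytest.fixture(scope="session")
def noisy_comparison():
    """Both preprocessing arms trained on the noise-degraded dataset.

    The comparison uses the image-branch (2-D) classifier: enhancement
    acts on the images, and on this synthetic family the descriptor
    branch alone already saturates the fused model's accuracy, which
    would mask the effect being measured.
    """
    cfg = recovery_config(noise_sigma=0.1)
    images, labels, _ = generate_dataset(cfg.dataset)
    out = {}
    for pre in (False, True):
        _, _, report = fit_pipeline(images, labels, cfg, preprocess=pre,
                                    variant="2d")
        out[pre] = report
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
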