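"""The dual-branch classifier (SDNet).

Two parallel feature extractors feed one fully connected softmax
head:

* the 2-D branch ingests ``H x W x 3`` images through three blocks of
  ``Conv2D(3x3, same) -> ReLU -> BatchNorm -> MaxPool(2x2, stride 2)``
  with 64/128/256 filters, then flattens;
* the 1-D branch ingests the handcrafted descriptor vector (GLCM +
  directional-LBP + HOG) through the analogous three
  ``Conv1D -> ReLU -> BatchNorm -> MaxPool`` blocks, then flattens.

The flattened deep features are concatenated (image branch first) and
projected by a single fully connected layer onto class logits; softmax
yields the class posterior.  At the nominal 256x256 input and a
34,596-long feature vector the flatten lengths are 262,144 and
1,106,944 (concatenation 1,369,088), and the per-layer trainable
parameter counts follow the standard formulas (``k_h k_w C_in C_out +
C_out`` for Conv2D, ``k C_in C_out + C_out`` for Conv1D, ``2C`` for
BatchNorm).

Either branch can be disabled (``branch="2d"`` / ``"1d"``) to obtain
the single-branch ablations with the same head structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .layers import (Adam, BatchNorm, Conv1D, Conv2D, Dense, Flatten,
                     MaxPool1D, MaxPool2D, ReLU, Sequential, softmax,
                     softmax_cross_entropy)

__all__ = ["SDNetConfig", "TrainingConfig", "SDNetModel", "build_model",
           "count_parameters", "train", "predict", "TrainResult"]


@dataclass(frozen=True)
class SDNetConfig:
    num_classes: int = 5
    conv2d_filters: tuple[int, ...] = (64, 128, 256)
    conv1d_filters: tuple[int, ...] = (64, 128, 256)
    kernel2d: int = 3
    kernel1d: int = 3
    input_image_size: tuple[int, int] = (256, 256)
    input_vector_length: int = 34_634   # 6 GLCM + 32 ILBP + 34,596 HOG
    fc_bias: bool = True
    branch: str = "both"                # "both" | "2d" | "1d"

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.branch not in ("both", "2d", "1d"):
            raise ValueError("branch must be 'both', '2d' or '1d'")
        if min(self.conv2d_filters) < 1 or min(self.conv1d_filters) < 1:
            raise ValueError("filter counts must be positive")
        if len(self.conv2d_filters) != len(self.conv1d_filters):
            raise ValueError("both branches must have the same depth")

    @classmethod
    def table_compat(cls) -> "SDNetConfig":
        """Accounting configuration reproducing the nominal printed
        architecture: HOG-only 34,596 input, 4 output units, biasless
        fully connected head."""
        return cls(num_classes=4, input_vector_length=34_596, fc_bias=False)


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    decay_rate: float = 0.5
    decay_every: int = 50       # epochs between step decays
    epochs: int = 200
    split: float = 0.3          # held-out fraction of a 70:30 split
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.learning_rate:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.split < 1.0:
            raise ValueError("split must be a fraction in (0, 1)")


class SDNetModel:
    """Built network: two branch stacks and the fusion head."""

    def __init__(self, config: SDNetConfig, branch2d: Sequential | None,
                 branch1d: Sequential | None, head: Dense,
                 flatten2d: int, flatten1d: int):
        self.config = config
        self.branch2d = branch2d
        self.branch1d = branch1d
        self.head = head
        self.flatten2d = flatten2d
        self.flatten1d = flatten1d

    # -- structure ----------------------------------------------------
    @property
    def fusion_length(self) -> int:
        return self.flatten2d + self.flatten1d

    def params(self):
        out = []
        for part in (self.branch2d, self.branch1d, self.head):
            if part is not None:
                out.extend(part.params())
        return out

    def last_conv2d(self) -> Conv2D:
        if self.branch2d is None:
            raise ValueError("model has no 2-D branch")
        return [l for l in self.branch2d.layers if isinstance(l, Conv2D)][-1]

    # -- inference ----------------------------------------------------
    def _branch_outputs(self, images, features, train=False):
        outs = []
        if self.branch2d is not None:
            outs.append(self.branch2d.forward(
                np.asarray(images, dtype=np.float32), train=train))
        if self.branch1d is not None:
            x1 = np.asarray(features, dtype=np.float32)[:, :, None]
            outs.append(self.branch1d.forward(x1, train=train))
        return outs

    def logits(self, images, features, train=False) -> np.ndarray:
        outs = self._branch_outputs(images, features, train=train)
        fused = np.concatenate(outs, axis=1) if len(outs) > 1 else outs[0]
        return self.head.forward(fused, train=train)

    def forward(self, images, features) -> np.ndarray:
        """Class-probability rows (inference mode)."""
        return softmax(self.logits(images, features, train=False))

    def backward_from_logits(self, dlogits: np.ndarray):
        """Backpropagate a logit gradient through head and branches."""
        dfused = self.head.backward(dlogits)
        if self.branch2d is not None and self.branch1d is not None:
            d2, d1 = dfused[:, : self.flatten2d], dfused[:, self.flatten2d:]
            self.branch2d.backward(d2)
            self.branch1d.backward(d1)
        elif self.branch2d is not None:
            self.branch2d.backward(dfused)
        else:
            self.branch1d.backward(dfused)


def _conv_block_2d(c_in, c_out, k, idx, rng):
    return [Conv2D(c_in, c_out, k, rng=rng, name=f"conv2d_{idx}"),
            ReLU(name=f"relu2d_{idx}"),
            BatchNorm(c_out, name=f"batchnorm2d_{idx}"),
            MaxPool2D(name=f"maxpool2d_{idx}")]


def _conv_block_1d(c_in, c_out, k, idx, rng):
    return [Conv1D(c_in, c_out, k, rng=rng, name=f"conv1d_{idx}"),
            ReLU(name=f"relu1d_{idx}"),
            BatchNorm(c_out, name=f"batchnorm1d_{idx}"),
            MaxPool1D(name=f"maxpool1d_{idx}")]


def build_model(config: SDNetConfig, seed: int = 0) -> SDNetModel:
    """Construct the network and compute its flatten/fusion lengths."""
    rng = np.random.default_rng(seed)

    branch2d = flatten2d = None
    if config.branch in ("both", "2d"):
        layers, c_in = [], 3
        h, w = config.input_image_size
        for i, c_out in enumerate(config.conv2d_filters, start=1):
            layers += _conv_block_2d(c_in, c_out, config.kernel2d, i, rng)
            c_in = c_out
            h, w = h // 2, w // 2   # pooling floors odd extents
        layers.append(Flatten(name="flatten2d"))
        branch2d = Sequential(layers, name="branch2d")
        flatten2d = h * w * c_in
    flatten2d = flatten2d or 0

    branch1d = flatten1d = None
    if config.branch in ("both", "1d"):
        layers, c_in = [], 1
        length = config.input_vector_length
        for i, c_out in enumerate(config.conv1d_filters, start=1):
            layers += _conv_block_1d(c_in, c_out, config.kernel1d, i, rng)
            c_in = c_out
            length = length // 2
        layers.append(Flatten(name="flatten1d"))
        branch1d = Sequential(layers, name="branch1d")
        flatten1d = length * c_in
    flatten1d = flatten1d or 0

    head = Dense(flatten2d + flatten1d, config.num_classes,
                 bias=config.fc_bias, rng=rng, name="fc")
    return SDNetModel(config, branch2d, branch1d, head, flatten2d, flatten1d)


def count_parameters(model: SDNetModel):
    """Per-layer trainable parameter counts and the total.

    Returns ``(table, total)`` where ``table`` is a list of
    ``(layer_name, count)`` rows; layers without parameters are
    reported with 0 so the table mirrors the full stack.
    """
    table = []
    for part in (model.branch2d, model.branch1d):
        if part is None:
            continue
        for layer in part.layers:
            table.append((layer.name, sum(p.size for p in layer.params())))
    table.append((model.head.name, sum(p.size for p in model.head.params())))
    return table, sum(c for _, c in table)


@dataclass
class TrainResult:
    model: SDNetModel
    history: list[dict]
    train_idx: np.ndarray
    test_idx: np.ndarray


def _stratified_split(labels: np.ndarray, test_fraction: float, seed: int):
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes to stratify the split")
    idx = np.arange(labels.size)
    tr, te = train_test_split(idx, test_size=test_fraction, stratify=labels,
                              random_state=seed)
    return np.sort(tr), np.sort(te)


def train(model: SDNetModel, images, features, labels,
          tc: TrainingConfig = TrainingConfig()) -> TrainResult:
    """Train on a stratified 70:30-style split with Adam + step decay.

    ``images`` is ``(N, H, W, 3)`` (ignored by 1-D-only models),
    ``features`` ``(N, L)`` (ignored by 2-D-only models), ``labels``
    integer classes.  The learning rate is multiplied by
    ``tc.decay_rate`` every ``tc.decay_every`` epochs.  History holds
    per-epoch mean train loss and train accuracy; everything is
    deterministic for a fixed ``tc.seed``.
    """
    labels = np.asarray(labels)
    tr_idx, te_idx = _stratified_split(labels, tc.split, tc.seed)
    rng = np.random.default_rng(tc.seed)
    opt = Adam(model.params(), lr=tc.learning_rate)

    imgs = np.asarray(images, dtype=np.float32)
    feats = np.asarray(features, dtype=np.float32)
    y = labels
    history = []
    for epoch in range(tc.epochs):
        if epoch > 0 and tc.decay_every > 0 and epoch % tc.decay_every == 0:
            opt.lr *= tc.decay_rate
        perm = rng.permutation(tr_idx)
        losses, n_correct = [], 0
        for start in range(0, perm.size, tc.batch_size):
            batch = perm[start:start + tc.batch_size]
            logits = model.logits(imgs[batch], feats[batch], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[batch])
            opt.zero_grad()
            model.backward_from_logits(dlogits)
            opt.step()
            losses.append(loss)
            n_correct += int((logits.argmax(axis=1) == y[batch]).sum())
        history.append({"epoch": epoch,
                        "train_loss": float(np.mean(losses)),
                        "train_accuracy": n_correct / perm.size,
                        "lr": opt.lr})
    return TrainResult(model=model, history=history,
                       train_idx=tr_idx, test_idx=te_idx)


def predict(model: SDNetModel, images, features, batch_size: int = 64):
    """Argmax labels and probabilities, preserving batch order.

    Probability ties resolve to the lowest class index (argmax rule).
    """
    n = len(np.asarray(features if model.branch2d is None else images))
    if n == 0:
        k = model.config.num_classes
        return np.zeros(0, dtype=int), np.zeros((0, k))
    all_probs = []
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        imgs = np.asarray(images)[sl] if model.branch2d is not None else None
        fts = np.asarray(features)[sl] if model.branch1d is not None else None
        all_probs.append(model.forward(imgs, fts))
    probs = np.concatenate(all_probs, axis=0)
    return probs.argmax(axis=1), probs
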