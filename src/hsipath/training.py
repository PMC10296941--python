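"""Training loops, the staged transfer protocol and evaluation metrics.

Classes are encoded 0 = normal, 1 = cancer throughout; "positive" in
the metrics means cancer, so sensitivity is the fraction of cancer
samples detected — the indicator clinicians weight most, since a higher
sensitivity means fewer missed lesions.

The transfer protocol mirrors staged fine-tuning: (1) train a
classification head on the large conventional-pathology set to get the
transfer backbone; (2) re-head and train on the target set at a low
learning rate; (3) fine-tune with all backbone blocks before the last
frozen (defaults: SGD, lr 0.0008, batch 50, 17 epochs).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn

__all__ = [
    "TrainConfig",
    "EvalReport",
    "TrainResult",
    "train",
    "evaluate",
    "freeze_through",
    "transfer_pipeline",
    "TransferResult",
]

LABELS = {"normal": 0, "cancer": 1}


@dataclass
class TrainConfig:
    """SGD hyperparameters; the defaults are the full-scale protocol
    (batch 128, lr 1e-4, momentum 0.9, 30 epochs, shuffled)."""

    batch_size: int = 128
    learning_rate: float = 1e-4
    momentum: float = 0.9
    epochs: int = 30
    optimizer: str = "sgd"
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "sgd":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class EvalReport:
    """Confusion counts and derived metrics at a probability threshold."""

    tp: int
    fp: int
    tn: int
    fn: int
    probabilities: np.ndarray = field(repr=False, default=None)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")


@dataclass
class TrainResult:
    model: nn.Network
    history: dict[str, list[float]]


def _check_dataset(y: np.ndarray) -> None:
    classes = np.unique(y)
    if len(y) == 0:
        raise ValueError("dataset is empty")
    if len(classes) < 2:
        raise ValueError("dataset must contain both classes")


def train(
    model: nn.Network,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TrainResult:
    """SGD training with per-epoch loss/accuracy history.

    Samples are reshuffled every epoch (seeded); given identical data,
    config and seed the final weights are bit-identical across runs.
    """
    x = np.ascontiguousarray(x, dtype=np.float32)
    y = np.asarray(y)
    _check_dataset(y)
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(model.params(), lr=config.learning_rate, momentum=config.momentum)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
    }
    n = len(x)
    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, train=True)
            loss, grad = nn.cross_entropy(logits, yb)
            model.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
        history["train_loss"].append(sum(losses) / n)
        history["train_acc"].append(correct / n)
        if x_val is not None:
            report = evaluate(model, x_val, y_val)
            logits = np.log(np.maximum(report.probabilities, 1e-30))
            vloss = -logits[np.arange(len(y_val)), y_val].mean()
            history["val_loss"].append(float(vloss))
            history["val_acc"].append(report.accuracy)
    return TrainResult(model=model, history=history)


def evaluate(
    model: nn.Network,
    x: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.5,
) -> EvalReport:
    """Confusion counts at the given cancer-probability threshold."""
    probs = model.predict_proba(np.ascontiguousarray(x, dtype=np.float32))
    y = np.asarray(y)
    pred = probs[:, LABELS["cancer"]] >= threshold
    actual = y == LABELS["cancer"]
    return EvalReport(
        tp=int((pred & actual).sum()),
        fp=int((pred & ~actual).sum()),
        tn=int((~pred & ~actual).sum()),
        fn=int((~pred & actual).sum()),
        probabilities=probs,
    )


def freeze_through(model: nn.Network, last_frozen_block: int) -> nn.Network:
    """Mark parameters in blocks 1..last_frozen_block non-trainable.

    Block tags come from the architecture spec (0 = stem/head, which is
    never frozen by this operation).  ``freeze_through(0)`` makes
    everything trainable again.
    """
    tags = {layer.block for layer in model.layers}
    if last_frozen_block < 0 or (last_frozen_block > 0 and last_frozen_block not in tags):
        raise ValueError(f"no block {last_frozen_block} in this model")
    for layer in model.layers:
        frozen = 1 <= layer.block <= last_frozen_block
        for p in layer.params():
            p.trainable = not frozen
    return model


def _re_head(model: nn.Network, rng: np.random.Generator) -> nn.Network:
    """Replace the final dense layer with a freshly initialized one."""
    model = copy.deepcopy(model)
    for i in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[i]
        if isinstance(layer, nn.Dense):
            n_in, n_out = layer.w.data.shape
            fresh = nn.Dense(n_in, n_out, rng=rng, name=layer.w.name.rsplit(".", 1)[0])
            fresh.block = layer.block
            model.layers[i] = fresh
            return model
    raise ValueError("model has no dense head to replace")


@dataclass
class TransferResult:
    stages: dict[str, TrainResult]

    def model(self, stage: str) -> nn.Network:
        return self.stages[stage].model


def transfer_pipeline(
    backbone: nn.Network,
    pretrain_set: tuple[np.ndarray, np.ndarray],
    target_set: tuple[np.ndarray, np.ndarray],
    stage_configs: dict[str, TrainConfig] | None = None,
    last_frozen_block: int | None = None,
    seed: int = 0,
) -> TransferResult:
    """Three-stage transfer: pretrain -> re-head + low-lr train -> fine-tune.

    Stage names in the result: ``trans`` (backbone + head trained on the
    pretrain set), ``stage1`` (re-headed and trained on the target set
    at a low learning rate with the pretrained conv blocks fixed) and
    ``stage2`` (fine-tuned with every backbone block before the last
    frozen, i.e. only the last conv block and the head learn).
    """
    configs = {
        "trans": TrainConfig(batch_size=50, learning_rate=0.005, epochs=5, seed=seed),
        "stage1": TrainConfig(batch_size=50, learning_rate=0.001, epochs=5, seed=seed + 1),
        "stage2": TrainConfig(batch_size=50, learning_rate=0.0008, epochs=17, seed=seed + 2),
    }
    if stage_configs:
        configs.update(stage_configs)
    rng = np.random.default_rng(seed)
    if pretrain_set[0].shape[1:] != target_set[0].shape[1:]:
        raise ValueError("pretrain and target sample shapes differ")

    trans = train(backbone, *pretrain_set, configs["trans"])

    model1 = _re_head(trans.model, rng)
    blocks = sorted({l.block for l in model1.layers if l.block > 0})
    if blocks:
        freeze_through(model1, blocks[-1])  # head-only warm-up
    stage1 = train(model1, *target_set, configs["stage1"])

    model2 = copy.deepcopy(stage1.model)
    if last_frozen_block is None:
        last_frozen_block = blocks[-2] if len(blocks) > 1 else 0
    freeze_through(model2, last_frozen_block)
    stage2 = train(model2, *target_set, configs["stage2"])

    return TransferResult(stages={"trans": trans, "stage1": stage1, "stage2": stage2})
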