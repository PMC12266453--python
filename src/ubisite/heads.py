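"""Stand-alone downstream classifiers for lysine-site features.

Two architectures, usable on raw protein-language-model embeddings or on
the latent codes of a trained conditional VAE:

* ``dnn_linear`` — a plain MLP: affine + batch-norm + leaky-ReLU hidden
  layers ending in a single-logit affine layer;
* ``res_dnn`` — ``num_blocks`` residual blocks (two FC layers each, with
  an identity skip when the widths match and an affine skip otherwise)
  ending in the same single-logit layer.

Both minimise binary cross-entropy on logits with Adam + decoupled weight
decay, optionally up-weighting the minority positive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .cvae import TrainingDivergenceError, cls_loss

DNN_LINEAR = "dnn_linear"
RES_DNN = "res_dnn"

#: probability cutoff used when converting scores to site labels
DEFAULT_DECISION_THRESHOLD = 0.4


@dataclass
class HeadConfig:
    """Hyperparameters of a downstream classifier head."""

    architecture: str = RES_DNN
    input_dim: int = 100
    layer_dims: list[int] = field(default_factory=lambda: [64])
    num_blocks: int = 1
    learning_rate: float = 1e-4
    weight_decay: float = 8e-3
    epochs: int = 50
    batch_size: int = 64
    class_weighting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in (DNN_LINEAR, RES_DNN):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not self.layer_dims:
            raise ValueError("layer_dims must be non-empty")
        if self.architecture == RES_DNN and self.num_blocks < 1:
            raise ValueError("num_blocks must be >= 1 for res_dnn")


def build_res_block(in_dim: int, out_dim: int,
                    rng: np.random.Generator | None = None,
                    name: str = "res") -> _nn.ResBlock:
    """One residual block; identity skip iff ``in_dim == out_dim``."""
    if in_dim < 1 or out_dim < 1:
        raise ValueError("dimensions must be >= 1")
    rng = rng or np.random.Generator(np.random.PCG64(0))
    return _nn.ResBlock(in_dim, out_dim, rng, name=name)


class ClassifierHead:
    """A trained classifier; build via :func:`fit_head`."""

    def __init__(self, config: HeadConfig) -> None:
        self.config = config
        rng = np.random.Generator(np.random.PCG64(config.seed))
        self._rng = rng
        if config.architecture == DNN_LINEAR:
            trunk, out_dim = _nn.dense_stack(config.input_dim,
                                             config.layer_dims, rng, "head")
        else:
            trunk, out_dim = _nn.res_stack(config.input_dim,
                                           config.layer_dims,
                                           config.num_blocks, rng, "head")
        self.net = _nn.Sequential(
            trunk.layers + [_nn.Linear(out_dim, 1, rng, "head.out")])
        self.training_history: list[float] = []
        self.pos_weight_: float | None = None

    def parameters(self) -> list[_nn.Parameter]:
        return self.net.parameters()

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ValueError(f"expected (n, {self.config.input_dim}), "
                             f"got {x.shape}")
        return x

    def predict_logits(self, features: np.ndarray) -> np.ndarray:
        return self.net.forward(self._check(features), train=False).ravel()

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return _nn.sigmoid(self.predict_logits(features))

    def predict_label(self, features: np.ndarray,
                      threshold: float = DEFAULT_DECISION_THRESHOLD
                      ) -> np.ndarray:
        return (self.predict_proba(features) >= threshold).astype(np.int64)

    def input_gradient(self, features: np.ndarray) -> np.ndarray:
        """d(logit)/d(input) per row, for gradient-based attribution."""
        x = self._check(features)
        self.net.forward(x, train=False)
        g = self.net.backward(np.ones((x.shape[0], 1)))
        for p in self.parameters():
            p.grad[...] = 0.0
        return g

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps(
            {"kind": "head", "config": asdict(self.config),
             "pos_weight": self.pos_weight_}, indent=2))
        _nn.save_arrays(directory / "params.bin", _nn.state_dict([self.net]))

    @classmethod
    def load(cls, directory: str | Path) -> "ClassifierHead":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        if meta.get("kind") != "head":
            raise ValueError(f"{directory}: not a classifier-head checkpoint")
        head = cls(HeadConfig(**meta["config"]))
        head.pos_weight_ = meta.get("pos_weight")
        _nn.load_state([head.net], _nn.load_arrays(directory / "params.bin"))
        return head


def fit_head(features: np.ndarray, labels: Sequence[int] | np.ndarray,
             config: HeadConfig | None = None) -> ClassifierHead:
    """Train a classifier head; reproducible from ``config.seed``."""
    x_all = np.asarray(features, dtype=np.float64)
    y_all = np.asarray(labels).ravel()
    if x_all.shape[0] != y_all.shape[0]:
        raise ValueError(f"{x_all.shape[0]} rows but {y_all.shape[0]} labels")
    if not np.isin(y_all, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    if len(np.unique(y_all)) < 2:
        raise ValueError("training labels contain a single class")
    if config is None:
        config = HeadConfig(input_dim=x_all.shape[1])
    if x_all.shape[1] != config.input_dim:
        raise ValueError(f"features have dim {x_all.shape[1]}, config expects "
                         f"{config.input_dim}")

    head = ClassifierHead(config)
    rng = head._rng
    pw: float | None = None
    if config.class_weighting:
        n_pos = int(y_all.sum())
        pw = (y_all.size - n_pos) / n_pos
        head.pos_weight_ = pw
    opt = _nn.AdamW(head.parameters(), lr=config.learning_rate,
                    weight_decay=config.weight_decay)
    n = x_all.shape[0]
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        batches = [perm[i:i + config.batch_size]
                   for i in range(0, n, config.batch_size)]
        if len(batches) > 1 and len(batches[-1]) == 1:
            batches[-2] = np.concatenate([batches[-2], batches[-1]])
            batches.pop()
        epoch_loss, seen = 0.0, 0
        for batch in batches:
            x, y = x_all[batch], y_all[batch].astype(np.float64)
            b = x.shape[0]
            opt.zero_grad()
            logits = head.net.forward(x, train=True).ravel()
            loss = cls_loss(logits, y_all[batch], pos_weight=pw)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch}")
            pw_eff = 1.0 if pw is None else pw
            sig = _nn.sigmoid(logits)
            g = (pw_eff * y * (sig - 1.0) + (1.0 - y) * sig) / b
            head.net.backward(g[:, None])
            opt.step()
            epoch_loss += loss * b
            seen += b
        head.training_history.append(epoch_loss / seen)
    return head


def predict_head(head: ClassifierHead, features: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`ClassifierHead.predict_proba`."""
    return head.predict_proba(features)
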