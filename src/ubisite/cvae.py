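"""Conditional variational autoencoder with a classification head.

The model compresses high-dimensional per-lysine embeddings into a
low-dimensional Gaussian latent code (mean ``mu`` and log-variance
``log_var`` per sample) through a residual encoder, reconstructs them
through a residual decoder, and attaches a classification head to the
latent code so the bottleneck is shaped by the ubiquitination labels while
it reconstructs.  Training minimises

    L = alpha * L_rec + beta * L_kld + gamma * L_cls

where L_rec is the mean squared reconstruction error over all entries,
L_kld the KL divergence of the latent Gaussian from the standard-normal
prior (averaged over the batch), and L_cls the binary cross-entropy of the
head's logits (optionally weighting the minority positive class).

Inference is deterministic: the latent code used for encoding and for the
classification head is ``mu``; a fresh standard-normal ``eps`` enters only
during training through the reparameterization ``z = mu + eps*exp(log_var/2)``.

Optimisation uses Adam with decoupled weight decay; one root seed drives
parameter initialisation, the ``eps`` draws and batch shuffling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .embedding import EmbeddingTable, batch_sites

LOG_VAR_CLAMP = 10.0


class TrainingDivergenceError(RuntimeError):
    """Raised when a non-finite loss appears during training."""


# ---------------------------------------------------------------------------
# loss primitives


def reparameterize(mu: np.ndarray, log_var: np.ndarray,
                   eps: np.ndarray) -> np.ndarray:
    """z = mu + eps * exp(log_var / 2), elementwise."""
    mu = np.asarray(mu, dtype=np.float64)
    log_var = np.asarray(log_var, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if not (mu.shape == log_var.shape == eps.shape):
        raise ValueError(f"shape mismatch: mu {mu.shape}, log_var "
                         f"{log_var.shape}, eps {eps.shape}")
    return mu + eps * np.exp(0.5 * log_var)


def rec_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared reconstruction error over all N*d entries."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    return float(np.mean((y_true - y_pred) ** 2))


def kld_loss(mu: np.ndarray, log_var: np.ndarray) -> float:
    """KL divergence of N(mu, exp(log_var)) from N(0, I), batch-averaged.

    -(1/2N) * sum_n sum_j (1 + log_var - mu^2 - exp(log_var)); non-negative
    for all inputs, zero exactly at the prior itself.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    log_var = np.atleast_2d(np.asarray(log_var, dtype=np.float64))
    if mu.shape != log_var.shape:
        raise ValueError(f"shape mismatch: {mu.shape} vs {log_var.shape}")
    n = mu.shape[0]
    return float(-0.5 / n * np.sum(1.0 + log_var - mu ** 2 - np.exp(log_var)))


def cls_loss(logits: np.ndarray, labels: np.ndarray,
             pos_weight: float | None = None) -> float:
    """Binary cross-entropy from logits, numerically stable.

    Uses log(sigmoid(t)) = -softplus(-t) and log(1 - sigmoid(t)) =
    -t - softplus(-t), so no probability is ever formed or clipped.
    ``pos_weight`` multiplies the positive-class term (minority up-weighting).
    """
    logits = np.asarray(logits, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if logits.shape != labels.shape:
        raise ValueError(f"length mismatch: {logits.shape} vs {labels.shape}")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    y = labels.astype(np.float64)
    pw = 1.0 if pos_weight is None else float(pos_weight)
    sp = _nn.softplus(-logits)
    per_sample = pw * y * sp + (1.0 - y) * (logits + sp)
    return float(per_sample.mean())


def total_loss(rec: float, kld: float, cls: float, alpha: float = 1.0,
               beta: float = 1.0, gamma: float = 1.0) -> float:
    """alpha*rec + beta*kld + gamma*cls."""
    return float(alpha * rec + beta * kld + gamma * cls)


# ---------------------------------------------------------------------------
# model


@dataclass
class CvaeConfig:
    """Hyperparameters of the conditional VAE.

    Defaults mirror the deployed configuration: 2560-dimensional input
    features compressed to a 100-dimensional latent code, AdamW with
    learning rate 1e-4 and weight decay 8e-3, and unit loss weights
    (a beta=0.3 variant is a documented alternative).  ``num_blocks``
    residual blocks form the encoder and decoder trunks, their widths
    cycling through ``encoder_layer_dims`` / ``decoder_layer_dims``.
    """

    input_dim: int = 2560
    latent_dim: int = 100
    encoder_layer_dims: list[int] = field(default_factory=lambda: [256])
    decoder_layer_dims: list[int] = field(default_factory=lambda: [256])
    cls_hidden_dims: list[int] = field(default_factory=list)
    num_blocks: int = 1
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    learning_rate: float = 1e-4
    weight_decay: float = 8e-3
    epochs: int = 50
    batch_size: int = 64
    class_weighting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim >= self.input_dim:
            raise ValueError("latent_dim must be smaller than input_dim")
        for name in ("alpha", "beta", "gamma", "weight_decay"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1 or self.num_blocks < 1:
            raise ValueError("epochs, batch_size and num_blocks must be >= 1")


@dataclass
class LatentCode:
    """Gaussian latent code of one site; ``z`` present only when sampled."""

    mu: np.ndarray
    log_var: np.ndarray
    z: np.ndarray | None = None


class CvaeModel:
    """Trained encoder/decoder/classifier state; build via :func:`fit_cvae`."""

    def __init__(self, config: CvaeConfig) -> None:
        self.config = config
        rng = np.random.Generator(np.random.PCG64(config.seed))
        self._rng = rng
        c = config
        self.encoder, enc_out = _nn.res_stack(
            c.input_dim, c.encoder_layer_dims, c.num_blocks, rng, "enc")
        self.mu_head = _nn.Linear(enc_out, c.latent_dim, rng, "mu")
        self.lv_head = _nn.Linear(enc_out, c.latent_dim, rng, "lv")
        self.decoder_trunk, dec_out = _nn.res_stack(
            c.latent_dim, c.decoder_layer_dims, c.num_blocks, rng, "dec")
        self.decoder_out = _nn.Linear(dec_out, c.input_dim, rng, "dec.out")
        cls_trunk, cls_out = _nn.dense_stack(
            c.latent_dim, c.cls_hidden_dims, rng, "cls")
        self.cls_head = _nn.Sequential(
            cls_trunk.layers + [_nn.Linear(cls_out, 1, rng, "cls.out")])
        self.training_history: list[dict[str, float]] = []
        self.pos_weight_: float | None = None

    # -- internals ----------------------------------------------------------

    def _modules(self) -> list[_nn.Layer]:
        return [self.encoder, self.mu_head, self.lv_head,
                self.decoder_trunk, self.decoder_out, self.cls_head]

    def parameters(self) -> list[_nn.Parameter]:
        return [p for m in self._modules() for p in m.parameters()]

    def _encode_raw(self, x: np.ndarray, train: bool
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = self.encoder.forward(x, train)
        mu = self.mu_head.forward(h, train)
        lv_raw = self.lv_head.forward(h, train)
        lv = np.clip(lv_raw, -LOG_VAR_CLAMP, LOG_VAR_CLAMP)
        return mu, lv, lv_raw

    def _check_dim(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ValueError(f"expected (n, {self.config.input_dim}) features, "
                             f"got {x.shape}")
        return x

    # -- public inference ----------------------------------------------------

    def encode(self, features: np.ndarray) -> list[LatentCode]:
        """Deterministic latent codes (mu/log_var; no sampling)."""
        x = self._check_dim(features)
        mu, lv, _ = self._encode_raw(x, train=False)
        return [LatentCode(mu=mu[i].copy(), log_var=lv[i].copy())
                for i in range(x.shape[0])]

    def encode_mu(self, features: np.ndarray) -> np.ndarray:
        """Latent mean matrix (n, latent_dim) — the deterministic code."""
        x = self._check_dim(features)
        mu, _, _ = self._encode_raw(x, train=False)
        return mu

    def reconstruct(self, features: np.ndarray) -> np.ndarray:
        x = self._check_dim(features)
        mu, _, _ = self._encode_raw(x, train=False)
        h = self.decoder_trunk.forward(mu, train=False)
        return self.decoder_out.forward(h, train=False)

    def predict_logits(self, features: np.ndarray) -> np.ndarray:
        x = self._check_dim(features)
        mu, _, _ = self._encode_raw(x, train=False)
        return self.cls_head.forward(mu, train=False).ravel()

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return _nn.sigmoid(self.predict_logits(features))

    def input_gradient(self, features: np.ndarray) -> np.ndarray:
        """d(logit)/d(input) per row, for gradient-based attribution."""
        x = self._check_dim(features)
        h = self.encoder.forward(x, train=False)
        mu = self.mu_head.forward(h, train=False)
        self.cls_head.forward(mu, train=False)
        g_mu = self.cls_head.backward(np.ones((x.shape[0], 1)))
        g_h = self.mu_head.backward(g_mu)
        g_x = self.encoder.backward(g_h)
        for p in self.parameters():
            p.grad[...] = 0.0
        return g_x

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        (directory / "config.json").write_text(json.dumps(
            {"kind": "cvae", "config": cfg, "pos_weight": self.pos_weight_},
            indent=2))
        _nn.save_arrays(directory / "params.bin",
                        _nn.state_dict(self._modules()))
        with open(directory / "history.tsv", "w") as fh:
            fh.write("epoch\trec_loss\tkld_loss\tcls_loss\ttotal_loss\n")
            for i, row in enumerate(self.training_history):
                fh.write(f"{i}\t{row['rec_loss']!r}\t{row['kld_loss']!r}\t"
                         f"{row['cls_loss']!r}\t{row['total_loss']!r}\n")

    @classmethod
    def load(cls, directory: str | Path) -> "CvaeModel":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        if meta.get("kind") != "cvae":
            raise ValueError(f"{directory}: not a cvae checkpoint")
        model = cls(CvaeConfig(**meta["config"]))
        model.pos_weight_ = meta.get("pos_weight")
        state = _nn.load_arrays(directory / "params.bin")
        _nn.load_state(model._modules(), state)
        history = (directory / "history.tsv")
        if history.exists():
            lines = history.read_text().strip().split("\n")[1:]
            for line in lines:
                _, rec, kld, cl, tot = line.split("\t")
                model.training_history.append(
                    {"rec_loss": float(rec), "kld_loss": float(kld),
                     "cls_loss": float(cl), "total_loss": float(tot)})
        return model


def _make_batches(n: int, table: EmbeddingTable | None, batch_size: int,
                  rng: np.random.Generator) -> list[np.ndarray]:
    """Batch index lists; same-protein sites stay grouped when known.

    The protein-group order is reshuffled every epoch so batch membership
    varies between epochs (plain SGD-style re-randomisation) while sites
    of one protein still travel together.
    """
    if table is not None:
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(table.sites):
            groups.setdefault(s.protein_id, []).append(i)
        group_list = [np.asarray(sorted(g, key=lambda i:
                                        table.sites[i].position))
                      for g in groups.values()]
        order = rng.permutation(len(group_list))
        batches = []
        current: list[int] = []
        for gi in order:
            g = group_list[gi]
            if len(g) > batch_size:
                if current:
                    batches.append(np.asarray(current))
                    current = []
                for start in range(0, len(g), batch_size):
                    chunk = g[start:start + batch_size]
                    if len(chunk) == batch_size:
                        batches.append(chunk)
                    else:
                        current = list(chunk)
                continue
            if len(current) + len(g) > batch_size:
                batches.append(np.asarray(current))
                current = []
            current.extend(g)
        if current:
            batches.append(np.asarray(current))
    else:
        perm = rng.permutation(n)
        batches = [perm[i:i + batch_size] for i in range(0, n, batch_size)]
    # batch-norm needs >= 2 samples per training batch: merge singletons
    merged: list[np.ndarray] = []
    for b in batches:
        if merged and (len(b) == 1 or len(merged[-1]) == 1):
            merged[-1] = np.concatenate([merged[-1], b])
        else:
            merged.append(b)
    return merged


def fit_cvae(features: EmbeddingTable | np.ndarray,
             labels: Sequence[int] | np.ndarray | None = None,
             config: CvaeConfig | None = None) -> CvaeModel:
    """Train a conditional VAE.

    ``features`` may be an :class:`EmbeddingTable` (same-protein sites are
    then kept in the same minibatch) or a plain (n, input_dim) matrix.
    ``labels`` defaults to the table's own labels.  Training is fully
    reproducible from ``config.seed``.
    """
    table = features if isinstance(features, EmbeddingTable) else None
    x_all = table.features if table is not None else np.asarray(
        features, dtype=np.float64)
    if labels is None:
        if table is None:
            raise ValueError("labels required when features is a plain matrix")
        labels = table.labels()
    y_all = np.asarray(labels).ravel()
    if config is None:
        config = CvaeConfig(input_dim=x_all.shape[1])
    if x_all.shape[0] != y_all.shape[0]:
        raise ValueError(f"{x_all.shape[0]} feature rows but "
                         f"{y_all.shape[0]} labels")
    if x_all.shape[1] != config.input_dim:
        raise ValueError(f"features have dim {x_all.shape[1]}, config expects "
                         f"{config.input_dim}")
    if not np.isin(y_all, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    if config.gamma > 0 and len(np.unique(y_all)) < 2:
        raise ValueError("training labels contain a single class")

    model = CvaeModel(config)
    rng = model._rng
    c = config
    pw: float | None = None
    if c.class_weighting and c.gamma > 0:
        n_pos = int(y_all.sum())
        n_neg = int(y_all.size - n_pos)
        pw = n_neg / n_pos
        model.pos_weight_ = pw
    opt = _nn.AdamW(model.parameters(), lr=c.learning_rate,
                    weight_decay=c.weight_decay)
    n, d = x_all.shape

    for epoch in range(c.epochs):
        sums = {"rec_loss": 0.0, "kld_loss": 0.0, "cls_loss": 0.0,
                "total_loss": 0.0}
        seen = 0
        for batch in _make_batches(n, table, c.batch_size, rng):
            x = x_all[batch]
            y = y_all[batch].astype(np.float64)
            b = x.shape[0]
            opt.zero_grad()

            mu, lv, lv_raw = model._encode_raw(x, train=True)
            eps = rng.standard_normal(mu.shape)
            z = reparameterize(mu, lv, eps)
            h = model.decoder_trunk.forward(z, train=True)
            xr = model.decoder_out.forward(h, train=True)

            rec = rec_loss(x, xr)
            kld = kld_loss(mu, lv)
            if c.gamma > 0:
                logits = model.cls_head.forward(z, train=True).ravel()
                cls = cls_loss(logits, y_all[batch], pos_weight=pw)
            else:
                cls = 0.0
            tot = total_loss(rec, kld, cls, c.alpha, c.beta, c.gamma)
            if not np.isfinite(tot):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch}")

            # backward: decoder path
            g_xr = c.alpha * 2.0 * (xr - x) / (b * d)
            g_h = model.decoder_out.backward(g_xr)
            g_z = model.decoder_trunk.backward(g_h)
            # classification path shares z
            if c.gamma > 0:
                pw_eff = 1.0 if pw is None else pw
                sig = _nn.sigmoid(logits)
                g_logit = (c.gamma / b) * (pw_eff * y * (sig - 1.0)
                                           + (1.0 - y) * sig)
                g_z = g_z + model.cls_head.backward(g_logit[:, None])
            # latent Gaussian parameters
            g_mu = g_z + c.beta * mu / b
            g_lv = (g_z * eps * 0.5 * np.exp(0.5 * lv)
                    + c.beta * (np.exp(lv) - 1.0) / (2.0 * b))
            g_lv = np.where(np.abs(lv_raw) < LOG_VAR_CLAMP, g_lv, 0.0)
            g_enc = model.mu_head.backward(g_mu) + model.lv_head.backward(g_lv)
            model.encoder.backward(g_enc)
            opt.step()

            sums["rec_loss"] += rec * b
            sums["kld_loss"] += kld * b
            sums["cls_loss"] += cls * b
            sums["total_loss"] += tot * b
            seen += b
        model.training_history.append(
            {k: v / seen for k, v in sums.items()})
    return model


def encode(model: CvaeModel, features: np.ndarray) -> list[LatentCode]:
    """Module-level alias for :meth:`CvaeModel.encode`."""
    return model.encode(features)


def predict_proba(model: CvaeModel, features: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`CvaeModel.predict_proba`."""
    return model.predict_proba(features)
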