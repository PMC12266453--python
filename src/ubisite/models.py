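"""The four deployable model variants and their common predictor surface.

* ``dnn_linear`` / ``res_dnn`` — a classifier head trained directly on the
  raw embeddings;
* ``cvae_dnn_linear`` / ``cvae_res_dnn`` — a conditional VAE first
  compresses the embeddings to latent means, then a head of the named
  architecture is trained on the latent codes.

Every variant exposes ``predict_proba``, ``predict_logits`` and
``input_gradient`` on raw features, so evaluation and attribution treat
them uniformly, and saves/loads through one checkpoint layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cvae import CvaeConfig, CvaeModel, fit_cvae
from .embedding import EmbeddingTable
from .heads import (DNN_LINEAR, RES_DNN, ClassifierHead, HeadConfig,
                    fit_head)

VARIANTS = ("dnn_linear", "res_dnn", "cvae_dnn_linear", "cvae_res_dnn")


class Predictor:
    """A trained variant: optional cVAE front end plus a classifier head."""

    def __init__(self, variant: str, head: ClassifierHead,
                 cvae: CvaeModel | None = None) -> None:
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; "
                             f"choose from {VARIANTS}")
        if variant.startswith("cvae_") != (cvae is not None):
            raise ValueError(f"variant {variant!r} and cVAE presence disagree")
        self.variant = variant
        self.head = head
        self.cvae = cvae

    @property
    def input_dim(self) -> int:
        return (self.cvae.config.input_dim if self.cvae is not None
                else self.head.config.input_dim)

    def _project(self, features: np.ndarray) -> np.ndarray:
        if self.cvae is None:
            return np.asarray(features, dtype=np.float64)
        return self.cvae.encode_mu(features)

    def predict_logits(self, features: np.ndarray) -> np.ndarray:
        return self.head.predict_logits(self._project(features))

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self.head.predict_proba(self._project(features))

    def input_gradient(self, features: np.ndarray) -> np.ndarray:
        """d(logit)/d(raw input), chained through the cVAE encoder when
        present."""
        if self.cvae is None:
            return self.head.input_gradient(features)
        x = self.cvae._check_dim(np.asarray(features, dtype=np.float64))
        # forward through encoder trunk and latent-mean head (eval mode),
        # then the classifier; backward in reverse over the same caches
        h = self.cvae.encoder.forward(x, train=False)
        mu = self.cvae.mu_head.forward(h, train=False)
        self.head.net.forward(mu, train=False)
        g_mu = self.head.net.backward(np.ones((x.shape[0], 1)))
        g_h = self.cvae.mu_head.backward(g_mu)
        g_x = self.cvae.encoder.backward(g_h)
        for p in self.head.parameters() + self.cvae.parameters():
            p.grad[...] = 0.0
        return g_x

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "variant.json").write_text(
            json.dumps({"variant": self.variant}, indent=2))
        self.head.save(directory / "head")
        if self.cvae is not None:
            self.cvae.save(directory / "cvae")

    @classmethod
    def load(cls, directory: str | Path) -> "Predictor":
        directory = Path(directory)
        variant = json.loads(
            (directory / "variant.json").read_text())["variant"]
        head = ClassifierHead.load(directory / "head")
        cvae = (CvaeModel.load(directory / "cvae")
                if (directory / "cvae").exists() else None)
        return cls(variant, head, cvae)


def train_variant(features: EmbeddingTable | np.ndarray,
                  labels: np.ndarray | None = None,
                  variant: str = "cvae_res_dnn",
                  cvae_config: CvaeConfig | None = None,
                  head_config: HeadConfig | None = None,
                  seed: int = 0) -> Predictor:
    """Train one of the four variants end to end.

    For cVAE variants the autoencoder is fitted first (with its
    classification head shaping the latent space), then the downstream
    head is fitted on the latent means.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    table = features if isinstance(features, EmbeddingTable) else None
    x = table.features if table is not None else np.asarray(
        features, dtype=np.float64)
    y = np.asarray(labels).ravel() if labels is not None else table.labels()

    arch = RES_DNN if variant.endswith("res_dnn") else DNN_LINEAR
    if variant.startswith("cvae_"):
        if cvae_config is None:
            # moderate schedule: long label-coupled training memorises the
            # training labels and the latent code stops generalising
            cvae_config = CvaeConfig(
                input_dim=x.shape[1],
                latent_dim=min(100, max(2, x.shape[1] // 2)),
                encoder_layer_dims=[64], decoder_layer_dims=[64],
                beta=0.3, epochs=60, learning_rate=1e-3, seed=seed)
        cvae = fit_cvae(features, y, cvae_config)
        codes = cvae.encode_mu(x)
        if head_config is None:
            head_config = HeadConfig(architecture=arch,
                                     input_dim=codes.shape[1],
                                     layer_dims=[32], epochs=30,
                                     learning_rate=1e-3,
                                     class_weighting=True, seed=seed)
        head = fit_head(codes, y, head_config)
        return Predictor(variant, head, cvae)
    if head_config is None:
        head_config = HeadConfig(architecture=arch, input_dim=x.shape[1],
                                 layer_dims=[32], epochs=30,
                                 learning_rate=1e-3, class_weighting=True,
                                 seed=seed)
    head = fit_head(x, y, head_config)
    return Predictor(variant, head, None)
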