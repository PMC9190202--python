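"""Slide-level HER2 score prediction from tumor-tile proportion vectors.

Two interchangeable schemes learn the scoring rule from data instead of
hard-coding thresholds: a polynomial-kernel support vector machine
(kernel=poly, gamma=10, C=2) and a four-layer perceptron
(4 -> 32 -> 16 -> 8 -> 4, ReLU after the hidden layers) trained full-batch
with momentum SGD and cross-entropy. The three-class clinical verdict is
always derived from the predicted four-class score, never predicted
separately.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .config import TUMOR_CLASSES, SCORE_TO_CLINICAL
from .errors import ConfigurationError, DataError
from .nn import SGD, Linear, Module, ReLU, cosine_lr, cross_entropy, softmax


@dataclass
class WHSPNConfig:
    scheme: str = "mlp"  # mlp | svm
    svm_gamma: float = 10.0
    svm_c: float = 2.0
    svm_degree: int = 3
    svm_coef0: float = 0.0
    mlp_hidden: tuple[int, ...] = (32, 16, 8)
    mlp_lr: float = 0.1
    mlp_epochs: int = 1000
    mlp_momentum: float = 0.9
    mlp_weight_decay: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("mlp", "svm"):
            raise ConfigurationError(f"unknown WHSPN scheme {self.scheme!r}")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["mlp_hidden"] = list(self.mlp_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WHSPNConfig":
        d = dict(d)
        if "mlp_hidden" in d:
            d["mlp_hidden"] = tuple(d["mlp_hidden"])
        return cls(**d)


class _MLP(Module):
    """Fully connected funnel over the 4-dim proportion vector."""

    def __init__(self, widths: list[int], rng: np.random.Generator):
        self.layers: list[Module] = []
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            self.layers.append(Linear(a, b, rng=rng, dtype=np.float64))
            if i < len(widths) - 2:
                self.layers.append(ReLU())

    def _children(self):
        return [(f"layers.{i}", m) for i, m in enumerate(self.layers)]

    def forward(self, x, train=False):
        for m in self.layers:
            x = m(x, train)
        return x

    def backward(self, g):
        for m in reversed(self.layers):
            g = m.backward(g)
        return g


def _validate_vectors(vectors: np.ndarray) -> np.ndarray:
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[1] != 4:
        raise DataError(f"proportion vectors must have 4 entries, got {vectors.shape[1]}")
    if np.any(vectors < -1e-12):
        raise DataError("proportion vectors must be non-negative")
    sums = vectors.sum(axis=1)
    bad = np.abs(sums - 1.0) > 1e-6
    if bad.any():
        raise DataError(f"proportion vectors must sum to 1 (got {sums[bad][:3]}...)")
    return vectors


@dataclass
class SlideScorer:
    """Fitted WHSPN: either a fitted SVC or the MLP weights."""

    config: WHSPNConfig
    svm: SVC | None = None
    mlp: _MLP | None = field(default=None, repr=False)

    def predict(self, vectors: np.ndarray) -> list[str]:
        vectors = _validate_vectors(vectors)
        if self.config.scheme == "svm":
            idx = self.svm.predict(vectors)
        else:
            idx = np.argmax(self.mlp(vectors), axis=1)
        return [TUMOR_CLASSES[i] for i in idx]

    def predict_proba(self, vectors: np.ndarray) -> np.ndarray:
        vectors = _validate_vectors(vectors)
        if self.config.scheme == "svm":
            raise ConfigurationError("probability output is only available for the mlp scheme")
        return softmax(self.mlp(vectors), axis=1)

    # -- persistence -----------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(f"{prefix}.json", "w") as fh:
            json.dump({"whspn_config": self.config.to_dict()}, fh, indent=2)
        if self.config.scheme == "svm":
            with open(f"{prefix}.pkl", "wb") as fh:
                pickle.dump(self.svm, fh)
        else:
            np.savez(f"{prefix}.npz", **self.mlp.state_dict())

    @classmethod
    def load(cls, prefix: str | Path) -> "SlideScorer":
        prefix = Path(prefix)
        with open(f"{prefix}.json") as fh:
            config = WHSPNConfig.from_dict(json.load(fh)["whspn_config"])
        if config.scheme == "svm":
            with open(f"{prefix}.pkl", "rb") as fh:
                return cls(config=config, svm=pickle.load(fh))
        mlp = _MLP([4, *config.mlp_hidden, 4], rng=np.random.default_rng(0))
        with np.load(f"{prefix}.npz") as data:
            mlp.load_state_dict({k: data[k] for k in data.files})
        return cls(config=config, mlp=mlp)


def train_whspn(
    vectors: np.ndarray, labels: list[str], config: WHSPNConfig | None = None
) -> SlideScorer:
    """Fit a slide scorer on labeled proportion vectors.

    All four HER2 scores must appear in the labels; the MLP run is
    reproducible under ``config.seed`` and the SVM fit is deterministic.
    """
    config = config or WHSPNConfig()
    vectors = _validate_vectors(vectors)
    if len(labels) != len(vectors):
        raise DataError("labels and vectors must align")
    bad = set(labels) - set(TUMOR_CLASSES)
    if bad:
        raise DataError(f"labels outside the four-class vocabulary: {sorted(map(str, bad))}")
    missing = set(TUMOR_CLASSES) - set(labels)
    if missing:
        raise DataError(f"classes absent from training labels: {sorted(missing)}")
    y = np.array([TUMOR_CLASSES.index(lab) for lab in labels])

    if config.scheme == "svm":
        svm = SVC(
            kernel="poly",
            gamma=config.svm_gamma,
            C=config.svm_c,
            degree=config.svm_degree,
            coef0=config.svm_coef0,
        )
        svm.fit(vectors, y)
        return SlideScorer(config=config, svm=svm)

    rng = np.random.default_rng(config.seed)
    mlp = _MLP([4, *config.mlp_hidden, 4], rng=rng)
    opt = SGD(
        mlp.parameters(),
        lr=config.mlp_lr,
        momentum=config.mlp_momentum,
        weight_decay=config.mlp_weight_decay,
    )
    for epoch in range(config.mlp_epochs):  # full-batch
        opt.lr = cosine_lr(config.mlp_lr, epoch, config.mlp_epochs)
        logits = mlp(vectors, train=True)
        _, dlogits = cross_entropy(logits, y)
        opt.zero_grad()
        mlp.backward(dlogits)
        opt.step()
    return SlideScorer(config=config, mlp=mlp)


def predict_whspn(scorer: SlideScorer, vector: np.ndarray) -> tuple[str, str]:
    """Four-class score and its derived three-class clinical verdict."""
    score = scorer.predict(np.atleast_2d(vector))[0]
    return score, SCORE_TO_CLINICAL[score]
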