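"""Run-level configuration objects and the fixed class vocabulary."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

#: Six tile classes in canonical (argmax tie-break) order.
TILE_CLASSES: tuple[str, ...] = ("0", "1+", "2+", "3+", "normal", "noise")
#: The four HER2-scored classes whose proportions form the slide vector.
TUMOR_CLASSES: tuple[str, ...] = ("0", "1+", "2+", "3+")
#: Clinical three-class grouping.
THREE_CLASSES: tuple[str, ...] = ("Negative", "Equivocal", "Positive")

#: 4-class score -> clinical interpretation (0/1+ negative, 2+ equivocal, 3+ positive).
SCORE_TO_CLINICAL: dict[str, str] = {
    "0": "Negative",
    "1+": "Negative",
    "2+": "Equivocal",
    "3+": "Positive",
}


@dataclass
class ModelConfig:
    """Architecture of the tile classifier.

    ``stage_depths``/``stage_widths`` give the number of 3x3 conv layers and
    the channel width of each of the five stages; the first layer of every
    stage has stride 2, so a 256x256 input reaches an 8x8 map before global
    pooling. ``arch`` selects the block family: ``ecm`` uses the re-
    parameterizable enhanced-convolution blocks (multi-branch in train mode,
    single fused conv with bias in deploy mode); ``chain`` is the plain
    baseline with neither bias nor normalization.
    """

    stage_depths: list[int] = field(default_factory=lambda: [1, 2, 4, 14, 1])
    stage_widths: list[int] = field(default_factory=lambda: [48, 48, 96, 192, 1280])
    n_classes: int = 6
    attention: str = "none"  # none | gct | se
    mode: str = "train"  # train | deploy
    arch: str = "ecm"  # ecm | chain
    se_reduction: int = 16
    in_channels: int = 3

    def __post_init__(self):
        if len(self.stage_depths) != 5 or len(self.stage_widths) != 5:
            raise ConfigurationError("stage_depths and stage_widths must have length 5")
        if any(d < 1 for d in self.stage_depths) or any(w < 1 for w in self.stage_widths):
            raise ConfigurationError("stage depths and widths must be positive")
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be positive")
        if self.attention not in ("none", "gct", "se"):
            raise ConfigurationError(f"unknown attention kind {self.attention!r}")
        if self.mode not in ("train", "deploy"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.arch not in ("ecm", "chain"):
            raise ConfigurationError(f"unknown arch {self.arch!r}")
        if self.se_reduction < 1:
            raise ConfigurationError("se_reduction must be positive")
        if self.attention == "se" and any(w % self.se_reduction for w in self.stage_widths):
            raise ConfigurationError(
                "every stage width must be divisible by se_reduction for SE attention"
            )

    @property
    def n_layers(self) -> int:
        return sum(self.stage_depths)

    def to_dict(self) -> dict:
        return {
            "stage_depths": list(self.stage_depths),
            "stage_widths": list(self.stage_widths),
            "n_classes": self.n_classes,
            "attention": self.attention,
            "mode": self.mode,
            "arch": self.arch,
            "se_reduction": self.se_reduction,
            "in_channels": self.in_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


@dataclass
class TrainConfig:
    """Optimisation settings for the tile classifier (SGD + cross-entropy)."""

    lr: float = 0.1
    weight_decay: float = 0.001
    batch_size: int = 256
    epochs: int = 200
    momentum: float = 0.9
    lr_schedule: str = "cosine"  # cosine | constant
    seed: int = 0

    def __post_init__(self):
        if min(self.lr, self.weight_decay, self.batch_size, self.epochs, self.momentum) < 0:
            raise ConfigurationError("training hyper-parameters must be non-negative")
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("batch_size and epochs must be positive")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ConfigurationError(f"unknown lr schedule {self.lr_schedule!r}")

    def to_dict(self) -> dict:
        return {
            "lr": self.lr,
            "weight_decay": self.weight_decay,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "momentum": self.momentum,
            "lr_schedule": self.lr_schedule,
            "seed": self.seed,
        }
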