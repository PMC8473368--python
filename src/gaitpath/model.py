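"""The spatiotemporal gait classifier.

Two-stage architecture:

1. **Spatial extractor** — a convolutional backbone applied to each of
   the 9 key frames independently.  In ``vgg16`` mode this is the
   standard 13-conv-layer / 5-block topology followed by a flatten and
   one 4096-unit fully connected layer (the truncation point); binary
   masks are replicated to 3 channels.  For fine-tuning, a dense head
   (a second 4096-unit layer and a 5-way softmax) is stacked on top and
   trained on individual key frames carrying their sequence label, with
   the first two convolutional blocks frozen; the head is then discarded.
   ``compact`` mode is a small 3-block backbone with the same interface,
   sized for CPU-scale experiments.

2. **Temporal classifier** — a bidirectional LSTM reads the 9 spatial
   feature vectors (one per key frame, 9 cells per direction) and the
   final hidden states of the two directions (``lstm_units`` each,
   256 by default) are concatenated into a fused spatiotemporal feature
   (512 by default).  A fully connected layer of the same size, dropout
   0.5 (training only) and a softmax layer over the gait classes complete
   the model.  Training minimizes categorical cross-entropy with the
   Nadam optimizer (Adam with Nesterov momentum) at learning rate 1e-4.

Pretrained backbone weights are an optional external asset: everything
here builds and trains from random initialization.  Final classification
layers are zero-initialized, so an untrained model outputs exactly
uniform probabilities and training is equivariant to relabelling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cycles import extract_key_frame_sets
from .errors import ConfigError, CycleDetectionError, TrainingError, ValidationError
from .io import (
    CLASS_LABELS,
    NormalizedFrame,
    SilhouetteFrame,
    SilhouetteSequence,
    clean_frame,
    normalize_frame,
)
from . import nn

_VGG_BLOCKS = [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)]
_COMPACT_BLOCKS = [(8, 1), (16, 1), (32, 1)]


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference setup)."""

    backbone: str = "vgg16"
    input_side: int = 224
    feature_dim: int = 4096
    lstm_units: int = 256
    n_classes: int = 5
    dropout: float = 0.5
    frozen_blocks: int = 2
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.backbone not in ("vgg16", "compact"):
            raise ConfigError(f"unknown backbone {self.backbone!r}")
        if self.feature_dim <= 0 or self.n_classes < 2:
            raise ConfigError("feature_dim must be > 0 and n_classes >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must lie in [0, 1)")
        n_pool = len(_VGG_BLOCKS) if self.backbone == "vgg16" else len(_COMPACT_BLOCKS)
        if self.input_side % (2**n_pool) != 0:
            raise ConfigError(
                f"input_side must be a multiple of {2**n_pool} for {self.backbone}"
            )
        if self.backbone == "vgg16":
            self.feature_dim = 4096


@dataclass
class TrainConfig:
    """Optimization settings (lr 1e-4, Nadam, categorical cross-entropy)."""

    learning_rate: float = 1e-4
    optimizer: str = "nadam"
    loss: str = "categorical_crossentropy"
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be >= 0")


@dataclass
class FeatureSequence:
    """9 ordered spatial feature vectors for one gait cycle."""

    vectors: np.ndarray  # (9, feature_dim)
    cycle_ref: tuple | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != 9:
            raise ValidationError("a feature sequence holds exactly 9 vectors")


@dataclass
class ClassProbabilities:
    probs: np.ndarray
    class_order: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)

    @property
    def decision(self) -> str:
        return self.class_order[int(self.probs.argmax())]


def _stack_masks(frames: Sequence[NormalizedFrame], channels: int) -> np.ndarray:
    x = np.stack([f.mask for f in frames]).astype(np.float32)[..., None]
    if channels == 3:
        x = np.repeat(x, 3, axis=-1)
    return x


class SpatialExtractor:
    """Truncated convolutional backbone producing one feature vector per frame."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
        blocks = _VGG_BLOCKS if config.backbone == "vgg16" else _COMPACT_BLOCKS
        self.in_channels = 3 if config.backbone == "vgg16" else 1
        self.conv_blocks: list[list[nn.Layer]] = []
        layers: list[nn.Layer] = []
        c_in = self.in_channels
        for bi, (c_out, n_conv) in enumerate(blocks):
            block: list[nn.Layer] = []
            for li in range(n_conv):
                block.append(nn.Conv2D(c_in, c_out, rng, name=f"block{bi + 1}.conv{li + 1}"))
                block.append(nn.ReLU())
                c_in = c_out
            block.append(nn.MaxPool2())
            self.conv_blocks.append(block)
            layers.extend(block)
        side = config.input_side // (2 ** len(blocks))
        flat = side * side * c_in
        layers.append(nn.Flatten())
        layers.append(nn.Dense(flat, config.feature_dim, rng, name="fc_feature"))
        layers.append(nn.ReLU())
        self.trunk = nn.Sequential(layers)
        # dense head used only during fine-tuning, discarded afterwards
        self.head = nn.Sequential(
            [
                nn.Dense(config.feature_dim, config.feature_dim, rng, name="fc_head"),
                nn.ReLU(),
                nn.Dense(config.feature_dim, config.n_classes, rng,
                         zero_init=True, name="fc_out"),
            ]
        )
        for bi in range(min(config.frozen_blocks, len(self.conv_blocks))):
            for layer in self.conv_blocks[bi]:
                for p in layer.params():
                    p.trainable = False

    def block_parameters(self, block_index: int) -> list[np.ndarray]:
        """Copies of the parameters of conv block ``block_index`` (0-based)."""
        return [
            p.value.copy()
            for layer in self.conv_blocks[block_index]
            for p in layer.params()
        ]

    def finetune(
        self,
        frames: Sequence[NormalizedFrame],
        labels: Sequence[int],
        train: TrainConfig,
    ) -> dict:
        """Stage-1 training on individual key frames with sequence labels.

        Trains the unfrozen conv blocks plus the dense head, then the
        head is no longer used: ``features`` returns the truncated
        trunk's output.  Returns the loss/accuracy history.
        """
        y = np.asarray(labels, dtype=int)
        if np.unique(y).size < 2:
            raise TrainingError("fine-tuning needs at least 2 distinct classes")
        x = _stack_masks(frames, self.in_channels)
        model = nn.Sequential(self.trunk.layers + self.head.layers)
        rng = np.random.default_rng(np.random.SeedSequence([train.seed, 202]))
        return nn.fit_classifier(
            model, x, y,
            epochs=train.epochs, batch_size=train.batch_size,
            lr=train.learning_rate, rng=rng,
        )

    def features(self, frames: Sequence[NormalizedFrame], batch_size: int = 64) -> np.ndarray:
        """Deterministic (eval-mode) feature vectors, one per frame."""
        x = _stack_masks(frames, self.in_channels)
        out = [
            self.trunk.forward(x[i : i + batch_size], train=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out, axis=0)


def build_spatial_extractor(config: ModelConfig, seed: int = 0) -> SpatialExtractor:
    return SpatialExtractor(config, seed)


def finetune_spatial_extractor(
    extractor: SpatialExtractor,
    labeled_key_frames: Sequence[tuple[NormalizedFrame, int]],
    train: TrainConfig,
    config: ModelConfig | None = None,
) -> SpatialExtractor:
    frames = [f for f, _ in labeled_key_frames]
    labels = [c for _, c in labeled_key_frames]
    extractor.finetune(frames, labels, train)
    return extractor


def extract_feature_sequence(
    extractor: SpatialExtractor, keyframes: Sequence[NormalizedFrame]
) -> FeatureSequence:
    """Feature vectors of exactly 9 key frames, in key-frame order."""
    if len(keyframes) != 9:
        raise ValidationError(f"expected 9 key frames, got {len(keyframes)}")
    return FeatureSequence(vectors=extractor.features(keyframes))


class TemporalClassifier:
    """BiLSTM temporal fusion plus the dense softmax classification head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
        fused = 2 * config.lstm_units
        self.bilstm = nn.BiLSTMLast(config.feature_dim, config.lstm_units, rng)
        self.model = nn.Sequential(
            [
                self.bilstm,
                nn.Dense(fused, fused, rng, name="fc1"),
                nn.ReLU(),
                nn.Dropout(config.dropout, rng),
                nn.Dense(fused, config.n_classes, rng, zero_init=True, name="fc2"),
            ]
        )

    def fused_features(self, x: np.ndarray) -> np.ndarray:
        """The concatenated final BiLSTM hidden states, shape (N, 2*lstm_units)."""
        return self.bilstm.forward(x.astype(np.float32), train=False)

    def train_on(self, data: Sequence[FeatureSequence], labels: Sequence[int],
                 train: TrainConfig) -> dict:
        if len(data) == 0:
            raise TrainingError("no feature sequences to train on")
        x = np.stack([d.vectors for d in data])
        y = np.asarray(labels, dtype=int)
        rng = np.random.default_rng(np.random.SeedSequence([train.seed, 404]))
        return nn.fit_classifier(
            self.model, x, y,
            epochs=train.epochs, batch_size=train.batch_size,
            lr=train.learning_rate, rng=rng,
        )

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.model.forward(x.astype(np.float32), train=False)
        return nn.softmax(logits.astype(np.float64))


def build_temporal_classifier(config: ModelConfig, seed: int = 0) -> TemporalClassifier:
    return TemporalClassifier(config, seed)


def train_classifier(
    model: TemporalClassifier,
    data: Sequence[FeatureSequence],
    train: TrainConfig,
    labels: Sequence[int] | None = None,
    class_order: Sequence[str] = CLASS_LABELS,
) -> tuple[TemporalClassifier, dict]:
    if labels is None:
        labels = [class_order.index(d.label) for d in data]
    if np.unique(labels).size < 2:
        raise TrainingError("training needs at least 2 classes")
    history = model.train_on(data, labels, train)
    return model, history


def predict(model: TemporalClassifier, features: FeatureSequence,
            class_order: tuple[str, ...] = CLASS_LABELS) -> ClassProbabilities:
    if features.vectors.shape[1] != model.config.feature_dim:
        raise ValidationError("feature dimension does not match the model")
    probs = model.predict_proba(features.vectors[None])[0]
    return ClassProbabilities(probs=probs, class_order=tuple(class_order))


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineConfig:
    """Preprocessing knobs tying cycle detection to the model input."""

    band_fraction: float = 0.15
    smooth_window: int = 5
    clean: bool = True  # largest-component + hole-fill before cycle detection
    mirror_to_canonical: bool = True
    height_fraction: float = 0.9
    class_order: tuple[str, ...] = CLASS_LABELS


class GaitPipeline:
    """Silhouette sequences in, per-cycle class probabilities out.

    ``fit`` runs the two training stages (CNN fine-tuning on key frames,
    then BiLSTM training on extracted feature sequences); ``classify``
    applies cycle detection, key-frame selection, normalization, feature
    extraction and classification to a new sequence.
    """

    def __init__(
        self,
        model_config: ModelConfig,
        stage1: TrainConfig,
        stage2: TrainConfig | None = None,
        pipeline_config: PipelineConfig | None = None,
        seed: int = 0,
    ):
        self.model_config = model_config
        self.stage1 = stage1
        self.stage2 = stage2 if stage2 is not None else stage1
        self.pc = pipeline_config if pipeline_config is not None else PipelineConfig()
        self.extractor = SpatialExtractor(model_config, seed)
        self.temporal = TemporalClassifier(model_config, seed)
        self.history: dict = {}

    def _prepare(self, seq: SilhouetteSequence) -> list[list[NormalizedFrame]]:
        """Key-frame stacks (one list of 9 normalized frames per cycle)."""
        if self.pc.mirror_to_canonical:
            seq = seq.canonical()
        if self.pc.clean:
            seq = SilhouetteSequence(
                frames=[clean_frame(f) for f in seq.frames],
                subject_id=seq.subject_id, class_label=seq.class_label,
                severity=seq.severity, direction=seq.direction,
                fps=seq.fps, is_repetition=seq.is_repetition,
            )
        cycles, keysets, _ = extract_key_frame_sets(
            seq, self.pc.band_fraction, self.pc.smooth_window
        )
        stacks = []
        for ks in keysets:
            stacks.append(
                [
                    normalize_frame(
                        seq.frames[i], self.model_config.input_side,
                        self.pc.height_fraction,
                    )
                    for i in ks.indices
                ]
            )
        return stacks

    def fit(self, sequences: Sequence[SilhouetteSequence]) -> "GaitPipeline":
        frames, frame_labels = [], []
        per_cycle: list[tuple[list[NormalizedFrame], int]] = []
        skipped = 0
        for seq in sequences:
            label = self.pc.class_order.index(seq.class_label)
            try:
                stacks = self._prepare(seq)
            except CycleDetectionError:
                skipped += 1
                continue
            for stack in stacks:
                frames.extend(stack)
                frame_labels.extend([label] * 9)
                per_cycle.append((stack, label))
        if not per_cycle:
            raise TrainingError("no usable gait cycles in the training data")
        self.history["stage1"] = self.extractor.finetune(frames, frame_labels, self.stage1)
        feats = [
            FeatureSequence(vectors=self.extractor.features(stack))
            for stack, _ in per_cycle
        ]
        labels = [lab for _, lab in per_cycle]
        self.history["stage2"] = self.temporal.train_on(feats, labels, self.stage2)
        self.history["skipped_training_sequences"] = skipped
        return self

    def feature_sequences(self, seq: SilhouetteSequence) -> list[FeatureSequence]:
        return [
            FeatureSequence(vectors=self.extractor.features(stack))
            for stack in self._prepare(seq)
        ]

    def classify(self, seq: SilhouetteSequence) -> tuple[list[ClassProbabilities], str]:
        """Per-cycle probabilities plus the sequence-level decision
        (argmax of the mean per-cycle probability vector)."""
        feats = self.feature_sequences(seq)
        x = np.stack([f.vectors for f in feats])
        probs = self.temporal.predict_proba(x)
        per_cycle = [
            ClassProbabilities(p, class_order=self.pc.class_order) for p in probs
        ]
        decision = self.pc.class_order[int(probs.mean(axis=0).argmax())]
        return per_cycle, decision

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Checkpoint as NPZ (parameters) with a JSON config sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, p in enumerate(self.extractor.trunk.params() + self.extractor.head.params()):
            arrays[f"spatial_{i}"] = p.value
        for i, p in enumerate(self.temporal.model.params()):
            arrays[f"temporal_{i}"] = p.value
        np.savez_compressed(path, **arrays)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "model_config": asdict(self.model_config),
                    "stage1": asdict(self.stage1),
                    "stage2": asdict(self.stage2),
                    "pipeline_config": {
                        **{k: v for k, v in asdict(self.pc).items() if k != "class_order"},
                        "class_order": list(self.pc.class_order),
                    },
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "GaitPipeline":
        path = Path(path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        pc = meta["pipeline_config"]
        pc["class_order"] = tuple(pc["class_order"])
        pipe = cls(
            ModelConfig(**meta["model_config"]),
            TrainConfig(**meta["stage1"]),
            TrainConfig(**meta["stage2"]),
            PipelineConfig(**pc),
        )
        data = np.load(path)
        for i, p in enumerate(pipe.extractor.trunk.params() + pipe.extractor.head.params()):
            p.value = data[f"spatial_{i}"].copy()
        for i, p in enumerate(pipe.temporal.model.params()):
            p.value = data[f"temporal_{i}"].copy()
        return pipe


def classify_sequence(
    seq: SilhouetteSequence, pipeline: GaitPipeline
) -> tuple[list[ClassProbabilities], str]:
    """Functional wrapper around :meth:`GaitPipeline.classify`."""
    return pipeline.classify(seq)
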