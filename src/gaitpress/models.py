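"""Identity models: CNN classifier and autoencoder embedding head.

The classifier consumes 32x32 average bilateral pressure maps through
three convolution + max-pool blocks, flattens, and passes a 256-neuron
hidden layer to a K-way softmax (K = 60 for the closed-set cohort, 48 for
the open-set enrolment).  The 256-dimensional hidden activations are the
identity embedding; an autoencoder (256 -> 64 -> 256, mean-squared
reconstruction loss) compresses them to the 64-dimensional feature
vectors used for open-set identification.

Hyperparameters not pinned by the architecture diagrams use the smallest
standard configuration: 3x3 kernels with filter progression 32-64-128,
2x2 max pooling, ReLU activations, Adam at learning rate 1e-3, 50 epochs,
batch size 16, validation split 0.1.  Training runs a fixed epoch budget
(no early stopping); convergence typically occurs around epoch 20.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nnet
from .preprocess import AveragePressureMap

__all__ = [
    "CnnConfig",
    "AeConfig",
    "TrainingTrace",
    "CnnClassifier",
    "Autoencoder",
    "maps_to_array",
    "train_cnn",
    "extract_embeddings",
    "train_autoencoder",
    "encode",
]

EMBED_DIM = 256
CODE_DIM = 64


@dataclass(frozen=True)
class CnnConfig:
    n_classes: int
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    fc_hidden: int = EMBED_DIM
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 16
    validation_split: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_hidden != EMBED_DIM:
            raise ValueError(f"penultimate layer width must be {EMBED_DIM}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")


@dataclass(frozen=True)
class AeConfig:
    input_dim: int = EMBED_DIM
    code_dim: int = CODE_DIM
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.code_dim != CODE_DIM or self.input_dim != EMBED_DIM:
            raise ValueError(
                f"autoencoder must map {EMBED_DIM} -> {CODE_DIM} -> {EMBED_DIM}"
            )


@dataclass
class TrainingTrace:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def maps_to_array(maps) -> tuple[np.ndarray, np.ndarray]:
    """Stack maps into (N, 1, 32, 32) float32 plus subject-id labels."""
    x = np.stack([m.grid for m in maps]).astype(np.float32)[:, None, :, :]
    y = np.array([m.subject_id for m in maps], dtype=np.int64)
    return x, y


class CnnClassifier:
    """Three conv/pool blocks -> flatten -> 256-unit hidden -> K softmax."""

    def __init__(self, config: CnnConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f1, f2, f3 = config.conv_filters
        self.backbone = nnet.Sequential([
            nnet.Conv3x3(1, f1, rng), nnet.ReLU(), nnet.MaxPool2x2(),
            nnet.Conv3x3(f1, f2, rng), nnet.ReLU(), nnet.MaxPool2x2(),
            nnet.Conv3x3(f2, f3, rng), nnet.ReLU(), nnet.MaxPool2x2(),
            nnet.Flatten(),
            nnet.Dense(4 * 4 * f3, config.fc_hidden, rng), nnet.ReLU(),
        ])
        self.head = nnet.Dense(config.fc_hidden, config.n_classes, rng)
        self.input_scale = 1.0  # set from the training data maximum
        self.class_ids: np.ndarray | None = None  # subject id per class index

    # -- inference ---------------------------------------------------------
    def _scaled(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float32) / self.input_scale)

    def logits(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = self._scaled(x)
        outs = []
        for i in range(0, len(x), batch_size):
            h = self.backbone.forward(x[i:i + batch_size])
            outs.append(self.head.forward(h))
        return np.concatenate(outs) if outs else np.zeros((0, self.config.n_classes))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nnet.softmax(self.logits(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted subject ids (mapped back through ``class_ids``)."""
        idx = self.logits(x).argmax(axis=1)
        if self.class_ids is not None:
            return self.class_ids[idx]
        return idx

    def embed(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """256-dimensional hidden-layer activations (identity embedding)."""
        x = self._scaled(x)
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.backbone.forward(x[i:i + batch_size]))
        return np.concatenate(outs) if outs else np.zeros((0, EMBED_DIM))

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        state = self.backbone.state_dict() + [p.copy() for p in self.head.params]
        np.savez_compressed(
            path / "cnn.npz",
            **{f"p{i}": p for i, p in enumerate(state)},
            class_ids=(self.class_ids if self.class_ids is not None
                       else np.array([], dtype=np.int64)),
            input_scale=np.array(self.input_scale),
        )
        (path / "cnn_config.json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "CnnClassifier":
        path = Path(path)
        cfg = CnnConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in
                           json.loads((path / "cnn_config.json").read_text()).items()})
        model = cls(cfg)
        with np.load(path / "cnn.npz") as data:
            n_backbone = len(model.backbone.params)
            state = [data[f"p{i}"] for i in range(n_backbone + 2)]
            model.backbone.load_state(state[:n_backbone])
            for p, s in zip(model.head.params, state[n_backbone:]):
                p[...] = s
            cids = data["class_ids"]
            model.class_ids = cids if cids.size else None
            model.input_scale = float(data["input_scale"])
        return model


def _stratified_split(y: np.ndarray, frac: float, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random holdout of ``frac``; returns (train_idx, val_idx)."""
    train, val = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        k = int(round(frac * len(idx)))
        val.extend(idx[:k])
        train.extend(idx[k:])
    return np.array(sorted(train)), np.array(sorted(val))


def train_cnn(maps_or_x, labels=None, config: CnnConfig | None = None
              ) -> tuple[CnnClassifier, TrainingTrace]:
    """Train the classifier on average pressure maps.

    Accepts either a list of :class:`AveragePressureMap` or a pre-stacked
    ``(N, 1, 32, 32)`` array with a label vector.  Labels are arbitrary
    subject ids; they are mapped to contiguous class indices internally and
    ``classifier.predict`` maps back.
    """
    if labels is None or isinstance(maps_or_x[0], AveragePressureMap):
        x, y = maps_to_array(maps_or_x)
    else:
        x = np.asarray(maps_or_x, dtype=np.float32)
        y = np.asarray(labels, dtype=np.int64)
    if config is None:
        raise ValueError("config is required")
    class_ids = np.unique(y)
    if len(class_ids) != config.n_classes:
        raise ValueError(
            f"config.n_classes={config.n_classes} but labels contain "
            f"{len(class_ids)} distinct subjects"
        )
    y_idx = np.searchsorted(class_ids, y)

    model = CnnClassifier(config)
    model.class_ids = class_ids
    scale = float(x.max())
    model.input_scale = scale if scale > 0 else 1.0
    trace = TrainingTrace()
    if config.epochs == 0:
        return model, trace

    rng = np.random.default_rng(config.seed + 1)
    tr_idx, va_idx = _stratified_split(y_idx, config.validation_split, rng)
    x_tr, y_tr = model._scaled(x[tr_idx]), y_idx[tr_idx]
    x_va, y_va = model._scaled(x[va_idx]), y_idx[va_idx]

    params = model.backbone.params + model.head.params
    grads = model.backbone.grads + model.head.grads
    opt = nnet.Adam(params, lr=config.learning_rate)

    for _epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        losses, hits, total = [], 0, 0
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            h = model.backbone.forward(xb)
            logits = model.head.forward(h)
            loss, dlogits = nnet.cross_entropy_grad(logits, yb)
            dh = model.head.backward(dlogits)
            model.backbone.backward(dh)
            opt.step(grads)
            losses.append(loss * len(sel))
            hits += int((logits.argmax(axis=1) == yb).sum())
            total += len(sel)
        trace.train_loss.append(sum(losses) / total)
        trace.train_acc.append(hits / total)
        if len(x_va):
            vlogits = np.concatenate([
                model.head.forward(model.backbone.forward(x_va[j:j + 256]))
                for j in range(0, len(x_va), 256)
            ])
            vloss, _ = nnet.cross_entropy_grad(vlogits.copy(), y_va)
            trace.val_loss.append(vloss)
            trace.val_acc.append(float((vlogits.argmax(axis=1) == y_va).mean()))
        else:
            trace.val_loss.append(float("nan"))
            trace.val_acc.append(float("nan"))
    return model, trace


def extract_embeddings(classifier: CnnClassifier, maps_or_x) -> np.ndarray:
    """256-dim hidden-layer vectors for a batch of maps."""
    if len(maps_or_x) and isinstance(maps_or_x[0], AveragePressureMap):
        x, _ = maps_to_array(maps_or_x)
    else:
        x = np.asarray(maps_or_x, dtype=np.float32)
    return classifier.embed(x)


class Autoencoder:
    """256 -> 64 -> 256 with ReLU code and linear reconstruction."""

    def __init__(self, config: AeConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = nnet.Sequential([
            nnet.Dense(config.input_dim, config.code_dim, rng), nnet.ReLU(),
        ])
        self.decoder = nnet.Sequential([
            nnet.Dense(config.code_dim, config.input_dim, rng),
        ])
        self.input_scale = 1.0

    def encode(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32) / self.input_scale
        return self.encoder.forward(x)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.decoder.forward(self.encode(x)) * self.input_scale

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        state = self.encoder.state_dict() + self.decoder.state_dict()
        np.savez_compressed(path / "ae.npz",
                            **{f"p{i}": p for i, p in enumerate(state)},
                            input_scale=np.array(self.input_scale))
        (path / "ae_config.json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "Autoencoder":
        path = Path(path)
        cfg = AeConfig(**json.loads((path / "ae_config.json").read_text()))
        model = cls(cfg)
        with np.load(path / "ae.npz") as data:
            n_enc = len(model.encoder.params)
            state = [data[f"p{i}"]
                     for i in range(n_enc + len(model.decoder.params))]
            model.encoder.load_state(state[:n_enc])
            model.decoder.load_state(state[n_enc:])
            model.input_scale = float(data["input_scale"])
        return model


def train_autoencoder(embeddings: np.ndarray, config: AeConfig
                      ) -> tuple[Autoencoder, TrainingTrace]:
    """Unsupervised reconstruction training on 256-dim embeddings."""
    x = np.asarray(embeddings, dtype=np.float32)
    if x.ndim != 2 or x.shape[1] != config.input_dim:
        raise ValueError(f"embeddings must be (N, {config.input_dim})")
    model = Autoencoder(config)
    scale = float(np.abs(x).max())
    model.input_scale = scale if scale > 0 else 1.0
    xs = x / model.input_scale
    trace = TrainingTrace()
    if config.epochs == 0:
        return model, trace
    rng = np.random.default_rng(config.seed + 1)
    params = model.encoder.params + model.decoder.params
    grads = model.encoder.grads + model.decoder.grads
    opt = nnet.Adam(params, lr=config.learning_rate)
    for _epoch in range(config.epochs):
        order = rng.permutation(len(xs))
        losses = []
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            xb = xs[sel]
            code = model.encoder.forward(xb)
            recon = model.decoder.forward(code)
            loss, drecon = nnet.mse_grad(recon, xb)
            dcode = model.decoder.backward(drecon)
            model.encoder.backward(dcode)
            opt.step(grads)
            losses.append(loss * len(sel))
        trace.train_loss.append(sum(losses) / len(xs))
    return model, trace


def encode(autoencoder: Autoencoder, embeddings: np.ndarray) -> np.ndarray:
    """64-dimensional identity codes for a batch of 256-dim embeddings."""
    return autoencoder.encode(np.asarray(embeddings, dtype=np.float32))
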