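"""11-class particle-count classifiers.

Two architecture profiles share one code path:

* ``b0`` — a faithful EfficientNet-B0 topology: nine stages (3x3 stem, seven
  stacked MBConv stages alternating 3x3 and 5x5 depthwise kernels with
  squeeze-and-excitation, then a 1x1 convolution + global average pooling +
  fully connected head), 224 x 224 x 3 input.
* ``desk`` — a reduced CNN (three conv/BN/ReLU/maxpool blocks, global
  average pooling, small dense head), 64 x 64 input, trainable on a laptop
  CPU in minutes.  Full-scale b0 training on ~90k images is a cluster job
  and is not exercised by the bundled experiments.

Input images are resized to the profile resolution and standardized per
image to zero mean / unit variance; grayscale data are replicated to three
channels so both profiles accept the same tensors.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .dataset import N_CLASSES, DatasetManifest, load_dataset_arrays

__all__ = [
    "ArchProfile", "TrainConfig", "TrainedModel",
    "B0_STAGES", "build_model", "train", "predict", "predict_labels",
    "preprocess",
]

# EfficientNet-B0 stage table: nine stages.  MBConv entries are
# (expansion ratio, output channels, repeats, first-layer stride, kernel).
B0_STAGES: tuple[dict, ...] = (
    {"op": "conv", "k": 3, "channels": 32, "stride": 2},
    {"op": "mbconv", "expansion": 1, "channels": 16, "repeats": 1, "stride": 1, "k": 3},
    {"op": "mbconv", "expansion": 6, "channels": 24, "repeats": 2, "stride": 2, "k": 3},
    {"op": "mbconv", "expansion": 6, "channels": 40, "repeats": 2, "stride": 2, "k": 5},
    {"op": "mbconv", "expansion": 6, "channels": 80, "repeats": 3, "stride": 2, "k": 3},
    {"op": "mbconv", "expansion": 6, "channels": 112, "repeats": 3, "stride": 1, "k": 5},
    {"op": "mbconv", "expansion": 6, "channels": 192, "repeats": 4, "stride": 2, "k": 5},
    {"op": "mbconv", "expansion": 6, "channels": 320, "repeats": 1, "stride": 1, "k": 3},
    {"op": "head", "k": 1, "channels": 1280},
)


@dataclass(frozen=True)
class ArchProfile:
    """Network profile: name, input resolution and (for b0) the stage table."""

    name: str = "desk"
    input_size: int = 64
    n_classes: int = N_CLASSES
    stages: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        if self.name not in ("b0", "desk"):
            raise ValueError(f"unknown profile {self.name!r}")
        if self.n_classes != N_CLASSES:
            raise ValueError(f"n_classes must be {N_CLASSES}")
        if self.name == "b0" and len(self.stages) != 9:
            raise ValueError("b0 profile requires the nine-stage table")

    @classmethod
    def b0(cls) -> "ArchProfile":
        return cls(name="b0", input_size=224, n_classes=N_CLASSES,
                   stages=B0_STAGES)

    @classmethod
    def desk(cls) -> "ArchProfile":
        return cls(name="desk", input_size=64, n_classes=N_CLASSES)


@dataclass
class TrainConfig:
    """Training hyperparameters (the source study states none; these are ours)."""

    optimizer: str = "adam"
    lr: float = 1e-3
    lr_schedule: str = "cosine"
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0
    augment: bool = False
    checkpoint_path: str | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")


# networks train in single precision; gradient checks in the nn tests use
# float64 layer instances
_DTYPE = np.float32


def _mbconv(in_c: int, spec: dict, stride: int,
            rng: np.random.Generator) -> nn.Layer:
    out_c, e, k = spec["channels"], spec["expansion"], spec["k"]
    mid = in_c * e
    layers: list[nn.Layer] = []
    if e != 1:
        layers += [nn.Conv2d(in_c, mid, 1, bias=False, rng=rng, dtype=_DTYPE),
                   nn.BatchNorm2d(mid, dtype=_DTYPE), nn.SiLU()]
    layers += [nn.DepthwiseConv2d(mid, k, stride=stride, rng=rng, dtype=_DTYPE),
               nn.BatchNorm2d(mid, dtype=_DTYPE), nn.SiLU(),
               nn.SqueezeExcite(mid, max(1, in_c // 4), rng=rng, dtype=_DTYPE),
               nn.Conv2d(mid, out_c, 1, bias=False, rng=rng, dtype=_DTYPE),
               nn.BatchNorm2d(out_c, dtype=_DTYPE)]
    body = nn.Sequential(*layers)
    if stride == 1 and in_c == out_c:
        return nn.Residual(body)
    return body


def _build_b0(profile: ArchProfile, rng: np.random.Generator) -> nn.Sequential:
    stages: list[nn.Layer] = []
    stem = profile.stages[0]
    in_c = stem["channels"]
    stages += [nn.Conv2d(3, in_c, stem["k"], stride=stem["stride"], bias=False,
                         rng=rng, dtype=_DTYPE),
               nn.BatchNorm2d(in_c, dtype=_DTYPE), nn.SiLU()]
    for spec in profile.stages[1:-1]:
        for r in range(spec["repeats"]):
            stride = spec["stride"] if r == 0 else 1
            stages.append(_mbconv(in_c, spec, stride, rng))
            in_c = spec["channels"]
    head = profile.stages[-1]
    stages += [nn.Conv2d(in_c, head["channels"], 1, bias=False, rng=rng,
                         dtype=_DTYPE),
               nn.BatchNorm2d(head["channels"], dtype=_DTYPE), nn.SiLU(),
               nn.GlobalAvgPool(),
               nn.Dense(head["channels"], profile.n_classes, rng=rng,
                        dtype=_DTYPE)]
    return nn.Sequential(*stages)


def _build_desk(profile: ArchProfile, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(3, 8, 3, bias=False, rng=rng, dtype=_DTYPE),
        nn.BatchNorm2d(8, dtype=_DTYPE), nn.ReLU(), nn.MaxPool2d(),
        nn.Conv2d(8, 16, 3, bias=False, rng=rng, dtype=_DTYPE),
        nn.BatchNorm2d(16, dtype=_DTYPE), nn.ReLU(), nn.MaxPool2d(),
        nn.Conv2d(16, 48, 3, bias=False, rng=rng, dtype=_DTYPE),
        nn.BatchNorm2d(48, dtype=_DTYPE), nn.ReLU(), nn.MaxPool2d(),
        nn.GlobalAvgPool(),
        nn.Dense(48, 96, rng=rng, dtype=_DTYPE), nn.ReLU(),
        nn.Dense(96, profile.n_classes, rng=rng, dtype=_DTYPE),
    )


@dataclass
class TrainedModel:
    """Architecture + parameters + label mapping + per-epoch training log."""

    profile: ArchProfile
    network: nn.Sequential
    label_map: tuple[int, ...] = tuple(range(N_CLASSES))
    log: list[dict] = field(default_factory=list)
    seed: int = 0

    def param_checksum(self) -> float:
        return float(sum(np.abs(p).sum() for p in self.network.params()))

    def save(self, path: str) -> None:
        meta = {"profile": {"name": self.profile.name,
                            "input_size": self.profile.input_size,
                            "n_classes": self.profile.n_classes},
                "label_map": list(self.label_map),
                "log": self.log, "seed": self.seed}
        arrays = {f"p{i}": p for i, p in enumerate(self.network.params())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        prof = (ArchProfile.b0() if meta["profile"]["name"] == "b0"
                else ArchProfile.desk())
        model = build_model(prof, seed=meta["seed"])
        for i, p in enumerate(model.network.params()):
            p[...] = data[f"p{i}"]
        model.label_map = tuple(meta["label_map"])
        model.log = list(meta["log"])
        return model


def build_model(profile: ArchProfile, seed: int = 0) -> TrainedModel:
    """Instantiate an untrained model with seed-deterministic initialization."""
    rng = np.random.default_rng(seed)
    if profile.name == "b0":
        net = _build_b0(profile, rng)
    else:
        net = _build_desk(profile, rng)
    return TrainedModel(profile=profile, network=net, seed=seed)


def preprocess(images: np.ndarray, profile: ArchProfile) -> np.ndarray:
    """Images (N,H,W), (H,W) or (N,H,W,3) -> standardized (N,3,S,S) tensors."""
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    if images.ndim == 4:  # channel-replicated input: collapse to grayscale
        images = images.mean(axis=3)
    n, h, w = images.shape
    s = profile.input_size
    if (h, w) != (s, s):
        images = np.stack([_sk_resize(im, (s, s), order=1, anti_aliasing=h > s)
                           for im in images])
    mean = images.mean(axis=(1, 2), keepdims=True)
    std = images.std(axis=(1, 2), keepdims=True)
    out = (images - mean) / np.maximum(std, 1e-9)
    return np.repeat(out[:, None, :, :], 3, axis=1).astype(_DTYPE)


def predict(model: TrainedModel, images: np.ndarray,
            batch_size: int = 256) -> np.ndarray:
    """Per-image class-probability vectors of length 11 (rows sum to 1)."""
    x = preprocess(images, model.profile)
    probs = []
    for i in range(0, x.shape[0], batch_size):
        logits = model.network.forward(x[i:i + batch_size], train=False)
        probs.append(nn.softmax(logits))
    return np.concatenate(probs, axis=0)


def predict_labels(model: TrainedModel, images: np.ndarray,
                   batch_size: int = 256) -> np.ndarray:
    """argmax labels (lowest index wins ties, the numpy argmax convention)."""
    return predict(model, images, batch_size).argmax(axis=1)


def _accuracy(model: TrainedModel, x: np.ndarray, labels: np.ndarray,
              batch_size: int) -> float:
    preds = []
    for i in range(0, x.shape[0], batch_size):
        logits = model.network.forward(x[i:i + batch_size], train=False)
        preds.append(logits.argmax(axis=1))
    return float((np.concatenate(preds) == labels).mean())


def train(model: TrainedModel, manifest: DatasetManifest | None = None,
          cfg: TrainConfig | None = None,
          data: dict | None = None) -> TrainedModel:
    """Minimize cross-entropy on the train split; keep the best-val checkpoint.

    ``data`` may pre-supply ``{"train": (images, labels), "val": ...}``
    arrays to skip manifest realization (used by callers that already hold
    the pixels in memory).  Returns the model with the parameters of the
    epoch with the highest validation accuracy (first epoch wins ties).
    """
    cfg = cfg or TrainConfig()
    if data is None and manifest is None:
        raise ValueError("provide a manifest or pre-realized data arrays")
    if data is None:
        data = {split: load_dataset_arrays(manifest, split)
                for split in ("train", "val")}
    (xtr_raw, ytr), (xva_raw, yva) = data["train"], data["val"]
    if len(ytr) == 0 or len(yva) == 0:
        raise ValueError("train and val splits must both be non-empty")
    xtr = preprocess(xtr_raw, model.profile)
    xva = preprocess(xva_raw, model.profile)
    ytr = np.asarray(ytr, dtype=int)
    yva = np.asarray(yva, dtype=int)

    rng = np.random.default_rng(cfg.seed)
    steps_per_epoch = max(1, len(ytr) // cfg.batch_size)
    params = model.network.params()
    opt = nn.Adam(params, lr=cfg.lr,
                  total_steps=(cfg.epochs * steps_per_epoch
                               if cfg.lr_schedule == "cosine" else None))
    best_acc, best_params = -1.0, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(ytr))
        losses = []
        for step in range(steps_per_epoch):
            idx = order[step * cfg.batch_size:(step + 1) * cfg.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            if cfg.augment:
                flip = rng.random(len(idx)) < 0.5
                xb = xb.copy()
                # reflection across the propagation axis is a symmetry of
                # the imaging model, so it is a label-preserving augmentation
                xb[flip] = xb[flip][:, :, ::-1, :]
            logits = model.network.forward(xb, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            model.network.backward(dlogits)
            opt.step(model.network.grads())
            losses.append(loss)
        val_acc = _accuracy(model, xva, yva, cfg.batch_size)
        model.log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                          "val_accuracy": val_acc})
        if val_acc > best_acc:
            best_acc = val_acc
            best_params = [p.copy() for p in params]
    for p, best in zip(params, best_params):
        p[...] = best
    if cfg.checkpoint_path:
        model.save(cfg.checkpoint_path)
    return model
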