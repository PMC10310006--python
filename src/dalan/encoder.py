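"""Weight-shared convolutional ROI encoders and ROI-level Cox training.

Every ROI in a bag passes through the *same* CNN trunk, yielding one
fixed-width embedding per ROI (default 256).  Two backbones are provided:

* ``small_cnn`` — three 3x3 conv blocks with 2x2 max pooling, global average
  pooling and a linear projection; runs comfortably on one CPU and is the
  default for the simulated designs.
* ``resnet50_like`` — a bottleneck residual network with the classic
  [3, 4, 6, 3] stage layout and batch normalisation, matching the
  architecture class used for full-size histology ROIs.  Weights may be
  loaded from an ``.npz`` checkpoint by parameter name.

Stage-1 training ("ROI-level fine-tuning") attaches a temporary scalar Cox
head, assigns each patient's (time, event) to every one of their ROIs, and
minimises the Cox partial likelihood over ROI minibatches with flip /
brightness / contrast augmentation.  Afterwards the front fraction of
parameter groups (forward order) can be frozen before bag-level training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .nn import Tensor
from .simulator import ROIImage
from .survival import SurvivalRecord

__all__ = [
    "EncoderConfig", "TrainConfig", "EmbeddingSequence", "build_encoder",
    "preprocess", "augment_image", "encode_bag", "RoiCoxModel",
    "fine_tune_roi_level", "train_roi_cox_model", "SmallCNN", "ResNet",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass
class EncoderConfig:
    backbone: str = "small_cnn"
    embedding_dim: int = 256
    pretrained_weights_path: str | None = None
    frozen_fraction: float = 0.5
    input_size: tuple[int, int] = (28, 28)
    in_channels: int = 1
    normalization_mean: tuple = (0.5,)
    normalization_std: tuple = (0.5,)

    @classmethod
    def histology(cls) -> "EncoderConfig":
        """Paper-scale profile: 256x256 RGB ROIs, ImageNet normalisation."""
        return cls(backbone="resnet50_like", input_size=(256, 256), in_channels=3,
                   normalization_mean=IMAGENET_MEAN, normalization_std=IMAGENET_STD)

    def __post_init__(self):
        if self.embedding_dim <= 0:
            raise ValueError("embedding_dim must be positive")
        if not (0.0 <= self.frozen_fraction <= 1.0):
            raise ValueError("frozen_fraction must lie in [0, 1]")
        if len(self.normalization_mean) != self.in_channels:
            raise ValueError("normalization vectors must match in_channels")


@dataclass
class TrainConfig:
    """Optimisation settings shared by stage-1 and bag-level training."""

    lr: float = 1e-3
    weight_decay: float = 1e-6
    epochs: int = 30
    batch_size: int = 64
    grad_clip: float = 1.0
    lr_gamma: float = 1.0
    seed: int = 0
    augment: tuple[str, ...] = ("hflip", "vflip", "brightness", "contrast")


@dataclass
class EmbeddingSequence:
    patient_id: str
    embeddings: np.ndarray        # N x embedding_dim
    order: np.ndarray             # indices of the sampled ROIs, post-shuffle


# ------------------------------------------------------------------ backbones
class SmallCNN(nn.Module):
    """3-block conv trunk -> global average pool -> linear embedding."""

    def __init__(self, in_channels: int, embedding_dim: int, rng: np.random.Generator,
                 widths: tuple[int, int, int] = (8, 16, 32)):
        super().__init__()
        w1, w2, w3 = widths
        self.conv1 = nn.Conv2d(in_channels, w1, 3, rng)
        self.conv2 = nn.Conv2d(w1, w2, 3, rng)
        self.conv3 = nn.Conv2d(w2, w3, 3, rng)
        self.pool = nn.MaxPool2d(2)
        self.proj = nn.Linear(w3, embedding_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.pool(self.conv1(x).relu())
        x = self.pool(self.conv2(x).relu())
        x = self.conv3(x).relu()
        x = x.mean(axis=(2, 3))          # global average pool -> (B, w3)
        return self.proj(x)


class BatchNorm2d(nn.Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = nn.Parameter(np.ones(channels))
        self.beta = nn.Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mean.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) - self.running_var)
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mean) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch: int, width: int, stride: int, rng: np.random.Generator):
        super().__init__()
        out_ch = width * self.expansion
        self.conv1 = nn.Conv2d(in_ch, width, 1, rng, padding=0)
        self.bn1 = BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, rng, stride=stride)
        self.bn2 = BatchNorm2d(width)
        self.conv3 = nn.Conv2d(width, out_ch, 1, rng, padding=0)
        self.bn3 = BatchNorm2d(out_ch)
        self.downsample = None
        if stride != 1 or in_ch != out_ch:
            self.downsample = nn.Sequential(nn.Conv2d(in_ch, out_ch, 1, rng,
                                                      stride=stride, padding=0),
                                            BatchNorm2d(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        identity = x if self.downsample is None else self.downsample(x)
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        return (out + identity).relu()


class ResNet(nn.Module):
    """Bottleneck residual trunk; ``layers=(3,4,6,3)`` gives the 50-layer layout."""

    def __init__(self, in_channels: int, embedding_dim: int, rng: np.random.Generator,
                 layers: tuple[int, ...] = (3, 4, 6, 3), base_width: int = 64):
        super().__init__()
        self.stem = nn.Conv2d(in_channels, base_width, 7, rng, stride=2, padding=3)
        self.stem_bn = BatchNorm2d(base_width)
        self.stem_pool = nn.MaxPool2d(2)
        blocks = []
        in_ch = base_width
        for stage, n_blocks in enumerate(layers):
            width = base_width * 2 ** stage
            for b in range(n_blocks):
                stride = 2 if (b == 0 and stage > 0) else 1
                blocks.append(Bottleneck(in_ch, width, stride, rng))
                in_ch = width * Bottleneck.expansion
        self.blocks = blocks
        self.proj = nn.Linear(in_ch, embedding_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem_pool(self.stem_bn(self.stem(x)).relu())
        for block in self.blocks:
            x = block(x)
        x = x.mean(axis=(2, 3))
        return self.proj(x)


def build_encoder(config: EncoderConfig, seed: int = 0) -> nn.Module:
    rng = np.random.default_rng(seed)
    if config.backbone == "small_cnn":
        enc = SmallCNN(config.in_channels, config.embedding_dim, rng)
    elif config.backbone == "resnet50_like":
        enc = ResNet(config.in_channels, config.embedding_dim, rng)
    else:
        raise ValueError(f"unknown backbone {config.backbone!r}")
    if config.pretrained_weights_path:
        state = dict(np.load(config.pretrained_weights_path))
        enc.load_state_dict(state)
    return enc


def freeze_front(module: nn.Module, fraction: float) -> int:
    """Freeze the front ``fraction`` of parameter groups in forward order.

    "Front half of the layers" is realised as the first ``ceil(fraction*G)``
    of the G parameter tensors as they appear along the forward pass.
    Returns the number of frozen groups.
    """
    params = module.parameters()
    n_frozen = int(np.ceil(fraction * len(params)))
    for i, p in enumerate(params):
        p.frozen = i < n_frozen
    return n_frozen


# -------------------------------------------------------------- preprocessing
def preprocess(image, config: EncoderConfig) -> np.ndarray:
    """[0,1] channels-last ROI -> normalised (C, H, W) float32 tensor."""
    pixels = image.pixels if isinstance(image, ROIImage) else np.asarray(image)
    if pixels.ndim == 2:
        pixels = pixels[:, :, None]
    if pixels.shape[2] != config.in_channels:
        raise ValueError(f"image has {pixels.shape[2]} channels; encoder expects "
                         f"{config.in_channels}")
    if pixels.shape[:2] != tuple(config.input_size):
        pixels = _sk_resize(pixels, config.input_size, anti_aliasing=True,
                            preserve_range=True)
    mean = np.asarray(config.normalization_mean)
    std = np.asarray(config.normalization_std)
    out = (pixels - mean) / std
    return np.ascontiguousarray(out.transpose(2, 0, 1), dtype=np.float32)


def augment_image(pixels: np.ndarray, rng: np.random.Generator,
                  ops=("hflip", "vflip", "brightness", "contrast")) -> np.ndarray:
    """Randomised augmentation on a [0,1] channels-last image."""
    out = pixels
    for op in ops:
        if op == "hflip":
            if rng.random() < 0.5:
                out = out[:, ::-1]
        elif op == "vflip":
            if rng.random() < 0.5:
                out = out[::-1]
        elif op == "rot90":
            out = np.rot90(out, k=int(rng.integers(0, 4)), axes=(0, 1))
        elif op == "brightness":
            out = out + rng.uniform(-0.1, 0.1)
        elif op == "contrast":
            m = out.mean()
            out = (out - m) * rng.uniform(0.8, 1.2) + m
        else:
            raise ValueError(f"unknown augmentation {op!r}")
    return np.clip(out, 0.0, 1.0)


def encode_bag(bag_images, encoder: nn.Module, config: EncoderConfig,
               patient_id: str = "", order=None) -> EmbeddingSequence:
    """Embed every image of a bag with the shared encoder (eval mode)."""
    if len(bag_images) == 0:
        raise ValueError("empty bag")
    encoder.eval()
    batch = np.stack([img if (isinstance(img, np.ndarray) and img.ndim == 3
                              and img.shape[0] == config.in_channels)
                      else preprocess(img, config) for img in bag_images])
    emb = encoder(Tensor(batch)).data
    return EmbeddingSequence(patient_id=patient_id, embeddings=emb,
                             order=np.arange(len(bag_images)) if order is None
                             else np.asarray(order))


# ----------------------------------------------------------- ROI-level training
class RoiCoxModel(nn.Module):
    """Shared trunk plus a scalar Cox head over single ROIs."""

    def __init__(self, encoder: nn.Module, config: EncoderConfig, seed: int = 0):
        super().__init__()
        self.encoder = encoder
        self.config = config
        self.head = nn.Linear(config.embedding_dim, 1, np.random.default_rng(seed + 17))

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.encoder(x))[:, 0]

    def predict_risks(self, images) -> np.ndarray:
        self.eval()
        batch = np.stack([preprocess(img, self.config) for img in images])
        return self(Tensor(batch)).data.astype(np.float64)


def train_roi_cox_model(model: RoiCoxModel, roi_dataset, train_cfg: TrainConfig,
                        verbose: bool = False) -> list[dict]:
    """Minimise the Cox loss over ROI minibatches; returns per-epoch history.

    ``roi_dataset`` is a list of (image, SurvivalRecord) pairs where each ROI
    inherits its patient's observed time and event flag.
    """
    if not roi_dataset:
        raise ValueError("empty ROI dataset")
    times = np.array([rec.time for _, rec in roi_dataset])
    events = np.array([rec.event for _, rec in roi_dataset])
    if events.sum() == 0:
        raise ValueError("all-censored ROI dataset: the Cox loss has no events")
    pixels = [img.pixels if isinstance(img, ROIImage) else np.asarray(img)
              for img, _ in roi_dataset]
    rng = np.random.default_rng(train_cfg.seed)
    opt = nn.AdamW(model.parameters(), lr=train_cfg.lr,
                   weight_decay=train_cfg.weight_decay)
    sched = nn.ExponentialLR(opt, train_cfg.lr_gamma)
    n = len(pixels)
    history = []
    for epoch in range(train_cfg.epochs):
        model.train()
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = perm[start:start + train_cfg.batch_size]
            if events[idx].sum() == 0:
                warnings.warn("skipping all-censored minibatch", stacklevel=2)
                continue
            batch = np.stack([
                preprocess(augment_image(pixels[i], rng, train_cfg.augment),
                           model.config) for i in idx])
            h = model(Tensor(batch))
            loss = nn.cox_ph_loss(h, times[idx], events[idx])
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(opt.params, train_cfg.grad_clip)
            opt.step()
            losses.append(loss.item())
        sched.step()
        history.append({"epoch": epoch, "loss": float(np.mean(losses)) if losses else np.nan,
                        "lr": sched.lr})
        if verbose:
            print(f"[roi] epoch {epoch:3d} loss {history[-1]['loss']:.4f}")
    return history


def fine_tune_roi_level(encoder: nn.Module, roi_dataset, config: EncoderConfig,
                        train_cfg: TrainConfig) -> nn.Module:
    """Stage-1 fine-tuning: train trunk+scalar head on ROIs, then freeze front.

    The temporary head is discarded; only the trunk transfers to the
    aggregation model, with the front ``config.frozen_fraction`` of its
    parameter groups frozen.
    """
    model = RoiCoxModel(encoder, config, seed=train_cfg.seed)
    train_roi_cox_model(model, roi_dataset, train_cfg)
    freeze_front(encoder, config.frozen_fraction)
    return encoder
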