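"""The attention-LSTM aggregation network for patient-level Cox regression.

A patient's bag of ROIs is sampled with replacement to a fixed length N
(default 10), augmented and shuffled during training, and embedded by the
weight-shared CNN.  The embedding sequence then passes through two
Attention-LSTM blocks — multi-head *self*-attention + a two-stacked LSTM,
then multi-head *co*-attention (whose query is, by default, the original
CNN embedding sequence) + another two-stacked LSTM — and a small MLP maps a
summary of the final hidden sequence to a single log-hazard.  Training
minimises the Cox negative partial log-likelihood with risk sets formed
within each minibatch, AdamW, gradient-norm clipping and optional
exponential learning-rate decay.

Ablation switches (``use_attention``, ``use_lstm``, augmentation and
freezing toggles) reproduce the standard component-removal variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .encoder import (EncoderConfig, TrainConfig, augment_image, build_encoder,
                      preprocess)
from .simulator import PatientBag
from .survival import RiskPrediction, concordance_index

__all__ = [
    "AttentionLSTMBlockConfig", "DalanConfig", "AttentionLSTMBlock", "DalanModel",
    "forward_bag", "train_dalan", "predict_bags", "sample_bag",
]


@dataclass
class AttentionLSTMBlockConfig:
    n_heads: int = 4
    model_dim: int = 256
    lstm_layers: int = 2
    lstm_hidden: int = 256
    co_attention: bool = False
    scale: str = "sqrt"            # "sqrt" (standard) or "linear" (score / d)

    def __post_init__(self):
        if self.model_dim % self.n_heads:
            raise ValueError("model_dim must be divisible by n_heads")
        if self.lstm_layers < 1:
            raise ValueError("lstm_layers must be >= 1")


@dataclass
class DalanConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    block1: AttentionLSTMBlockConfig = field(default_factory=AttentionLSTMBlockConfig)
    block2: AttentionLSTMBlockConfig = field(
        default_factory=lambda: AttentionLSTMBlockConfig(co_attention=True))
    mlp_dims: tuple[int, ...] = (64,)
    bag_sample_size: int = 10
    inference_draws: int = 8
    summary: str = "last"          # "last" hidden state or "mean" pooling
    co_query: str = "embedding"    # query source of block 2: raw CNN embeddings
    use_attention: bool = True     # ablation: False -> LSTM-only blocks
    use_lstm: bool = True          # ablation: False -> attention-only blocks

    def __post_init__(self):
        if self.bag_sample_size < 1:
            raise ValueError("bag_sample_size must be >= 1")
        if self.summary not in ("last", "mean"):
            raise ValueError("summary must be 'last' or 'mean'")
        if self.co_query not in ("embedding", "block1"):
            raise ValueError("co_query must be 'embedding' or 'block1'")
        if not (self.use_attention or self.use_lstm):
            raise ValueError("at least one of attention/LSTM must be enabled")


class AttentionLSTMBlock(nn.Module):
    """Multi-head (co-)attention followed by a stacked LSTM over the sequence."""

    def __init__(self, cfg: AttentionLSTMBlockConfig, rng: np.random.Generator,
                 use_attention: bool = True, use_lstm: bool = True):
        super().__init__()
        self.cfg = cfg
        self.use_attention = use_attention
        self.use_lstm = use_lstm
        if use_attention:
            self.attention = nn.MultiHeadAttention(cfg.model_dim, cfg.n_heads, rng,
                                                   scale=cfg.scale)
        if use_lstm:
            self.lstm = nn.LSTM(cfg.model_dim, cfg.lstm_hidden, cfg.lstm_layers, rng)

    def forward(self, x: Tensor, query: Tensor | None = None) -> Tensor:
        if self.use_attention:
            q = query if (self.cfg.co_attention and query is not None) else x
            x = self.attention(q, x)
        if self.use_lstm:
            x = self.lstm(x)
        return x


class DalanModel(nn.Module):
    def __init__(self, config: DalanConfig, seed: int = 0,
                 encoder: nn.Module | None = None):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder = encoder if encoder is not None else build_encoder(config.encoder, seed=seed)
        self.block1 = AttentionLSTMBlock(config.block1, rng,
                                         config.use_attention, config.use_lstm)
        self.block2 = AttentionLSTMBlock(config.block2, rng,
                                         config.use_attention, config.use_lstm)
        dims = (config.block2.lstm_hidden if config.use_lstm else config.block2.model_dim,
                *config.mlp_dims, 1)
        layers = []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            layers.append(nn.Linear(a, b, rng))
            if i < len(dims) - 2:
                layers.append(nn.ReLU())
        self.mlp = nn.Sequential(*layers)

    def aggregate(self, embeddings: Tensor) -> Tensor:
        """(B, N, D) embedding sequences -> (B,) log-hazards."""
        s1 = self.block1(embeddings)
        query = embeddings if self.config.co_query == "embedding" else s1
        s2 = self.block2(s1, query=query)
        if self.config.summary == "last":
            pooled = s2[:, -1, :]
        else:
            pooled = s2.mean(axis=1)
        return self.mlp(pooled)[:, 0]

    def forward(self, images: np.ndarray, bag_size: int) -> Tensor:
        """(B*N, C, H, W) preprocessed images -> (B,) log-hazards."""
        emb = self.encoder(Tensor(images))
        B = images.shape[0] // bag_size
        return self.aggregate(emb.reshape(B, bag_size, emb.shape[-1]))


# -------------------------------------------------------------- bag plumbing
def sample_bag(bag: PatientBag, n: int, rng: np.random.Generator,
               training: bool, config: DalanConfig,
               augment_ops=("hflip", "vflip", "brightness", "contrast")) -> np.ndarray:
    """Sample ``n`` ROIs with replacement; augment and shuffle when training.

    Returns a (n, C, H, W) float32 array ready for the encoder.  Sampling
    with replacement plus order shuffling makes the model robust to input
    order and to intra-bag heterogeneity.
    """
    if not bag.rois:
        raise ValueError("empty bag")
    idx = rng.integers(0, len(bag.rois), size=n)
    if training:
        rng.shuffle(idx)
    imgs = []
    for i in idx:
        px = bag.rois[i].pixels
        if training and augment_ops:
            px = augment_image(px, rng, augment_ops)
        imgs.append(preprocess(px, config.encoder))
    return np.stack(imgs)


def forward_bag(bag: PatientBag, model: DalanModel, rng: np.random.Generator,
                training: bool = False,
                augment_ops=("hflip", "vflip", "brightness", "contrast")) -> RiskPrediction:
    """Predict one patient's log-hazard.

    At inference the prediction is the average over ``inference_draws``
    independent ROI samplings (reproducible given the generator state).
    """
    cfg = model.config
    draws = 1 if training else cfg.inference_draws
    model.train() if training else model.eval()
    values = []
    for _ in range(draws):
        batch = sample_bag(bag, cfg.bag_sample_size, rng, training, cfg, augment_ops)
        h = model(batch, cfg.bag_sample_size)
        values.append(float(h.data[0]))
    return RiskPrediction(patient_id=bag.patient_id, log_hazard=float(np.mean(values)))


def predict_bags(model: DalanModel, bags, seed: int = 0) -> list[RiskPrediction]:
    """Batched inference over a cohort, averaging over inference draws."""
    cfg = model.config
    model.eval()
    rng = np.random.default_rng(seed)
    totals = np.zeros(len(bags))
    for _ in range(cfg.inference_draws):
        batch = np.concatenate([sample_bag(b, cfg.bag_sample_size, rng,
                                           training=False, config=cfg) for b in bags])
        totals += model(batch, cfg.bag_sample_size).data.astype(np.float64)
    totals /= cfg.inference_draws
    return [RiskPrediction(patient_id=b.patient_id, log_hazard=float(v))
            for b, v in zip(bags, totals)]


# ------------------------------------------------------------------- training
def train_dalan(model: DalanModel, train_bags, train_cfg: TrainConfig,
                val_bags=None, augment: bool = True,
                verbose: bool = False) -> list[dict]:
    """Bag-level Cox training; returns per-epoch history rows.

    Each minibatch stacks ``bag_sample_size`` sampled-with-replacement,
    augmented, shuffled ROIs per patient; the partial-likelihood risk sets
    are formed within the minibatch.  Batches without any event are skipped
    with a warning.
    """
    if len(train_bags) < 2:
        raise ValueError("need at least two training bags")
    cfg = model.config
    rng = np.random.default_rng(train_cfg.seed)
    times = np.array([b.record.time for b in train_bags])
    events = np.array([b.record.event for b in train_bags])
    if events.sum() == 0:
        raise ValueError("all-censored training set")
    opt = nn.AdamW(model.parameters(), lr=train_cfg.lr,
                   weight_decay=train_cfg.weight_decay)
    sched = nn.ExponentialLR(opt, train_cfg.lr_gamma)
    ops = train_cfg.augment if augment else ()
    n = len(train_bags)
    history = []
    for epoch in range(train_cfg.epochs):
        model.train()
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = perm[start:start + train_cfg.batch_size]
            if len(idx) < 2 or events[idx].sum() == 0:
                if len(idx) >= 2:
                    warnings.warn("skipping all-censored minibatch", stacklevel=2)
                continue
            batch = np.concatenate([
                sample_bag(train_bags[i], cfg.bag_sample_size, rng,
                           training=True, config=cfg, augment_ops=ops) for i in idx])
            h = model(batch, cfg.bag_sample_size)
            loss = nn.cox_ph_loss(h, times[idx], events[idx])
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(opt.params, train_cfg.grad_clip)
            opt.step()
            losses.append(loss.item())
        sched.step()
        row = {"epoch": epoch, "loss": float(np.mean(losses)) if losses else np.nan,
               "lr": sched.lr, "val_cindex": np.nan}
        if val_bags is not None:
            preds = predict_bags(model, val_bags, seed=train_cfg.seed + 1000 + epoch)
            row["val_cindex"] = concordance_index(
                [p.log_hazard for p in preds], [b.record for b in val_bags], ties="half")
        history.append(row)
        if verbose:
            print(f"[dalan] epoch {epoch:3d} loss {row['loss']:.4f} "
                  f"val c-index {row['val_cindex']:.3f}")
    return history
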