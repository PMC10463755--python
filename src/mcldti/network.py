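"""The interaction-prediction network.

Architecture overview:

* **Drug encoder** — two modalities.  The rendered molecular image passes
  through a small CNN backbone (conv / batch-norm / ReLU / max-pool
  stages reducing each side by 16) whose spatial cells become tokens; the
  chemical text passes through a token embedding.  Each modality stream
  is refined by pre-norm multi-head self-attention (MSA) blocks and the
  two are combined as ``X_drug = lambda1 * X_img + lambda2 * X_txt`` with
  learnable (or fixed) scalar weights.
* **Target encoder** — embedded k-gram tokens of the protein sequence,
  refined by MSA blocks.  In the drug-drug (DDI) variant the partner is a
  second drug encoded by the same drug encoder.
* **Decoders** — one per entity, each an MSA block followed by a
  multi-head cross-attention (MCA) block whose queries come from the
  decoder's own stream and keys/values from the other entity, producing
  the interaction maps Z_drug->target and Z_target->drug.
* **Fusion head** — the two maps, resampled to a common token length, are
  stacked as a 2-channel image and passed through Conv2D, a token-axis
  mean collapse, Conv1D, an MLP and a final fully connected layer to one
  logit, squashed to an interaction probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, stack
from .nn.layers import (
    BatchNorm2d,
    Conv1dLayer,
    Conv2dLayer,
    CrossBlock,
    Dropout,
    Embedding,
    EncoderBlock,
    Linear,
    MaxPool2x2,
    Module,
    Parameter,
)


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Every architecture hyperparameter, including the ablation switches.

    Defaults are CPU-scale: they train in minutes on the synthetic
    benchmarks while keeping every architectural element of the full
    model.  Widths and lengths are freely configurable for larger runs.
    """

    h: int = 48                      # image side; must divide by 16
    channels: int = 3
    d_model: int = 32
    n_heads: int = 4
    depth: int = 1                   # MSA / MCA layers per block
    mlp_ratio: float = 2.0
    dropout: float = 0.2
    L_drug: int = 48                 # drug text token length
    L_tgt: int = 80                  # target token length
    k_drug: int = 1                  # k-gram size for drug text
    k_tgt: int = 3                   # k-gram size for target sequence
    conv_channels: tuple = (8, 16, 32, 64)
    fusion_conv2d_channels: int = 8
    fusion_conv1d_channels: int = 16
    fusion_hidden: int = 512
    lambda_mode: str = "learnable"   # or "fixed"
    lambda1: float = 1.0
    lambda2: float = 1.0
    modalities: tuple = ("image", "text")
    use_mca: bool = True
    mca_query_source: str = "self"   # or "other"
    task: str = "dti"                # or "ddi"
    drug_text_source: str = "chem"   # or "smiles" (image+SMILES ablation)

    def __post_init__(self):
        if self.h % 16:
            raise ConfigError(f"image side h={self.h} must be divisible by 16")
        if self.d_model % self.n_heads:
            raise ConfigError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}")
        if not self.modalities:
            raise ConfigError("at least one drug modality must be enabled")
        if not set(self.modalities) <= {"image", "text"}:
            raise ConfigError(f"unknown modalities {self.modalities}")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must lie in [0, 1)")
        if self.lambda_mode not in ("learnable", "fixed"):
            raise ConfigError(f"unknown lambda_mode {self.lambda_mode!r}")
        if self.task not in ("dti", "ddi"):
            raise ConfigError(f"unknown task {self.task!r}")
        if len(self.conv_channels) != 4:
            raise ConfigError("conv_channels must list 4 stage widths")

    @property
    def n_img_tokens(self) -> int:
        return (self.h // 16) ** 2

    @property
    def L_drug_eff(self) -> int:
        """Token length of the combined drug stream."""
        return self.L_drug if "text" in self.modalities else self.n_img_tokens

    @property
    def L_tgt_eff(self) -> int:
        return self.L_drug_eff if self.task == "ddi" else self.L_tgt

    @property
    def L_fuse(self) -> int:
        return min(self.L_drug_eff, self.L_tgt_eff)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["conv_channels"] = list(self.conv_channels)
        d["modalities"] = list(self.modalities)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "conv_channels" in d:
            d["conv_channels"] = tuple(d["conv_channels"])
        if "modalities" in d:
            d["modalities"] = tuple(d["modalities"])
        return cls(**d)


@dataclass
class FeatureMap:
    """L x d token matrix plus its padding mask."""

    tokens: Tensor
    pad_mask: np.ndarray | None = None

    def __post_init__(self):
        if not isinstance(self.tokens, Tensor):
            self.tokens = Tensor(self.tokens)


def resample_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Adaptive token-axis averaging matrix (n_out x n_in), rows sum to 1."""
    m = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo = (i * n_in) // n_out
        hi = -(-((i + 1) * n_in) // n_out)  # ceil
        m[i, lo:hi] = 1.0 / (hi - lo)
    return m


def resample_tokens(x: Tensor, n_out: int) -> Tensor:
    """Resample a (B, L, d) token stream to length n_out by averaging."""
    n_in = x.shape[-2]
    if n_in == n_out:
        return x
    return Tensor(resample_matrix(n_in, n_out)) @ x


def combine_modalities(x_img: FeatureMap | None, x_txt: FeatureMap | None,
                       lam1, lam2) -> FeatureMap:
    """Weighted sum of the two drug modality streams.

    Image tokens are resampled along the token axis to the text length
    before summation.  With a single modality present this is a
    pass-through of that modality (the ablation configurations).
    """
    if x_img is None and x_txt is None:
        raise ConfigError("at least one modality stream is required")
    if x_txt is None:
        return x_img
    if x_img is None:
        return x_txt
    img = resample_tokens(x_img.tokens, x_txt.tokens.shape[-2])
    lam1 = lam1 if isinstance(lam1, Tensor) else Tensor(float(lam1))
    lam2 = lam2 if isinstance(lam2, Tensor) else Tensor(float(lam2))
    tokens = img * lam1 + x_txt.tokens * lam2
    # the image contributes at every position, so nothing stays padded
    mask = np.zeros(tokens.shape[1], dtype=bool)
    return FeatureMap(tokens=tokens, pad_mask=mask)


class ConvBackbone(Module):
    """Four conv/BN/ReLU/max-pool stages, then a linear projection to d_model.

    Each stage halves the spatial side, so an h x h image becomes
    (h/16)^2 tokens.  Convolutions use replicate ("edge") padding so that
    a spatially constant image yields identical token vectors.
    """

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        chans = (cfg.channels,) + tuple(cfg.conv_channels)
        self.convs = [Conv2dLayer(chans[i], chans[i + 1], 3, rng, padding=1,
                                  pad_mode="edge") for i in range(4)]
        self.norms = [BatchNorm2d(c) for c in cfg.conv_channels]
        self.pool = MaxPool2x2()
        self.proj = Linear(cfg.conv_channels[-1], cfg.d_model, rng)

    def __call__(self, images: Tensor) -> FeatureMap:
        x = images
        for conv, norm in zip(self.convs, self.norms):
            x = self.pool(norm(conv(x)).relu())
        B, C, Hs, Ws = x.shape
        tokens = x.reshape(B, C, Hs * Ws).swapaxes(1, 2)  # row-major cells
        tokens = self.proj(tokens)
        return FeatureMap(tokens=tokens,
                          pad_mask=np.zeros(Hs * Ws, dtype=bool))


def conv_backbone(images: np.ndarray, backbone: ConvBackbone) -> FeatureMap:
    """Functional wrapper: run images (B, h, h, c) through a backbone."""
    x = Tensor(np.asarray(images).transpose(0, 3, 1, 2))
    return backbone(x)


class _TokenEncoder(Module):
    """Embedding + learned positional embedding + MSA blocks."""

    def __init__(self, n_vocab: int, L: int, cfg: ModelConfig, rng):
        super().__init__()
        self.emb = Embedding(n_vocab, cfg.d_model, rng)
        self.pos = Parameter(rng.normal(0.0, 0.02, size=(L, cfg.d_model)))
        self.blocks = [EncoderBlock(cfg.d_model, cfg.n_heads, cfg.mlp_ratio,
                                    cfg.dropout, rng) for _ in range(cfg.depth)]

    def __call__(self, tokens: np.ndarray, pad_mask: np.ndarray) -> FeatureMap:
        x = self.emb(tokens) + self.pos
        for blk in self.blocks:
            x = blk(x, pad_mask=pad_mask)
        return FeatureMap(tokens=x, pad_mask=pad_mask)


class MCLDTINet(Module):
    """The full two-entity interaction classifier."""

    def __init__(self, cfg: ModelConfig, vocab_drug_size: int,
                 vocab_tgt_size: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        d = cfg.d_model

        if "image" in cfg.modalities:
            self.backbone = ConvBackbone(cfg, rng)
            self.img_pos = Parameter(
                rng.normal(0.0, 0.02, size=(cfg.n_img_tokens, d)))
            self.img_msa = [EncoderBlock(d, cfg.n_heads, cfg.mlp_ratio,
                                         cfg.dropout, rng)
                            for _ in range(cfg.depth)]
        if "text" in cfg.modalities:
            self.txt_enc = _TokenEncoder(vocab_drug_size, cfg.L_drug, cfg, rng)

        if cfg.lambda_mode == "learnable" and len(cfg.modalities) == 2:
            self.lam1 = Parameter(np.asarray(cfg.lambda1))
            self.lam2 = Parameter(np.asarray(cfg.lambda2))
        else:
            self.lam1, self.lam2 = cfg.lambda1, cfg.lambda2

        if cfg.task == "dti":
            self.tgt_enc = _TokenEncoder(vocab_tgt_size, cfg.L_tgt, cfg, rng)
        # in DDI mode the partner reuses the drug encoder (no extra params)

        self.drug_dec_msa = [EncoderBlock(d, cfg.n_heads, cfg.mlp_ratio,
                                          cfg.dropout, rng)
                             for _ in range(cfg.depth)]
        self.tgt_dec_msa = [EncoderBlock(d, cfg.n_heads, cfg.mlp_ratio,
                                         cfg.dropout, rng)
                            for _ in range(cfg.depth)]
        if cfg.use_mca:
            self.drug_dec_mca = [CrossBlock(d, cfg.n_heads, cfg.mlp_ratio,
                                            cfg.dropout, rng,
                                            query_source=cfg.mca_query_source)
                                 for _ in range(cfg.depth)]
            self.tgt_dec_mca = [CrossBlock(d, cfg.n_heads, cfg.mlp_ratio,
                                           cfg.dropout, rng,
                                           query_source=cfg.mca_query_source)
                                for _ in range(cfg.depth)]

        self.fuse_conv2d = Conv2dLayer(2, cfg.fusion_conv2d_channels, 3, rng)
        self.fuse_conv1d = Conv1dLayer(cfg.fusion_conv2d_channels,
                                       cfg.fusion_conv1d_channels, 3, rng)
        self.fuse_mlp = Linear(cfg.fusion_conv1d_channels * d,
                               cfg.fusion_hidden, rng)
        self.fuse_drop = Dropout(cfg.dropout)
        self.fuse_fc = Linear(cfg.fusion_hidden, 1, rng)

    # -- encoders -------------------------------------------------------------
    def encode_drug(self, batch: dict, prefix: str = "drug") -> FeatureMap:
        cfg = self.cfg
        x_img = x_txt = None
        if "image" in cfg.modalities:
            images = Tensor(batch[f"{prefix}_images"])
            fmap = self.backbone(images)
            x = fmap.tokens + self.img_pos
            for blk in self.img_msa:
                x = blk(x)
            x_img = FeatureMap(tokens=x, pad_mask=fmap.pad_mask)
        if "text" in cfg.modalities:
            x_txt = self.txt_enc(batch[f"{prefix}_tokens"],
                                 batch[f"{prefix}_mask"])
        return combine_modalities(x_img, x_txt, self.lam1, self.lam2)

    def encode_target(self, batch: dict) -> FeatureMap:
        if self.cfg.task == "ddi":
            return self.encode_drug(batch, prefix="partner")
        return self.tgt_enc(batch["tgt_tokens"], batch["tgt_mask"])

    # -- decoders -------------------------------------------------------------
    def decode_pair(self, x_drug: FeatureMap, x_tgt: FeatureMap):
        """Bi-directional cross learning -> (Z_drug->target, Z_target->drug)."""
        d, t = x_drug.tokens, x_tgt.tokens
        for blk in self.drug_dec_msa:
            d = blk(d, pad_mask=x_drug.pad_mask)
        for blk in self.tgt_dec_msa:
            t = blk(t, pad_mask=x_tgt.pad_mask)
        if self.cfg.use_mca:
            d_in, t_in = d, t
            for blk in self.drug_dec_mca:
                d = blk(d, t_in, other_pad_mask=x_tgt.pad_mask,
                        stream_pad_mask=x_drug.pad_mask)
            for blk in self.tgt_dec_mca:
                t = blk(t, d_in, other_pad_mask=x_drug.pad_mask,
                        stream_pad_mask=x_tgt.pad_mask)
        return (FeatureMap(tokens=d, pad_mask=x_drug.pad_mask),
                FeatureMap(tokens=t, pad_mask=x_tgt.pad_mask))

    # -- fusion head ----------------------------------------------------------
    def fuse_predict(self, z_dt: FeatureMap, z_td: FeatureMap) -> Tensor:
        """Fuse the two interaction maps into a probability in (0, 1)."""
        L = self.cfg.L_fuse
        a = resample_tokens(z_dt.tokens, L)
        b = resample_tokens(z_td.tokens, L)
        x = stack([a, b], axis=1)              # (B, 2, L, d)
        x = self.fuse_conv2d(x).relu()
        x = x.mean(axis=2)                     # collapse token axis -> (B, C, d)
        x = self.fuse_conv1d(x).relu()
        B = x.shape[0]
        x = x.reshape(B, -1)
        x = self.fuse_drop(self.fuse_mlp(x).relu())
        logit = self.fuse_fc(x)
        return logit.sigmoid().reshape(B)

    def __call__(self, batch: dict) -> Tensor:
        x_drug = self.encode_drug(batch)
        x_tgt = self.encode_target(batch)
        z_dt, z_td = self.decode_pair(x_drug, x_tgt)
        p = self.fuse_predict(z_dt, z_td)
        if not np.all(np.isfinite(p.data)):
            raise FloatingPointError("non-finite activations in forward pass")
        return p
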