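"""The encoder-transformer-decoder contact-map predictor.

Two 1D convolutional encoders (sequence: 5 channels; genomic features: 2
channels) reduce a 2-Mb input to 256 bins through a stride-2 header and
twelve convolution modules (a shape-preserving residual block followed by
a stride-2 scaling block, hidden widths 32,32,32,32,64,64,128,128,128,
128,256,256).  The concatenated encoder outputs feed a transformer stack
(eight attention layers, eight heads, relative key-query positional
embedding), whose per-bin features are pairwise-concatenated into a
512-channel 256x256 grid and decoded by five dilated 2D residual blocks
(dilations 2,4,8,16,32) and a final 1x1 convolution to a single-channel
256x256 map.  The full-scale and desk-scale configurations share this
one code path.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor

FULL_SCHEDULE = (32, 32, 32, 32, 64, 64, 128, 128, 128, 128, 256, 256)
DESK_SCHEDULE = (8, 8, 8, 16, 16, 32, 32, 64, 64)


@dataclass
class ModelConfig:
    window_length: int = 2_097_152
    bin_size: int = 8_192
    seq_channels: int = 5
    feature_channels: int = 2
    encoder_hidden_schedule: Sequence[int] = FULL_SCHEDULE
    encoder_kernel_width: int = 5
    n_attention_layers: int = 8
    n_heads: int = 8
    d_model: int = 256
    ffn_dim: Optional[int] = None
    decoder_dilations: Sequence[int] = (2, 4, 8, 16, 32)
    decoder_channels: int = 256
    seed: int = 0

    def __post_init__(self):
        self.encoder_hidden_schedule = tuple(self.encoder_hidden_schedule)
        self.decoder_dilations = tuple(self.decoder_dilations)
        n = self.n_bins
        if n * self.bin_size != self.window_length or n & (n - 1):
            raise ValueError("window_length / bin_size must be a power of two")
        # one halving from the stride-2 header plus one per scaling block
        needed = int(math.log2(self.window_length // n)) - 1
        if len(self.encoder_hidden_schedule) != needed:
            raise ValueError(
                f"encoder schedule must have {needed} entries for "
                f"window {self.window_length} at {n} bins")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def n_bins(self) -> int:
        return self.window_length // self.bin_size

    @classmethod
    def full_scale(cls, **overrides) -> "ModelConfig":
        return cls(**overrides)

    @classmethod
    def desk_scale(cls, **overrides) -> "ModelConfig":
        """Small configuration trainable on one CPU in minutes."""
        kw = dict(window_length=65_536, bin_size=1_024,
                  encoder_hidden_schedule=DESK_SCHEDULE,
                  n_attention_layers=2, n_heads=2, d_model=32,
                  decoder_channels=16)
        kw.update(overrides)
        return cls(**kw)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


def decoder_receptive_field(dilations: Sequence[int], kernel: int = 3,
                            convs_per_block: int = 2) -> int:
    """Receptive-field side (cells) of the dilated decoder stack."""
    return 1 + convs_per_block * (kernel - 1) * sum(dilations)


class ResidualBlock1d(nn.Module):
    """Two same-padded kernel-5 convolutions with BN/ReLU and an additive skip."""

    def __init__(self, ch, kernel, rng):
        super().__init__()
        pad = kernel // 2
        self.conv1 = nn.Conv1d(ch, ch, kernel, padding=pad, rng=rng)
        self.bn1 = nn.BatchNorm1d(ch)
        self.conv2 = nn.Conv1d(ch, ch, kernel, padding=pad, rng=rng)
        self.bn2 = nn.BatchNorm1d(ch)
        # start near-identity: damping the branch at init stabilizes deep
        # stacks early in training (gamma stays trainable, unlike zero init
        # which the trailing ReLU would freeze)
        self.bn2.gamma.data[...] = 0.1

    def forward(self, x):
        h = ag.relu(self.bn1(self.conv1(x)))
        h = ag.relu(self.bn2(self.conv2(h)))
        return x + h


class ScalingBlock1d(nn.Module):
    """Stride-2 convolution halving length and rescaling channel width."""

    def __init__(self, cin, cout, kernel, rng):
        super().__init__()
        self.conv = nn.Conv1d(cin, cout, kernel, stride=2, padding=kernel // 2, rng=rng)
        self.bn = nn.BatchNorm1d(cout)

    def forward(self, x):
        return ag.relu(self.bn(self.conv(x)))


class Encoder1d(nn.Module):
    def __init__(self, in_ch, schedule, kernel, rng):
        super().__init__()
        self.header = nn.Conv1d(in_ch, schedule[0], kernel, stride=2,
                                padding=kernel // 2, rng=rng)
        ch = schedule[0]
        self.blocks: List[nn.Module] = []
        for i, cout in enumerate(schedule):
            res = ResidualBlock1d(ch, kernel, rng)
            sc = ScalingBlock1d(ch, cout, kernel, rng)
            setattr(self, f"res{i}", res)
            setattr(self, f"scale{i}", sc)
            self.blocks.append((res, sc))
            ch = cout

    def forward(self, x, captures: Optional[Dict[str, Tensor]] = None, prefix: str = ""):
        h = self.header(x)
        if captures is not None:
            captures[prefix + "header"] = h
        for i, (res, sc) in enumerate(self.blocks):
            h = sc(res(h))
            if captures is not None:
                captures[prefix + f"block{i}"] = h
        return h


class DecoderBlock2d(nn.Module):
    """Dilated 2D residual block; the skip is 1x1-projected on width change."""

    def __init__(self, cin, cout, dilation, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, padding=dilation, dilation=dilation, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=dilation, dilation=dilation, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.bn2.gamma.data[...] = 0.1   # near-identity start (see 1D block)
        self.proj = nn.Conv2d(cin, cout, 1, rng=rng) if cin != cout else None

    def forward(self, x):
        h = ag.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        skip = self.proj(x) if self.proj is not None else x
        return ag.relu(skip + h)


def pairwise_concat(features: Tensor) -> Tensor:
    """(N, L, D) per-bin features -> (N, 2D, L, L) grid.

    ``grid[:, :D, i, j] = f_i`` and ``grid[:, D:, i, j] = f_j``, so cell
    (i, j) concatenates the features at positions i and j and cells (i, j)
    and (j, i) are channel permutations of each other.
    """
    N, L, D = features.shape
    f = ag.transpose(features, (0, 2, 1))           # (N, D, L)
    rows = ag.broadcast_to(ag.reshape(f, (N, D, L, 1)), (N, D, L, L))
    cols = ag.broadcast_to(ag.reshape(f, (N, D, 1, L)), (N, D, L, L))
    return ag.concat([rows, cols], axis=1)


class ContactPredictor(nn.Module):
    """Forward contract: stacked window inputs -> log-space contact map."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.encoder_kernel_width
        sched = config.encoder_hidden_schedule
        self.seq_encoder = Encoder1d(config.seq_channels, sched, k, rng)
        self.feat_encoder = Encoder1d(config.feature_channels, sched, k, rng)
        # the two encoder outputs are concatenated channel-wise and reduced
        # to d_model by a learned width-1 convolution
        self.reduce = nn.Conv1d(2 * sched[-1], config.d_model, 1, rng=rng)
        self.transformer_layers: List[nn.TransformerLayer] = []
        for i in range(config.n_attention_layers):
            layer = nn.TransformerLayer(config.d_model, config.n_heads,
                                        config.n_bins, config.ffn_dim, rng)
            setattr(self, f"attn_layer{i}", layer)
            self.transformer_layers.append(layer)
        dils = config.decoder_dilations
        cin = 2 * config.d_model
        self.decoder_blocks: List[DecoderBlock2d] = []
        for i, d in enumerate(dils):
            blk = DecoderBlock2d(cin, config.decoder_channels, d, rng)
            setattr(self, f"dec_block{i}", blk)
            self.decoder_blocks.append(blk)
            cin = config.decoder_channels
        self.head = nn.Conv2d(config.decoder_channels, 1, 1, rng=rng)
        self.captures: Dict[str, Tensor] = {}

    # -- staged forward, exposed for attribution and tests ----------------
    def encode(self, x: Tensor, capture: bool = False) -> Tensor:
        caps = self.captures if capture else None
        hs = self.seq_encoder(x[:, :self.config.seq_channels], caps, "seq_encoder.")
        hf = self.feat_encoder(x[:, self.config.seq_channels:], caps, "feat_encoder.")
        h = self.reduce(ag.concat([hs, hf], axis=1))
        if capture:
            self.captures["reduce"] = h
        return ag.transpose(h, (0, 2, 1))            # (N, L, D)

    def transform(self, h: Tensor, capture: bool = False) -> Tensor:
        for i, layer in enumerate(self.transformer_layers):
            h = layer(h)
            if capture:
                self.captures[f"transformer.layer{i}"] = h
        return h

    def decode(self, grid: Tensor, capture: bool = False) -> Tensor:
        h = grid
        for i, blk in enumerate(self.decoder_blocks):
            h = blk(h)
            if capture:
                self.captures[f"decoder.block{i}"] = h
        out = self.head(h)                            # (N, 1, L, L)
        N, _, L, _ = out.shape
        return ag.reshape(out, (N, L, L))

    def forward(self, inputs, capture: bool = False) -> Tensor:
        if capture:
            self.captures = {}
        x = inputs if isinstance(inputs, Tensor) else Tensor(
            np.asarray(inputs, dtype=nn.DTYPE))
        if x.ndim == 2:
            x = ag.reshape(x, (1,) + x.shape)
        h = self.transform(self.encode(x, capture), capture)
        out = self.decode(pairwise_concat(h), capture)
        if capture:
            self.captures["output"] = out
        return out

    def attention_weights(self) -> List[np.ndarray]:
        """Per-layer (n_heads, L, L) softmax weights of the last forward pass."""
        return [l.attn.last_weights[0] for l in self.transformer_layers]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- persistence -------------------------------------------------------
    def save(self, path):
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            self.config.to_json().encode(), dtype=np.uint8)
        np.savez_compressed(path, **state)

    @classmethod
    def load(cls, path) -> "ContactPredictor":
        with np.load(path) as z:
            cfg = ModelConfig.from_json(bytes(z["__config__"]).decode())
            model = cls(cfg)
            model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return model
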