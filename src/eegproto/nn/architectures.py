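"""The two compact 1-D CNN architectures and their specs.

Both networks map fixed-length multichannel windows to a probability in
(0, 1). The cross-subject model is a three-stage residual CNN with
squeeze-and-excitation; the subject-dependent model is a five-block
depthwise-separable residual temporal CNN with SE and attention pooling
that fuses the raw window with two hand-crafted feature branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..records import ConfigurationError
from .autodiff import Tensor, concat
from .layers import (
    AttentionPool,
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    GaussianNoise,
    GlobalAveragePool,
    Layer,
    LayerNorm,
    MaxPool1D,
    SEBlock,
    SeparableConv1D,
    SpatialDropout1D,
)


@dataclass(frozen=True)
class ResNetSESpec:
    stage_filters: tuple[int, ...] = (64, 96, 128)
    stage_kernels: tuple[int, ...] = (11, 9, 7)
    stage_dilations: tuple[int, ...] = (1, 2, 4)
    blocks_per_stage: int = 2
    head_units: int = 128
    noise_std: float = 0.01
    dropout: float = 0.3

    @staticmethod
    def tiny() -> "ResNetSESpec":
        """Scaled-down spec for CPU-bound tests and smoke runs."""
        return ResNetSESpec(stage_filters=(8, 12, 16), head_units=16)


@dataclass(frozen=True)
class ResTcnSpec:
    stem_filters: int = 64
    stem_kernel: int = 5
    block_filters: tuple[int, ...] = (64, 96, 128, 192, 256)
    block_dilations: tuple[int, ...] = (1, 2, 4, 8, 12)
    kernel: int = 5
    pooled_blocks: int = 4
    raw_head_units: int = 192
    dwt_hidden: tuple[int, int] = (256, 128)
    feats_hidden: tuple[int, int] = (192, 128)
    fusion_units: int = 160
    noise_std: float = 0.01
    spatial_dropout: float = 0.1
    dropout: float = 0.3

    @staticmethod
    def tiny() -> "ResTcnSpec":
        return ResTcnSpec(
            stem_filters=8,
            block_filters=(8, 12, 16, 20, 24),
            raw_head_units=24,
            dwt_hidden=(32, 16),
            feats_hidden=(32, 16),
            fusion_units=24,
        )


class Model:
    """Base: parameter bookkeeping, checkpointing, and batched inference."""

    n_inputs = 1

    def params(self) -> list[Tensor]:
        raise NotImplementedError

    def forward(self, inputs: tuple[np.ndarray, ...], training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        raise NotImplementedError

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.data = w.copy()

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def predict_proba(self, inputs: tuple[np.ndarray, ...], batch_size: int = 256) -> np.ndarray:
        from .autodiff import no_grad

        n = inputs[0].shape[0]
        out = np.empty(n)
        with no_grad():
            for lo in range(0, n, batch_size):
                hi = min(lo + batch_size, n)
                batch = tuple(np.asarray(a[lo:hi]) for a in inputs)
                out[lo:hi] = self.forward(batch, training=False).data.ravel()
        return out


class _ResidualSEBlock(Layer):
    """Conv-BN-ReLU x2 with SE gating and a projected shortcut."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dilation: int,
                 rng: np.random.Generator, use_se: bool = True):
        self.conv1 = Conv1D(in_ch, out_ch, kernel, rng, dilation)
        self.bn1 = BatchNorm(out_ch)
        self.conv2 = Conv1D(out_ch, out_ch, kernel, rng, dilation)
        self.bn2 = BatchNorm(out_ch)
        self.se = SEBlock(out_ch, rng) if use_se else None
        self.proj = Conv1D(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def params(self):
        layers = [self.conv1, self.bn1, self.conv2, self.bn2, self.se, self.proj]
        return [p for layer in layers if layer is not None for p in layer.params()]

    def __call__(self, x, training=False, rng=None):
        y = self.bn1(self.conv1(x), training).relu()
        y = self.bn2(self.conv2(y), training).relu()
        if self.se is not None:
            y = self.se(y)
        shortcut = self.proj(x) if self.proj is not None else x
        return y + shortcut


class ResNetSE(Model):
    """Three-stage residual SE network for raw windows (cross-subject model)."""

    def __init__(self, win_samples: int, n_channels: int,
                 spec: ResNetSESpec = ResNetSESpec(), seed: int = 0):
        if win_samples % 8 != 0:
            raise ConfigurationError("window length must be divisible by 8 (three pooling stages)")
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.spec = spec
        self.noise = GaussianNoise(spec.noise_std)
        self.blocks: list[tuple[_ResidualSEBlock, MaxPool1D | None]] = []
        in_ch = n_channels
        for f, k, d in zip(spec.stage_filters, spec.stage_kernels, spec.stage_dilations):
            for i in range(spec.blocks_per_stage):
                pool = MaxPool1D(2) if i == 0 else None
                self.blocks.append((_ResidualSEBlock(in_ch, f, k, d, rng), pool))
                in_ch = f
        self.gap = GlobalAveragePool()
        self.drop1 = Dropout(spec.dropout)
        self.head = Dense(in_ch, spec.head_units, rng, activation="relu")
        self.drop2 = Dropout(spec.dropout)
        self.out = Dense(spec.head_units, 1, rng, activation="sigmoid")

    def params(self):
        out = []
        for block, _ in self.blocks:
            out += block.params()
        out += self.head.params() + self.out.params()
        return out

    def forward(self, inputs, training=False, rng=None):
        x = Tensor(np.asarray(inputs[0], dtype=np.float64))
        h = self.noise(x, training, rng)
        for block, pool in self.blocks:
            h = block(h, training, rng)
            if pool is not None:
                h = pool(h)
        h = self.gap(h)
        h = self.drop1(h, training, rng)
        h = self.head(h)
        h = self.drop2(h, training, rng)
        return self.out(h)

    def time_lengths(self, win_samples: int) -> list[int]:
        """Temporal length after each pooling stage (diagnostic)."""
        lengths = [win_samples]
        for _, pool in self.blocks:
            if pool is not None:
                lengths.append(lengths[-1] // 2)
        return lengths


class _SeparableResidualBlock(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, dilation: int,
                 rng: np.random.Generator, sdrop: float, use_se: bool = True):
        self.conv1 = SeparableConv1D(in_ch, out_ch, kernel, rng, dilation)
        self.bn1 = BatchNorm(out_ch)
        self.conv2 = SeparableConv1D(out_ch, out_ch, kernel, rng, dilation)
        self.bn2 = BatchNorm(out_ch)
        self.sdrop = SpatialDropout1D(sdrop)
        self.se = SEBlock(out_ch, rng) if use_se else None
        self.proj = Conv1D(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def params(self):
        layers = [self.conv1, self.bn1, self.conv2, self.bn2, self.se, self.proj]
        return [p for layer in layers if layer is not None for p in layer.params()]

    def __call__(self, x, training=False, rng=None):
        y = self.bn1(self.conv1(x), training).relu()
        y = self.sdrop(y, training, rng)
        y = self.bn2(self.conv2(y), training).relu()
        if self.se is not None:
            y = self.se(y)
        shortcut = self.proj(x) if self.proj is not None else x
        return y + shortcut


class ResTcnSEAttention(Model):
    """Three-branch hybrid (raw + DWT + FEATS) subject-dependent model.

    ``use_se=False`` / ``use_attention=False`` build the structural ablation
    variants (attention pooling replaced by global average pooling).
    """

    n_inputs = 3

    def __init__(self, win_samples: int, n_channels: int, dwt_dim: int = 175,
                 feats_dim: int = 167, spec: ResTcnSpec = ResTcnSpec(),
                 use_se: bool = True, use_attention: bool = True, seed: int = 0):
        if win_samples % 2 ** spec.pooled_blocks != 0:
            raise ConfigurationError("window length must be divisible by 16 (four pooled blocks)")
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.spec = spec
        self.use_attention = use_attention
        self.noise = GaussianNoise(spec.noise_std)
        self.stem = Conv1D(n_channels, spec.stem_filters, spec.stem_kernel, rng)
        self.blocks: list[tuple[_SeparableResidualBlock, MaxPool1D | None]] = []
        in_ch = spec.stem_filters
        for i, (f, d) in enumerate(zip(spec.block_filters, spec.block_dilations)):
            pool = MaxPool1D(2) if i < spec.pooled_blocks else None
            self.blocks.append(
                (_SeparableResidualBlock(in_ch, f, spec.kernel, d, rng, spec.spatial_dropout, use_se), pool)
            )
            in_ch = f
        self.pool = AttentionPool(in_ch, rng) if use_attention else GlobalAveragePool()
        self.raw_drop1 = Dropout(spec.dropout)
        self.raw_head = Dense(in_ch, spec.raw_head_units, rng, activation="relu")
        self.raw_drop2 = Dropout(spec.dropout)

        self.dwt_norm = LayerNorm(dwt_dim)
        self.dwt_fc1 = Dense(dwt_dim, spec.dwt_hidden[0], rng, activation="relu")
        self.dwt_drop = Dropout(spec.dropout)
        self.dwt_fc2 = Dense(spec.dwt_hidden[0], spec.dwt_hidden[1], rng, activation="relu")

        self.feats_norm = LayerNorm(feats_dim)
        self.feats_fc1 = Dense(feats_dim, spec.feats_hidden[0], rng, activation="relu")
        self.feats_drop = Dropout(spec.dropout)
        self.feats_fc2 = Dense(spec.feats_hidden[0], spec.feats_hidden[1], rng, activation="relu")

        fused = spec.raw_head_units + spec.dwt_hidden[1] + spec.feats_hidden[1]
        self.fusion = Dense(fused, spec.fusion_units, rng, activation="relu")
        self.fusion_drop = Dropout(spec.dropout)
        self.out = Dense(spec.fusion_units, 1, rng, activation="sigmoid")

    def params(self):
        out = self.stem.params()
        for block, _ in self.blocks:
            out += block.params()
        if isinstance(self.pool, AttentionPool):
            out += self.pool.params()
        for layer in (
            self.raw_head, self.dwt_norm, self.dwt_fc1, self.dwt_fc2,
            self.feats_norm, self.feats_fc1, self.feats_fc2, self.fusion, self.out,
        ):
            out += layer.params()
        return out

    def forward(self, inputs, training=False, rng=None):
        raw, dwt, feats = (Tensor(np.asarray(a, dtype=np.float64)) for a in inputs)
        h = self.noise(raw, training, rng)
        h = self.stem(h)
        for block, pool in self.blocks:
            h = block(h, training, rng)
            if pool is not None:
                h = pool(h)
        h = self.pool(h)
        h = self.raw_drop1(h, training, rng)
        h = self.raw_head(h)
        raw_emb = self.raw_drop2(h, training, rng)

        d = self.dwt_fc1(self.dwt_norm(dwt))
        d = self.dwt_drop(d, training, rng)
        dwt_emb = self.dwt_fc2(d)

        f = self.feats_fc1(self.feats_norm(feats))
        f = self.feats_drop(f, training, rng)
        feats_emb = self.feats_fc2(f)

        fused = concat([raw_emb, dwt_emb, feats_emb], axis=-1)
        fused = self.fusion(fused)
        fused = self.fusion_drop(fused, training, rng)
        return self.out(fused)

    def time_lengths(self, win_samples: int) -> list[int]:
        lengths = [win_samples]
        for _, pool in self.blocks:
            lengths.append(lengths[-1] // 2 if pool is not None else lengths[-1])
        return lengths


#: Named ablation variants of the subject-dependent model.
ABLATION_VARIANTS: dict[str, dict] = {
    "res_tcn_se_attention": {"use_se": True, "use_attention": True},
    "res_tcn_se": {"use_se": True, "use_attention": False},
    "res_tcn_attention": {"use_se": False, "use_attention": True},
    "res_tcn": {"use_se": False, "use_attention": False},
}
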