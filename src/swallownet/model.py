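"""Paired pre/post-swallow change-detection network.

Architecture: a width-scalable inverted-residual convolutional encoder (a
compact MobileNetV3-style stack) is applied to the pre- and post-swallow mel
spectrograms separately — with shared (Siamese) weights by default — the two
feature maps are concatenated along channels, a decoder expands the
concatenated channel budget by 6x and then 2x (12x total) with 1x1
convolutions, and a fully convolutional head (global average pooling
followed by a 1x1 convolution) emits a single logit. Batch normalization
follows every convolution. The logit's sigmoid is the probability of the
aspiration class.

The shared encoder is evaluated once per step on the batch-stacked
[pre; post] input, so layer caches remain valid for the backward pass.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    InvertedResidual,
    Layer,
    ReLU,
    Sequential,
    sigmoid,
)


@dataclass(frozen=True)
class ModelConfig:
    """Detector hyperparameters.

    ``width_multiplier`` scales every channel count; 2.0 matches the
    memory-bound clinical configuration, 0.25 is the desk-scale default.
    ``decoder_expansions`` are the successive channel-expansion factors
    applied after concatenation (6 then 2, 12x total).
    """

    width_multiplier: float = 0.25
    base_channels: tuple[int, int, int, int] = (16, 24, 40, 64)
    expand_ratios: tuple[int, int, int] = (1, 4, 4)
    decoder_expansions: tuple[int, int] = (6, 2)
    shared_encoder: bool = True

    def __post_init__(self) -> None:
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if len(self.decoder_expansions) != 2:
            raise ValueError("decoder_expansions must be an ordered pair")

    def scaled(self, channels: int) -> int:
        return max(4, int(round(channels * self.width_multiplier)))

    @property
    def encoder_out_channels(self) -> int:
        return self.scaled(self.base_channels[-1])


def _build_encoder(cfg: ModelConfig, rng: np.random.Generator) -> Sequential:
    c = [cfg.scaled(ch) for ch in cfg.base_channels]
    e = cfg.expand_ratios
    return Sequential(
        [
            Conv2d(1, c[0], 3, stride=2, padding=1, rng=rng),  # stem
            BatchNorm2d(c[0]),
            ReLU(),
            InvertedResidual(c[0], c[1], e[0], stride=2, rng=rng),
            ReLU(),
            InvertedResidual(c[1], c[2], e[1], stride=2, rng=rng),
            ReLU(),
            InvertedResidual(c[2], c[3], e[2], stride=2, rng=rng),
            ReLU(),
        ]
    )


class PairedDetector:
    """Dual-input encoder + concatenation + expanding decoder + 1-logit head."""

    def __init__(self, cfg: ModelConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.encoder = _build_encoder(cfg, rng)
        self.encoder_post = None if cfg.shared_encoder else _build_encoder(cfg, rng)
        c_enc = cfg.encoder_out_channels
        c_cat = 2 * c_enc
        e1, e2 = cfg.decoder_expansions
        self.decoder = Sequential(
            [
                Conv2d(c_cat, e1 * c_cat, 1, rng=rng),
                BatchNorm2d(e1 * c_cat),
                ReLU(),
                Conv2d(e1 * c_cat, e1 * e2 * c_cat, 1, rng=rng),
                BatchNorm2d(e1 * e2 * c_cat),
                ReLU(),
            ]
        )
        self.head = Sequential(
            [GlobalAvgPool(), Conv2d(e1 * e2 * c_cat, 1, 1, rng=rng)]
        )
        self._c_enc = c_enc
        self.training = True

    # -- graph bookkeeping --------------------------------------------------

    def _modules(self) -> list[Sequential]:
        mods = [self.encoder]
        if self.encoder_post is not None:
            mods.append(self.encoder_post)
        mods.extend([self.decoder, self.head])
        return mods

    def param_items(self):
        names = ["encoder", "encoder_post", "decoder", "head"]
        for mod_name, mod in zip(
            names if self.encoder_post is not None else ["encoder", "decoder", "head"],
            self._modules(),
        ):
            for name, p, g in mod.param_items():
                yield f"{mod_name}.{name}", p, g

    def num_params(self) -> int:
        return sum(p.size for _, p, _ in self.param_items())

    def param_checksum(self) -> float:
        return float(sum(np.abs(p).sum() for _, p, _ in self.param_items()))

    def channel_trace(self) -> list[dict]:
        """Walk the built graph and report each stage's channel arithmetic."""
        cfg = self.cfg
        c = [cfg.scaled(ch) for ch in cfg.base_channels]
        e1, e2 = cfg.decoder_expansions
        c_cat = 2 * self._c_enc
        trace = [
            {"stage": "stem", "in_channels": 1, "out_channels": c[0]},
            {"stage": "encoder_block1", "in_channels": c[0], "out_channels": c[1]},
            {"stage": "encoder_block2", "in_channels": c[1], "out_channels": c[2]},
            {"stage": "encoder_block3", "in_channels": c[2], "out_channels": c[3]},
            {
                "stage": "concat",
                "in_channels": self._c_enc,
                "out_channels": c_cat,
                "factor": 2,
            },
            {
                "stage": "decoder_expand1",
                "in_channels": c_cat,
                "out_channels": self.decoder.layers[0].out_channels,
                "factor": e1,
            },
            {
                "stage": "decoder_expand2",
                "in_channels": self.decoder.layers[3].in_channels,
                "out_channels": self.decoder.layers[3].out_channels,
                "factor": e2,
            },
            {
                "stage": "head",
                "in_channels": self.head.layers[1].in_channels,
                "out_channels": 1,
            },
        ]
        return trace

    # -- forward / backward --------------------------------------------------

    def forward(self, pre: np.ndarray, post: np.ndarray) -> np.ndarray:
        """(B, 1, n_mels, n_frames) x 2 -> logits (B,)."""
        pre = np.asarray(pre, dtype=np.float64)
        post = np.asarray(post, dtype=np.float64)
        if pre.shape != post.shape:
            raise ValueError(f"branch shape mismatch: {pre.shape} vs {post.shape}")
        if pre.ndim != 4 or pre.shape[1] != 1:
            raise ValueError("inputs must be shaped (batch, 1, n_mels, n_frames)")
        b = pre.shape[0]
        for mod in self._modules():
            mod.training = self.training
        if self.encoder_post is None:
            stacked = np.concatenate([pre, post], axis=0)
            feats = self.encoder.forward(stacked)
            f_pre, f_post = feats[:b], feats[b:]
        else:
            f_pre = self.encoder.forward(pre)
            f_post = self.encoder_post.forward(post)
        cat = np.concatenate([f_pre, f_post], axis=1)
        out = self.head.forward(self.decoder.forward(cat))
        logits = out.reshape(b)
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite logits")
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        b = dlogits.shape[0]
        grad = dlogits.reshape(b, 1, 1, 1)
        grad = self.decoder.backward(self.head.backward(grad))
        c = self._c_enc
        g_pre, g_post = grad[:, :c], grad[:, c:]
        if self.encoder_post is None:
            self.encoder.backward(np.concatenate([g_pre, g_post], axis=0))
        else:
            self.encoder.backward(g_pre)
            self.encoder_post.backward(g_post)

    def predict_proba(self, logits: np.ndarray) -> np.ndarray:
        """Sigmoid of the logit: probability of the aspiration class."""
        return sigmoid(np.asarray(logits, dtype=np.float64))

    # -- persistence ----------------------------------------------------------

    def _stateful_layers(self):
        def walk(prefix: str, layer: Layer):
            if isinstance(layer, Sequential):
                for i, sub in enumerate(layer.layers):
                    yield from walk(f"{prefix}.{i}", sub)
            elif isinstance(layer, InvertedResidual):
                yield from walk(f"{prefix}.body", layer.body)
            else:
                yield prefix, layer

        names = (
            ["encoder", "decoder", "head"]
            if self.encoder_post is None
            else ["encoder", "encoder_post", "decoder", "head"]
        )
        for name, mod in zip(names, self._modules()):
            yield from walk(name, mod)

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for prefix, layer in self._stateful_layers():
            for name, p in layer.params.items():
                state[f"{prefix}.{name}"] = p.copy()
            if isinstance(layer, BatchNorm2d):
                state[f"{prefix}.running_mean"] = layer.running_mean.copy()
                state[f"{prefix}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for prefix, layer in self._stateful_layers():
            for name in layer.params:
                layer.params[name][...] = state[f"{prefix}.{name}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"{prefix}.running_mean"]
                layer.running_var[...] = state[f"{prefix}.running_var"]


def build_detector(cfg: ModelConfig | None = None, seed: int = 0) -> PairedDetector:
    """Construct a seeded detector from a ModelConfig."""
    return PairedDetector(cfg or ModelConfig(), seed=seed)


def save_checkpoint(
    path: str | Path,
    detector: PairedDetector,
    mel_config_dict: dict | None = None,
) -> None:
    """Single-file checkpoint: weights + ModelConfig + MelConfig (self-describing)."""
    meta = {
        "model_config": asdict(detector.cfg),
        "mel_config": mel_config_dict or {},
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **detector.state_dict(),
    )


def load_checkpoint(path: str | Path) -> tuple[PairedDetector, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        mc = meta["model_config"]
        mc["base_channels"] = tuple(mc["base_channels"])
        mc["expand_ratios"] = tuple(mc["expand_ratios"])
        mc["decoder_expansions"] = tuple(mc["decoder_expansions"])
        detector = PairedDetector(ModelConfig(**mc))
        detector.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    detector.training = False
    return detector, meta
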