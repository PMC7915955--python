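"""Size-configurable 3D fully-convolutional DenseNet (encoder-decoder).

The architecture follows the FC-DenseNet ("Tiramisu") pattern extended to
3D: an initial convolution, a down path of dense blocks each followed by a
transition down (1x1x1 convolution + average pooling), a bottleneck dense
block, and a mirrored up path of transposed-convolution transitions with
skip concatenations from the matching encoder scale.  Within a dense block
every layer receives the concatenation of the block input and all previous
layer outputs and contributes ``growth_rate`` feature maps.  The clinical
profile uses layers-per-block [3, 4, 4, 5, 7] with growth rate 12 and four
transitions; desk-scale profiles shrink every one of these knobs through
the same configuration object.

Normalization layers are omitted: the pipeline trains with batch size 1,
where batch statistics are meaningless (instance norm can be added later
without changing the interface).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Var, avg_pool, concat, conv3d, relu, transposed_conv3d
from .losses import softmax


@dataclass
class NetworkConfig:
    """Architecture hyperparameters of the FC-DenseNet."""

    layers_per_block: Tuple[int, ...] = (3, 4, 4, 5, 7)
    growth_rate: int = 12
    n_transitions: int = 4
    in_channels: int = 1
    out_channels: int = 2
    mode: str = "single_label"  # "single_label" (softmax) | "multilabel" (sigmoid)
    first_channels: int = 0  # 0 -> 2 * growth_rate
    kernel_size: Tuple[int, int, int] = (3, 3, 3)
    pool_factors: Tuple[Tuple[int, int, int], ...] = ()  # () -> (2,2,2) each
    append_coords: bool = False  # append 3 normalized coordinate channels

    def __post_init__(self) -> None:
        self.layers_per_block = tuple(int(v) for v in self.layers_per_block)
        if len(self.layers_per_block) != self.n_transitions + 1:
            raise ValueError(
                f"layers_per_block has {len(self.layers_per_block)} entries; "
                f"need n_transitions + 1 = {self.n_transitions + 1}")
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if self.mode not in ("single_label", "multilabel"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.pool_factors:
            self.pool_factors = tuple((2, 2, 2) for _ in range(self.n_transitions))
        else:
            self.pool_factors = tuple(tuple(int(v) for v in f) for f in self.pool_factors)
        if len(self.pool_factors) != self.n_transitions:
            raise ValueError("need one pool-factor triple per transition")
        if not self.first_channels:
            self.first_channels = 2 * self.growth_rate

    @property
    def total_downsampling(self) -> Tuple[int, int, int]:
        total = [1, 1, 1]
        for f in self.pool_factors:
            total = [t * v for t, v in zip(total, f)]
        return tuple(total)

    def validate_input_shape(self, spatial: Sequence[int]) -> None:
        total = self.total_downsampling
        if any(s % t for s, t in zip(spatial, total)):
            raise ValueError(
                f"input spatial shape {tuple(spatial)} not divisible by the "
                f"network's total downsampling {total}")

    def to_json(self) -> str:
        return json.dumps({
            "layers_per_block": list(self.layers_per_block),
            "growth_rate": self.growth_rate, "n_transitions": self.n_transitions,
            "in_channels": self.in_channels, "out_channels": self.out_channels,
            "mode": self.mode, "first_channels": self.first_channels,
            "kernel_size": list(self.kernel_size),
            "pool_factors": [list(f) for f in self.pool_factors],
            "append_coords": self.append_coords})

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        d = json.loads(s)
        d["layers_per_block"] = tuple(d["layers_per_block"])
        d["kernel_size"] = tuple(d["kernel_size"])
        d["pool_factors"] = tuple(tuple(f) for f in d["pool_factors"])
        return cls(**d)


class FCDenseNet3D:
    """A built network: parameter store + forward pass."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.params: Dict[str, Var] = {}
        self._rng = np.random.default_rng(seed)
        self._build()

    # -- parameter helpers ---------------------------------------------------
    def _conv_param(self, name: str, cin: int, cout: int, kernel) -> None:
        fan_in = cin * int(np.prod(kernel))
        std = np.sqrt(2.0 / fan_in)
        w = self._rng.normal(0.0, std, size=(cout, cin) + tuple(kernel))
        self.params[f"{name}.w"] = Var(w, requires_grad=True)
        self.params[f"{name}.b"] = Var(np.zeros(cout), requires_grad=True)

    def _build(self) -> None:
        cfg = self.config
        k = cfg.kernel_size
        g = cfg.growth_rate
        in_ch = cfg.in_channels + (3 if cfg.append_coords else 0)
        self._conv_param("first", in_ch, cfg.first_channels, k)
        ch = cfg.first_channels
        self._skip_channels: List[int] = []
        for i in range(cfg.n_transitions):
            for j in range(cfg.layers_per_block[i]):
                self._conv_param(f"down{i}.layer{j}", ch + j * g, g, k)
            ch += cfg.layers_per_block[i] * g
            self._skip_channels.append(ch)
            self._conv_param(f"td{i}", ch, ch, (1, 1, 1))
        for j in range(cfg.layers_per_block[cfg.n_transitions]):
            self._conv_param(f"bottleneck.layer{j}", ch + j * g, g, k)
        new_ch = cfg.layers_per_block[cfg.n_transitions] * g
        for i in range(cfg.n_transitions):
            factors = cfg.pool_factors[cfg.n_transitions - 1 - i]
            self._conv_param(f"tu{i}", new_ch, new_ch, factors)
            skip = self._skip_channels[cfg.n_transitions - 1 - i]
            n_layers = cfg.layers_per_block[cfg.n_transitions - 1 - i]
            cin = new_ch + skip
            for j in range(n_layers):
                self._conv_param(f"up{i}.layer{j}", cin + j * g, g, k)
            self._last_up_channels = cin + n_layers * g
            new_ch = n_layers * g
        if cfg.n_transitions == 0:
            self._last_up_channels = ch + new_ch  # degenerate: bottleneck only
        self._conv_param("head", self._last_up_channels, cfg.out_channels, (1, 1, 1))

    def parameters(self) -> Dict[str, Var]:
        return self.params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # -- forward -------------------------------------------------------------
    def _conv(self, name: str, x: Var) -> Var:
        return conv3d(x, self.params[f"{name}.w"], self.params[f"{name}.b"])

    def _dense_block(self, prefix: str, x: Var, n_layers: int):
        feats = [x]
        new = []
        for j in range(n_layers):
            inp = feats[0] if len(feats) == 1 else concat(feats)
            y = relu(self._conv(f"{prefix}.layer{j}", inp))
            feats.append(y)
            new.append(y)
        full = concat(feats)
        new_cat = new[0] if len(new) == 1 else concat(new)
        return full, new_cat

    def forward(self, x) -> Var:
        """Input (X, Y, Z) or (C, X, Y, Z) array -> per-voxel class scores
        of identical spatial size."""
        if not isinstance(x, Var):
            x = np.asarray(x)
            if x.ndim == 3:
                x = x[None]
            x = Var(x)
        cfg = self.config
        cfg.validate_input_shape(x.data.shape[1:])
        if cfg.append_coords:
            # normalized voxel-coordinate channels in [-1, 1]; lets the
            # network disambiguate position-defined (e.g. bilateral) classes
            spatial = x.data.shape[1:]
            axes = [np.linspace(-1.0, 1.0, n, dtype=x.data.dtype) if n > 1
                    else np.zeros(1, dtype=x.data.dtype) for n in spatial]
            coords = np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)
            x = Var(np.concatenate([x.data, coords], axis=0))
        h = relu(self._conv("first", x))
        skips: List[Var] = []
        for i in range(cfg.n_transitions):
            full, _ = self._dense_block(f"down{i}", h, cfg.layers_per_block[i])
            skips.append(full)
            h = avg_pool(self._conv(f"td{i}", full), cfg.pool_factors[i])
        full, new = self._dense_block("bottleneck", h, cfg.layers_per_block[cfg.n_transitions])
        if cfg.n_transitions == 0:
            return self._conv("head", full)
        for i in range(cfg.n_transitions):
            factors = cfg.pool_factors[cfg.n_transitions - 1 - i]
            up = transposed_conv3d(new, self.params[f"tu{i}.w"], self.params[f"tu{i}.b"], factors)
            merged = concat([up, skips[cfg.n_transitions - 1 - i]])
            full, new = self._dense_block(f"up{i}", merged, cfg.layers_per_block[cfg.n_transitions - 1 - i])
        return self._conv("head", full)

    def predict(self, x) -> Tuple[np.ndarray, np.ndarray]:
        """Deterministic inference: (probabilities, hard labels).

        Single-label mode: per-voxel softmax, labels by argmax (ties break
        toward the lower class index).  Multilabel mode: per-channel
        sigmoid, labels by a 0.5 threshold.
        """
        scores = self.forward(x).data
        if self.config.mode == "single_label":
            probs = softmax(scores.astype(np.float64))
            labels = probs.argmax(axis=0)
        else:
            probs = 1.0 / (1.0 + np.exp(-scores.astype(np.float64)))
            labels = (probs >= 0.5).astype(np.int64)
        return probs, labels

    # -- checkpointing -------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in state:
                raise KeyError(f"checkpoint missing parameter {k}")
            if state[k].shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            v.data = np.asarray(state[k], dtype=v.data.dtype).copy()

    def save(self, path) -> None:
        """Self-describing checkpoint: weights + architecture config."""
        np.savez_compressed(path, __config__=self.config.to_json(), **self.state_dict())

    @classmethod
    def load(cls, path) -> "FCDenseNet3D":
        with np.load(path, allow_pickle=False) as z:
            cfg = NetworkConfig.from_json(str(z["__config__"]))
            net = cls(cfg, seed=0)
            net.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return net

    def copy(self) -> "FCDenseNet3D":
        clone = FCDenseNet3D(self.config, seed=0)
        clone.load_state_dict(self.state_dict())
        return clone


def build_network(config: NetworkConfig, seed: int = 0) -> FCDenseNet3D:
    """Build a seeded FC-DenseNet; same (config, seed) -> identical weights."""
    return FCDenseNet3D(config, seed=seed)
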