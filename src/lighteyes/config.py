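"""Declarative configuration for the network, the loss and training runs.

Configs are plain dataclasses loadable from YAML or JSON files; keys are
lowercase (``nc``, ``nl``, ``narrow_width``, ``variant``, ...).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

VARIANTS = ("full", "A1", "A2", "A3")


@dataclass
class NetworkConfig:
    """Architecture description of the full-resolution segmentation network.

    Attributes
    ----------
    nc : int
        Filters per convolution in the wide encoder block (default 16).
    nl : int
        Number of encoder convolutions (default 24).
    narrow_width : int
        Filters after the width-reduction layer (default 8).
    variant : str
        ``full`` (three decoder branches + fusion) or one of the
        deep-supervision truncations ``A1``/``A2``/``A3``.
    kernel_size : int
        Spatial kernel side of every convolution (odd; default 3).
    pooling : str
        ``max`` or ``average`` for the decoder's single 2x2 pooling.
    upsample_mode : str
        ``bilinear`` or ``nearest`` for the pooled branch's x2 upsampling.
    fusion_input : str
        Whether the fusion convolution consumes the branch ``logits``
        (default) or ``probabilities`` (post-sigmoid maps).
    """

    nc: int = 16
    nl: int = 24
    narrow_width: int = 8
    variant: str = "full"
    kernel_size: int = 3
    pooling: str = "max"
    upsample_mode: str = "bilinear"
    fusion_input: str = "logits"

    def __post_init__(self) -> None:
        if self.nl < 2:
            raise ValueError(f"nl must be >= 2, got {self.nl}")
        if self.nc < 1:
            raise ValueError(f"nc must be >= 1, got {self.nc}")
        if self.narrow_width < 1:
            raise ValueError(f"narrow_width must be >= 1, got {self.narrow_width}")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.pooling not in ("max", "average"):
            raise ValueError(f"pooling must be 'max' or 'average', got {self.pooling!r}")
        if self.upsample_mode not in ("bilinear", "nearest"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        if self.fusion_input not in ("logits", "probabilities"):
            raise ValueError(f"unknown fusion_input {self.fusion_input!r}")

    # Width schedule: wide block is layers 1..nl//2, the width-reduction
    # conv is layer nl//2 + 1, everything after runs at narrow_width.  The
    # mid-branch tap sits two convs after the reduction (layer 15 of 24).
    @property
    def n_wide(self) -> int:
        return max(1, self.nl // 2)

    @property
    def mid_tap(self) -> int:
        return min(self.n_wide + 3, self.nl)

    def encoder_channels(self, i: int) -> tuple[int, int]:
        """(in, out) channels of encoder conv ``i`` (1-based)."""
        cin = 3 if i == 1 else (self.nc if i <= self.n_wide + 1 else self.narrow_width)
        cout = self.nc if i <= self.n_wide else self.narrow_width
        return cin, cout


@dataclass
class DropLossConfig:
    """Configuration of the hard-negative random-drop loss.

    ``drop_function`` maps a background pixel's predicted foreground
    probability to its drop probability; the shipped default is the linear
    function 1 - p, under which a background pixel is *kept* with
    probability exactly equal to its activation.  ``kind='class_balanced'``
    keeps every background pixel (drop function identically zero).
    """

    kind: str = "random_drop"  # or "class_balanced"
    reduction: str = "sum"  # or "mean"
    heads: tuple[str, ...] = ("fused", "aux1", "aux2", "aux3")
    head_weights: dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("random_drop", "class_balanced"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.reduction not in ("sum", "mean"):
            raise ValueError(f"unknown reduction {self.reduction!r}")

    def weight(self, head: str) -> float:
        if self.head_weights is None:
            return 1.0
        return float(self.head_weights.get(head, 1.0))


@dataclass
class TrainConfig:
    """One training run: optimiser, iteration budget, loss, architecture."""

    iterations: int = 200
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    init: str = "xavier"
    batch_size: int = 1
    seed: int = 0
    checkpoint_every: int = 0  # 0 = only at the end
    augment: bool = True
    loss: DropLossConfig = field(default_factory=DropLossConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        if self.batch_size != 1:
            raise ValueError("batch size is fixed at 1")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.init.lower() != "xavier":
            raise ValueError(f"unsupported init scheme {self.init!r}")


def _as_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def save_config(cfg, path: str | Path) -> None:
    path = Path(path)
    data = _as_dict(cfg)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def _load_raw(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def load_network_config(path: str | Path) -> NetworkConfig:
    return network_config_from_dict(_load_raw(path))


def network_config_from_dict(d: dict) -> NetworkConfig:
    known = {f.name for f in dataclasses.fields(NetworkConfig)}
    return NetworkConfig(**{k: v for k, v in d.items() if k in known})


def load_train_config(path: str | Path) -> TrainConfig:
    d = _load_raw(path)
    loss = d.pop("loss", {}) or {}
    net = d.pop("network", {}) or {}
    if isinstance(loss.get("heads"), list):
        loss["heads"] = tuple(loss["heads"])
    known = {f.name for f in dataclasses.fields(TrainConfig)}
    return TrainConfig(
        loss=DropLossConfig(**loss),
        network=network_config_from_dict(net),
        **{k: v for k, v in d.items() if k in known and k not in ("loss", "network")},
    )
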