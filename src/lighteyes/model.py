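"""The segmentation network: a full-resolution convolutional encoder with a
three-branch, deeply supervised decoder.

The encoder stacks ``nl`` same-padded 3x3 convolutions (default 24) with no
downsampling, so feature maps keep the input resolution throughout; width is
capped at ``nc`` filters (default 16) and halved to ``narrow_width`` (default
8) midway to bound memory.  The decoder reads two encoder taps: a mid-depth
tap (receptive field 33x33) and the final tap (49x49), plus a pooled branch
that trades resolution for a 66x66 field, and fuses the three single-channel
maps with one last 3x3 convolution.  Each branch is a supervised head; the
``A1``/``A2``/``A3`` variants truncate the network to a single head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Concat, Conv2d, Pool2, ReLU, Upsample2, sigmoid
from .config import NetworkConfig

__all__ = [
    "LayerSpec",
    "ModelSummary",
    "ProbabilityMaps",
    "LightEyesModel",
    "build_model",
    "count_parameters",
    "receptive_field",
]


@dataclass
class LayerSpec:
    """One row of the architecture accounting."""

    name: str
    kind: str  # conv+relu | conv | pool | upsample | concat
    in_channels: int
    out_channels: int
    kernel: int
    stride: float
    n_params: int
    rf: int  # receptive-field side in input pixels
    half_res: bool = False

    @property
    def n_filters(self) -> int:
        return self.out_channels if self.kind.startswith("conv") else 0


@dataclass
class ModelSummary:
    rows: list[LayerSpec]
    total_params: int
    total_filters: int

    def to_text(self) -> str:
        lines = [
            f"{'layer':<14}{'kind':<12}{'output size':<18}"
            f"{'#filters':>9}{'#params':>9}{'RF':>5}"
        ]
        for r in self.rows:
            size = "H/2 x W/2" if r.half_res else "H x W"
            size += f" x {r.out_channels}" if r.out_channels > 1 else ""
            nf = str(r.n_filters) if r.n_filters else "-"
            lines.append(
                f"{r.name:<14}{r.kind:<12}{size:<18}{nf:>9}{r.n_params:>9}{r.rf:>5}"
            )
        lines.append(
            f"{'total':<14}{'':<12}{'':<18}{self.total_filters:>9}"
            f"{self.total_params:>9}{'':>5}"
        )
        lines.append("(per-layer op counts are not reported)")
        return "\n".join(lines)


@dataclass
class ProbabilityMaps:
    """Per-pixel foreground probabilities at full input resolution.

    ``fused`` is the network output (for the single-head variants it is that
    head's map); auxiliary maps are present only when the variant computes
    them.  Raw pre-sigmoid logits are retained per head for loss evaluation.
    """

    fused: np.ndarray
    aux1: np.ndarray | None = None
    aux2: np.ndarray | None = None
    aux3: np.ndarray | None = None
    logits: dict = field(default_factory=dict)


# -- graph construction -------------------------------------------------------


def _build_graph(cfg: NetworkConfig):
    """Return (nodes, heads, aliases). nodes = [(name, layer, [inputs])]."""
    nodes: list[tuple[str, object, list[str]]] = []

    def add(name, layer, *inputs):
        nodes.append((name, layer, list(inputs)))
        return name

    k = cfg.kernel_size
    n_enc = cfg.mid_tap if cfg.variant == "A1" else cfg.nl
    prev = "image"
    for i in range(1, n_enc + 1):
        cin, cout = cfg.encoder_channels(i)
        add(f"conv{i}", Conv2d(cin, cout, k), prev)
        prev = add(f"relu{i}", ReLU(), f"conv{i}")
    mid, last = f"relu{cfg.mid_tap}", f"relu{cfg.nl}"
    nw = cfg.narrow_width

    heads: dict[str, str] = {}
    if cfg.variant in ("full", "A1"):
        add("aux1_head", Conv2d(nw, 1, k), mid)
        heads["aux1"] = "aux1_head"
    if cfg.variant in ("full", "A2"):
        add("aux2_head", Conv2d(nw, 1, k), last)
        heads["aux2"] = "aux2_head"
    if cfg.variant in ("full", "A3"):
        prev = add("pool", Pool2(cfg.pooling), last)
        for j in range(1, 4):
            add(f"branch3_conv{j}", Conv2d(nw, nw, k), prev)
            prev = add(f"branch3_relu{j}", ReLU(), f"branch3_conv{j}")
        add("aux3_head", Conv2d(nw, 1, k), prev)
        add("aux3_up", Upsample2(cfg.upsample_mode), "aux3_head")
        heads["aux3"] = "aux3_up"
    if cfg.variant == "full":
        add("concat", Concat(), "aux1_head", "aux2_head", "aux3_up")
        add("fusion", Conv2d(3, 1, k), "concat")
        heads["fused"] = "fusion"

    # classic layer numbering (valid when it does not collide with encoder names)
    aliases: dict[str, str] = {}
    classic = {
        "conv25": "branch3_conv1",
        "conv26": "branch3_conv2",
        "conv27": "branch3_conv3",
        "conv28": "aux3_head",
        "conv29": "aux2_head",
        "conv30": "aux1_head",
        "conv31": "fusion",
    }
    existing = {n for n, _, _ in nodes}
    for alias, target in classic.items():
        if alias not in existing and target in existing:
            aliases[alias] = target
    for short, target in (
        ("aux1", "aux1_head"),
        ("aux2", "aux2_head"),
        ("aux3", "aux3_head"),
        ("fused", "fusion"),
        ("encoder", f"conv{cfg.nl}"),
    ):
        if target in existing:
            aliases[short] = target
    return nodes, heads, aliases


class LightEyesModel:
    """A built network: owns the layer graph, weights and gradients."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.nodes, self.heads, self.aliases = _build_graph(config)
        self._layers = {name: layer for name, layer, _ in self.nodes}
        self._rf, self._jump = self._trace_receptive_fields()
        self._cache: dict[str, np.ndarray] | None = None

    # -- weights --------------------------------------------------------------

    def init_weights(self, rng: np.random.Generator | int) -> None:
        """Xavier/Glorot-uniform weights, zero biases, in graph order."""
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        for name, layer, _ in self.nodes:
            if isinstance(layer, Conv2d):
                layer.init_weights(rng)

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer, _ in self.nodes:
            for pname, arr in layer.params().items():
                out[f"{name}.{pname}"] = arr
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer, _ in self.nodes:
            for pname, arr in layer.grads().items():
                out[f"{name}.{pname}"] = arr
        return out

    def zero_grads(self) -> None:
        for g in self.gradients().values():
            g[...] = 0.0

    def count_parameters(self) -> int:
        return sum(int(v.size) for v in self.parameters().values())

    # -- receptive fields -----------------------------------------------------

    def _trace_receptive_fields(self):
        """Standard recursion rf += (k-1)*jump; jump *= stride, per node."""
        rf = {"image": 1.0}
        jump = {"image": 1.0}
        for name, layer, inputs in self.nodes:
            if isinstance(layer, Conv2d):
                k, s = layer.kernel, 1.0
            elif isinstance(layer, Pool2):
                k, s = 2, 2.0
            elif isinstance(layer, Upsample2):
                k, s = (1, 0.5) if layer.mode == "nearest" else (2, 0.5)
            else:  # ReLU / Concat: pass-through
                k, s = 1, 1.0
            in_rf = max(rf[i] for i in inputs)
            in_jump = jump[inputs[0]]
            rf[name] = in_rf + (k - 1) * in_jump
            jump[name] = in_jump * s
        return rf, jump

    def receptive_field(self, tap: str) -> int:
        """Side length, in input pixels, of the square influencing one unit
        of layer ``tap`` (accepts canonical names, classic conv numbers and
        the aliases aux1/aux2/aux3/fused)."""
        name = self.aliases.get(tap, tap)
        if name not in self._rf:
            raise KeyError(f"unknown tap {tap!r}")
        return int(round(self._rf[name]))

    # -- forward / backward ---------------------------------------------------

    @staticmethod
    def _prepare(image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float64)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError(
                f"expected an H x W x 3 image, got shape {image.shape}"
            )
        h, w = image.shape[:2]
        if h % 2 or w % 2:
            raise ValueError(
                f"input size {h}x{w} has an odd dimension; pad the image to "
                "even height and width (the pooled decoder branch halves and "
                "restores the resolution) and crop the output back"
            )
        if image.max() > 1.5:  # 8-bit range; scale to [0, 1]
            image = image / 255.0
        return np.ascontiguousarray(image.transpose(2, 0, 1))

    def forward(
        self, image: np.ndarray, keep_cache: bool = False
    ) -> ProbabilityMaps:
        """Run the network on one ``H x W x 3`` image (values in [0,1] or
        [0,255]); returns full-resolution probability maps."""
        x = self._prepare(image)
        cache: dict[str, np.ndarray] = {"image": x}
        for name, layer, inputs in self.nodes:
            cache[name] = layer.forward(*(cache[i] for i in inputs))
        self._cache = cache if keep_cache else None

        logits = {h: cache[n][0] for h, n in self.heads.items()}
        probs = {h: sigmoid(z) for h, z in logits.items()}
        fused_head = "fused" if "fused" in probs else next(iter(probs))
        return ProbabilityMaps(
            fused=probs[fused_head],
            aux1=probs.get("aux1"),
            aux2=probs.get("aux2"),
            aux3=probs.get("aux3"),
            logits=logits,
        )

    def activation(self, tap: str) -> np.ndarray:
        """Cached raw output of a layer from the last ``forward(...,
        keep_cache=True)`` call (for inspection/oracles)."""
        if self._cache is None:
            raise RuntimeError("run forward(image, keep_cache=True) first")
        return self._cache[self.aliases.get(tap, tap)]

    def backward(self, head_grads: dict[str, np.ndarray]) -> None:
        """Accumulate parameter gradients given dLoss/dlogit per head.

        Requires the preceding ``forward`` to have been called with
        ``keep_cache=True``.
        """
        if self._cache is None:
            raise RuntimeError("run forward(image, keep_cache=True) first")
        grads: dict[str, np.ndarray] = {}
        for head, g in head_grads.items():
            node = self.heads[head]
            g = np.asarray(g, dtype=np.float64)[None]  # add channel axis
            grads[node] = grads.get(node, 0.0) + g
        for name, layer, inputs in reversed(self.nodes):
            if name not in grads:
                continue
            gin = layer.backward(grads.pop(name))
            if len(inputs) == 1:
                gin = [gin]
            for iname, g in zip(inputs, gin):
                if iname == "image":
                    continue
                if iname in grads:
                    grads[iname] = grads[iname] + g
                else:
                    grads[iname] = g
        self._cache = None

    # -- summary --------------------------------------------------------------

    def summary(self) -> ModelSummary:
        relu_after = {
            inputs[0]
            for _, layer, inputs in self.nodes
            if isinstance(layer, ReLU)
        }
        rows = []
        for name, layer, inputs in self.nodes:
            if isinstance(layer, ReLU):
                continue  # folded into the conv row
            if isinstance(layer, Conv2d):
                rows.append(
                    LayerSpec(
                        name=name,
                        kind="conv+relu" if name in relu_after else "conv",
                        in_channels=layer.in_channels,
                        out_channels=layer.out_channels,
                        kernel=layer.kernel,
                        stride=1,
                        n_params=(layer.kernel**2 * layer.in_channels + 1)
                        * layer.out_channels,
                        rf=self.receptive_field(name),
                        half_res=self._jump[name] > 1,
                    )
                )
            elif isinstance(layer, Pool2):
                rows.append(
                    LayerSpec(name, "pool", 0, 0, 2, 2, 0,
                              self.receptive_field(name), half_res=True)
                )
            elif isinstance(layer, Upsample2):
                rows.append(
                    LayerSpec(name, "upsample", 0, 1, 2, 0.5, 0,
                              self.receptive_field(name))
                )
            elif isinstance(layer, Concat):
                rows.append(
                    LayerSpec(name, "concat", 0, 3, 1, 1, 0,
                              self.receptive_field(name))
                )
        total_params = sum(r.n_params for r in rows)
        total_filters = sum(r.n_filters for r in rows)
        return ModelSummary(rows, total_params, total_filters)

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        import dataclasses as _dc
        import json as _json

        arrays = {k: v for k, v in self.parameters().items()}
        arrays["__config__"] = np.frombuffer(
            _json.dumps(_dc.asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "LightEyesModel":
        import json as _json

        from .config import network_config_from_dict

        with np.load(path) as data:
            cfg = network_config_from_dict(
                _json.loads(bytes(data["__config__"]).decode())
            )
            model = cls(cfg)
            params = model.parameters()
            for k, arr in params.items():
                if k not in data:
                    raise ValueError(f"weights file missing parameter {k}")
                if data[k].shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {k}: file {data[k].shape} vs "
                        f"model {arr.shape}"
                    )
                arr[...] = data[k]
        return model

    def make_optimizer(self, lr: float = 1e-3, **kw) -> Adam:
        return Adam(self.parameters(), lr=lr, **kw)


# -- module-level conveniences -------------------------------------------------


def build_model(
    config: NetworkConfig | None = None, seed: int | None = None
) -> tuple[LightEyesModel, ModelSummary]:
    """Build the network from a config; optionally initialise weights."""
    config = config or NetworkConfig()
    model = LightEyesModel(config)
    if seed is not None:
        model.init_weights(seed)
    return model, model.summary()


def count_parameters(model: LightEyesModel) -> int:
    return model.count_parameters()


def receptive_field(config: NetworkConfig | LightEyesModel, tap: str) -> int:
    """Receptive-field side (input pixels) of layer ``tap``."""
    model = config if isinstance(config, LightEyesModel) else LightEyesModel(config)
    return model.receptive_field(tap)
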