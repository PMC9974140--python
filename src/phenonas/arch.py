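"""Architecture specifications for the shared-trunk multi-task network.

An :class:`ArchitectureSpec` is a DAG of :class:`LayerSpec` nodes with
exactly one 5-way softmax classification head (genotype) and two single-unit
regression heads (leaf count, leaf area).  Shapes are derived layer by
layer, and trainable parameters are counted in closed form:

* conv:  ``k*k*c_in*c_out + c_out``
* dense / regression head:  ``d_in*d_out + d_out``
* everything else: 0

:func:`reference_architecture` builds the published optimal model: a
28x28x3 input, four valid 3x3/32 convolutions in series, a flatten →
dense(5) → softmax genotype branch, and two regression branches (one
through dropout) flattened straight off the fourth convolution.  Its total
is 118,247 trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "reference_architecture",
    "count_parameters",
    "LAYER_KINDS",
]

LAYER_KINDS = (
    "input",
    "cast",
    "conv",
    "flatten",
    "dropout",
    "dense",
    "softmax_head",
    "regression_head",
    "add",
    "concat",
)

_PARAMETRIC = {"conv", "dense", "regression_head"}


@dataclass(frozen=True)
class LayerSpec:
    """One node of the architecture DAG.

    ``params`` holds kind-specific settings: conv layers use ``kernel``,
    ``filters``, ``padding`` ("valid"/"same") and ``activation``
    ("relu"/"linear"); dense uses ``units`` and ``activation``; dropout uses
    ``rate``; input uses ``shape``.  Regression heads are single-unit dense
    layers and carry their own weights, mirroring how summary tables of the
    generating framework report them.
    """

    name: str
    kind: str
    inbound: tuple[str, ...] = ()
    params: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")

    @property
    def p(self) -> dict:
        return dict(self.params)

    @staticmethod
    def make(name: str, kind: str, inbound: tuple[str, ...] = (), **params) -> "LayerSpec":
        return LayerSpec(name=name, kind=kind, inbound=tuple(inbound), params=tuple(sorted(params.items())))


def _conv_defaults(p: dict) -> dict:
    return {"kernel": 3, "padding": "valid", "activation": "relu", **p}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Topologically ordered DAG of layers with three task heads."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = (28, 28, 3)
    provenance: tuple[tuple[str, object], ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def layer(self, name: str) -> LayerSpec:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)

    def consumers(self, name: str) -> list[LayerSpec]:
        return [layer for layer in self.layers if name in layer.inbound]

    def validate(self) -> None:
        names = [layer.name for layer in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        seen: set[str] = set()
        for layer in self.layers:
            for src in layer.inbound:
                if src not in seen:
                    raise ValueError(
                        f"layer {layer.name!r} references {src!r} before its definition "
                        "(layers must be in topological order)"
                    )
            seen.add(layer.name)
        kinds = [layer.kind for layer in self.layers]
        if kinds.count("input") != 1:
            raise ValueError("exactly one input layer required")
        if kinds.count("softmax_head") != 1 or kinds.count("regression_head") != 2:
            raise ValueError("need exactly one classification head and two regression heads")
        for layer in self.layers:
            if layer.kind == "conv":
                p = _conv_defaults(layer.p)
                if p["kernel"] < 1 or p["filters"] < 1:
                    raise ValueError(f"{layer.name}: conv kernel and filters must be >= 1")
            if layer.kind == "dense" and layer.p.get("units", 0) < 1:
                raise ValueError(f"{layer.name}: dense units must be >= 1")
        # heads must be reachable from the input
        reach = {names[kinds.index("input")]}
        for layer in self.layers:
            if layer.inbound and all(src in reach for src in layer.inbound):
                reach.add(layer.name)
        for layer in self.layers:
            if layer.kind.endswith("_head") and layer.name not in reach:
                raise ValueError(f"head {layer.name!r} not reachable from input")
        self.output_shapes()  # raises on inconsistent wiring

    # -- shapes ------------------------------------------------------------

    def output_shapes(self) -> dict[str, tuple[int, ...]]:
        """Derive every layer's output shape (without the batch axis)."""
        shapes: dict[str, tuple[int, ...]] = {}
        for layer in self.layers:
            ins = [shapes[s] for s in layer.inbound]
            p = layer.p
            if layer.kind == "input":
                shape: tuple[int, ...] = tuple(p.get("shape", self.input_shape))
            elif layer.kind in ("cast", "dropout"):
                (shape,) = ins
            elif layer.kind == "conv":
                (src,) = ins
                if len(src) != 3:
                    raise ValueError(f"{layer.name}: conv input must be 3-D, got {src}")
                cp = _conv_defaults(p)
                k, f = cp["kernel"], cp["filters"]
                h, w, _ = src
                if cp["padding"] == "same":
                    shape = (h, w, f)
                else:
                    if h < k or w < k:
                        raise ValueError(f"{layer.name}: input {src} smaller than kernel {k}")
                    shape = (h - k + 1, w - k + 1, f)
            elif layer.kind == "flatten":
                (src,) = ins
                n = 1
                for d in src:
                    n *= d
                shape = (n,)
            elif layer.kind in ("dense", "regression_head"):
                (src,) = ins
                if len(src) != 1:
                    raise ValueError(f"{layer.name}: dense input must be flat, got {src}")
                shape = (p.get("units", 1),)
            elif layer.kind == "softmax_head":
                (src,) = ins
                shape = src
            elif layer.kind == "add":
                a, b = ins
                if a != b:
                    raise ValueError(f"{layer.name}: add requires equal shapes, got {a} vs {b}")
                shape = a
            elif layer.kind == "concat":
                a, b = ins
                if a[:-1] != b[:-1]:
                    raise ValueError(f"{layer.name}: concat requires equal spatial dims, got {a} vs {b}")
                shape = (*a[:-1], a[-1] + b[-1])
            else:  # pragma: no cover
                raise AssertionError(layer.kind)
            shapes[layer.name] = shape
        return shapes

    def heads(self) -> tuple[str, str, str]:
        """Names of (classification, count-regression, area-regression) heads,
        in layer order for the regression pair."""
        cls = [l.name for l in self.layers if l.kind == "softmax_head"]
        reg = [l.name for l in self.layers if l.kind == "regression_head"]
        return cls[0], reg[0], reg[1]

    # -- identity & serialization -----------------------------------------

    def structural_key(self) -> str:
        """Canonical string identifying the structure (names excluded from
        parameter comparison only via this key's construction order)."""
        parts = []
        for layer in self.layers:
            parts.append((layer.name, layer.kind, layer.inbound, layer.params))
        return json.dumps(parts, sort_keys=False, default=str)

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "layers": [
                {"name": l.name, "kind": l.kind, "inbound": list(l.inbound), "params": dict(l.params)}
                for l in self.layers
            ],
        }

    @staticmethod
    def from_dict(doc: dict) -> "ArchitectureSpec":
        layers = tuple(
            LayerSpec.make(
                l["name"], l["kind"], tuple(l["inbound"]),
                **{k: tuple(v) if isinstance(v, list) else v for k, v in l["params"].items()},
            )
            for l in doc["layers"]
        )
        return ArchitectureSpec(layers=layers, input_shape=tuple(doc["input_shape"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @staticmethod
    def load(path: str | Path) -> "ArchitectureSpec":
        return ArchitectureSpec.from_dict(json.loads(Path(path).read_text()))


def count_parameters(arch: ArchitectureSpec) -> tuple[dict[str, int], int]:
    """Closed-form per-layer trainable-parameter counts and their total."""
    shapes = arch.output_shapes()
    counts: dict[str, int] = {}
    for layer in arch.layers:
        if layer.kind == "conv":
            p = _conv_defaults(layer.p)
            (src,) = [shapes[s] for s in layer.inbound]
            counts[layer.name] = p["kernel"] * p["kernel"] * src[-1] * p["filters"] + p["filters"]
        elif layer.kind in ("dense", "regression_head"):
            (src,) = [shapes[s] for s in layer.inbound]
            units = layer.p.get("units", 1)
            counts[layer.name] = src[0] * units + units
        else:
            counts[layer.name] = 0
    return counts, sum(counts.values())


def reference_architecture() -> ArchitectureSpec:
    """The published optimal multi-task model, layer for layer.

    Four 3x3/32 valid convolutions share a trunk; the genotype branch is
    flatten → dense(5) → softmax, the leaf-count branch is dropout →
    flatten → 1-unit regression head, and the leaf-area branch flattens the
    fourth convolution directly into its own 1-unit regression head.
    """
    L = LayerSpec.make
    layers = (
        L("input_1", "input", shape=(28, 28, 3)),
        L("cast_to_float32", "cast", ("input_1",)),
        L("conv2d", "conv", ("cast_to_float32",), kernel=3, filters=32, padding="valid", activation="relu"),
        L("conv2d_1", "conv", ("conv2d",), kernel=3, filters=32, padding="valid", activation="relu"),
        L("conv2d_2", "conv", ("conv2d_1",), kernel=3, filters=32, padding="valid", activation="relu"),
        L("conv2d_3", "conv", ("conv2d_2",), kernel=3, filters=32, padding="valid", activation="relu"),
        L("flatten", "flatten", ("conv2d_3",)),
        L("dropout", "dropout", ("conv2d_3",), rate=0.25),
        L("dense", "dense", ("flatten",), units=5, activation="linear"),
        L("flatten_1", "flatten", ("dropout",)),
        L("flatten_2", "flatten", ("conv2d_3",)),
        L("classification_head_1", "softmax_head", ("dense",)),
        L("regression_head_1", "regression_head", ("flatten_1",), units=1),
        L("regression_head_2", "regression_head", ("flatten_2",), units=1),
    )
    return ArchitectureSpec(layers=layers, input_shape=(28, 28, 3))
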