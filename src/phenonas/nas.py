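"""Miniature neural-architecture-search engine.

The search follows the morphism-based Bayesian-optimization recipe: seed
architectures (plain CNN, residual, densely connected) are trained with
early stopping; a Gaussian-process surrogate over an architecture edit
distance predicts the validation objective of unseen candidates; new
candidates are generated by *function-preserving* network morphisms
(deepen, widen, add skip connection) from parents passed through a
simulated-annealing gate; a lower-confidence-bound acquisition picks the
next architecture to train; after ``max_trials`` trials the best
architecture is retrained from scratch in full.

Objective convention: every trial is scored by its best validation total
loss (lower is better); the maximized performance f(a) of the usual NAS
formulation is the negative of this objective.

Morphism weight transfer makes each child compute the same function as its
trained parent before retraining: deepening inserts an identity-initialized
convolution, widening copies existing filters into the new channels and
zero-initializes all consumer cross-terms, and a new skip connection is
merged through a zero-initialized 1x1 projection.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .arch import ArchitectureSpec, LayerSpec, count_parameters, _conv_defaults
from .model import Network, TrainConfig, build, train

__all__ = [
    "SearchSpace",
    "MorphismAction",
    "TrialRecord",
    "SurrogateState",
    "SearchConfig",
    "initialize_seeds",
    "morph_architecture",
    "apply_morphism",
    "architecture_distance",
    "surrogate_update",
    "surrogate_predict",
    "acquisition",
    "anneal_accept",
    "propose",
    "early_stop",
    "search",
    "trial_log_to_csv",
]

FAMILIES = ("plain-cnn", "residual", "dense-connected")
PASSTHROUGH = {"cast", "dropout", "flatten"}


@dataclass(frozen=True)
class SearchSpace:
    families: tuple[str, ...] = FAMILIES
    min_depth: int = 2  # convolution count bounds for the trunk
    max_depth: int = 8
    width_menu: tuple[int, ...] = (16, 32, 64)
    morphisms: tuple[str, ...] = ("deepen", "widen", "add_skip")
    input_shape: tuple[int, int, int] = (28, 28, 3)
    n_classes: int = 5

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("at least one seed family must be enabled")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {unknown}")
        if not (1 <= self.min_depth <= self.max_depth):
            raise ValueError("inconsistent depth bounds")


@dataclass(frozen=True)
class MorphismAction:
    kind: str  # deepen | widen | add_skip
    target: str  # layer to deepen/widen, or skip source
    magnitude: int = 0  # new width for widen; unused otherwise
    dest: str = ""  # skip destination for add_skip


@dataclass
class TrialRecord:
    trial_id: int
    arch: ArchitectureSpec
    objective: float  # best validation total loss (lower is better)
    epochs_run: int
    stopped_early: bool
    parent_id: int | None = None
    n_parameters: int = 0
    is_retrain: bool = False


@dataclass
class SearchConfig:
    max_trials: int = 10
    epochs_per_trial: int = 50
    retrain_epochs: int = 300
    patience: int = 5
    beta: float = 2.5  # acquisition exploration weight, decays by gamma per trial
    t0: float = 1.0  # initial annealing temperature
    gamma: float = 0.9  # per-trial decay of both temperature and beta
    batch_size: int = 32
    learning_rate: float = 1e-3
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    weight_decay: float = 0.0
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")
        if self.t0 <= 0 or not (0 < self.gamma < 1):
            raise ValueError("need T0 > 0 and 0 < gamma < 1")


# ---------------------------------------------------------------------------
# seed architectures
# ---------------------------------------------------------------------------

def _head_block(trunk: str) -> tuple[LayerSpec, ...]:
    L = LayerSpec.make
    return (
        L("flatten", "flatten", (trunk,)),
        L("dropout", "dropout", (trunk,), rate=0.25),
        L("dense", "dense", ("flatten",), units=5, activation="linear"),
        L("flatten_1", "flatten", ("dropout",)),
        L("flatten_2", "flatten", (trunk,)),
        L("classification_head_1", "softmax_head", ("dense",)),
        L("regression_head_1", "regression_head", ("flatten_1",), units=1),
        L("regression_head_2", "regression_head", ("flatten_2",), units=1),
    )


def _seed_architecture(family: str, space: SearchSpace) -> ArchitectureSpec:
    L = LayerSpec.make
    width = space.width_menu[min(1, len(space.width_menu) - 1)]
    base = [
        L("input_1", "input", shape=space.input_shape),
        L("cast_to_float32", "cast", ("input_1",)),
    ]
    if family == "plain-cnn":
        base += [
            L("conv2d", "conv", ("cast_to_float32",), kernel=3, filters=width, padding="valid", activation="relu"),
            L("conv2d_1", "conv", ("conv2d",), kernel=3, filters=width, padding="valid", activation="relu"),
        ]
        trunk = "conv2d_1"
    elif family == "residual":
        base += [
            L("conv2d", "conv", ("cast_to_float32",), kernel=3, filters=width, padding="same", activation="relu"),
            L("conv2d_1", "conv", ("conv2d",), kernel=3, filters=width, padding="same", activation="relu"),
            L("add", "add", ("conv2d", "conv2d_1")),
            L("conv2d_2", "conv", ("add",), kernel=3, filters=width, padding="same", activation="relu"),
            L("add_1", "add", ("add", "conv2d_2")),
        ]
        trunk = "add_1"
    elif family == "dense-connected":
        w = space.width_menu[0]
        base += [
            L("conv2d", "conv", ("cast_to_float32",), kernel=3, filters=w, padding="same", activation="relu"),
            L("conv2d_1", "conv", ("conv2d",), kernel=3, filters=w, padding="same", activation="relu"),
            L("concat", "concat", ("conv2d", "conv2d_1")),
            L("conv2d_2", "conv", ("concat",), kernel=3, filters=w, padding="same", activation="relu"),
            L("concat_1", "concat", ("concat", "conv2d_2")),
        ]
        trunk = "concat_1"
    else:
        raise ValueError(f"unknown family {family!r}")
    return ArchitectureSpec(layers=tuple(base) + _head_block(trunk), input_shape=space.input_shape)


def initialize_seeds(space: SearchSpace, n_seeds: int, seed: int) -> list[ArchitectureSpec]:
    """Build the initial architectures, cycling through the enabled families."""
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if n_seeds > len(space.families):
        raise ValueError(
            f"only {len(space.families)} distinct seed architectures are constructible, asked for {n_seeds}"
        )
    rng = np.random.default_rng(seed)  # reserved for future stochastic seeds
    del rng
    return [_seed_architecture(space.families[i % len(space.families)], space) for i in range(n_seeds)]


# ---------------------------------------------------------------------------
# morphisms
# ---------------------------------------------------------------------------

def _fresh_name(arch: ArchitectureSpec, base: str) -> str:
    existing = {l.name for l in arch.layers}
    if base not in existing:
        return base
    i = 1
    while f"{base}_{i}" in existing:
        i += 1
    return f"{base}_{i}"


def _parametric_consumers(arch: ArchitectureSpec, name: str) -> list[str]:
    """Transitive consumers of ``name`` up to the first parameter-carrying
    layer on each path; raises if a path hits a merge layer."""
    out: list[str] = []
    stack = [c.name for c in arch.consumers(name)]
    while stack:
        cur = stack.pop()
        layer = arch.layer(cur)
        if layer.kind in ("conv", "dense", "regression_head"):
            out.append(cur)
        elif layer.kind in PASSTHROUGH:
            stack.extend(c.name for c in arch.consumers(cur))
        else:
            raise ValueError(f"widening blocked: channel change reaches {layer.kind} layer {cur!r}")
    return out


def morph_architecture(arch: ArchitectureSpec, action: MorphismAction) -> ArchitectureSpec:
    """Pure structural edit; see :func:`apply_morphism` for weight transfer."""
    layers = list(arch.layers)
    if action.kind == "deepen":
        target = arch.layer(action.target)
        if target.kind != "conv":
            raise ValueError("deepen targets a convolution layer")
        width = _conv_defaults(target.p)["filters"]
        new_name = _fresh_name(arch, "conv2d_m")
        new = LayerSpec.make(new_name, "conv", (target.name,), kernel=3, filters=width,
                             padding="same", activation="relu")
        rewired = []
        for layer in layers:
            if layer.name != target.name and target.name in layer.inbound:
                layer = LayerSpec(layer.name, layer.kind,
                                  tuple(new_name if s == target.name else s for s in layer.inbound),
                                  layer.params)
            rewired.append(layer)
        idx = [l.name for l in rewired].index(target.name)
        rewired.insert(idx + 1, new)
        return ArchitectureSpec(tuple(rewired), arch.input_shape)

    if action.kind == "widen":
        target = arch.layer(action.target)
        if target.kind != "conv":
            raise ValueError("widen targets a convolution layer")
        old = _conv_defaults(target.p)["filters"]
        if action.magnitude <= old:
            raise ValueError(f"widened width must exceed current {old}, got {action.magnitude}")
        _parametric_consumers(arch, target.name)  # raises if blocked by add/concat
        widened = LayerSpec.make(target.name, "conv", target.inbound,
                                 **{**_conv_defaults(target.p), "filters": action.magnitude})
        return ArchitectureSpec(
            tuple(widened if l.name == target.name else l for l in layers), arch.input_shape
        )

    if action.kind == "add_skip":
        shapes = arch.output_shapes()
        src, dst = action.target, action.dest
        names = [l.name for l in layers]
        if names.index(src) >= names.index(dst):
            raise ValueError("skip source must precede its destination")
        s_shape, d_shape = shapes[src], shapes[dst]
        if len(s_shape) != 3 or len(d_shape) != 3 or s_shape[:2] != d_shape[:2]:
            raise ValueError(f"skip endpoints spatially incompatible: {s_shape} vs {d_shape}")
        proj_name = _fresh_name(arch, "skip_proj")
        add_name = _fresh_name(arch, "skip_add")
        proj = LayerSpec.make(proj_name, "conv", (src,), kernel=1, filters=d_shape[2],
                              padding="same", activation="linear")
        merge = LayerSpec.make(add_name, "add", (dst, proj_name))
        rewired = []
        for layer in layers:
            if layer.name != dst and dst in layer.inbound and layer.name != add_name:
                layer = LayerSpec(layer.name, layer.kind,
                                  tuple(add_name if s == dst else s for s in layer.inbound),
                                  layer.params)
            rewired.append(layer)
        idx = [l.name for l in rewired].index(dst)
        rewired[idx + 1 : idx + 1] = [proj, merge]
        return ArchitectureSpec(tuple(rewired), arch.input_shape)

    raise ValueError(f"unknown morphism kind {action.kind!r}")


def apply_morphism(model: Network, action: MorphismAction) -> Network:
    """Structural edit plus function-preserving weight transfer.

    The returned network computes the same function as ``model`` (up to
    float32 rounding) on every input, before any retraining.
    """
    parent = model.arch
    child_arch = morph_architecture(parent, action)
    child = Network.__new__(Network)
    child.arch = child_arch
    child.shapes = child_arch.output_shapes()
    child.params = {k: {n: a.copy() for n, a in d.items()} for k, d in model.params.items()}

    if action.kind == "deepen":
        new_name = next(l.name for l in child_arch.layers if l.name not in {p.name for p in parent.layers})
        width = _conv_defaults(parent.layer(action.target).p)["filters"]
        W = np.zeros((3, 3, width, width), dtype=np.float32)
        for c in range(width):
            W[1, 1, c, c] = 1.0
        child.params[new_name] = {"W": W, "b": np.zeros(width, dtype=np.float32)}

    elif action.kind == "widen":
        old = _conv_defaults(parent.layer(action.target).p)["filters"]
        new = action.magnitude
        tp = child.params[action.target]
        copy_idx = np.arange(new - old) % old  # duplicate existing filters cyclically
        tp["W"] = np.concatenate([tp["W"], tp["W"][..., copy_idx]], axis=-1)
        tp["b"] = np.concatenate([tp["b"], tp["b"][copy_idx]])
        parent_shapes = parent.output_shapes()
        for cons in _parametric_consumers(parent, action.target):
            layer = parent.layer(cons)
            cp = child.params[cons]
            if layer.kind == "conv":
                k = cp["W"].shape[0]
                zeros = np.zeros((k, k, new - old, cp["W"].shape[3]), dtype=np.float32)
                cp["W"] = np.concatenate([cp["W"], zeros], axis=2)
            else:  # dense / regression_head fed through a flatten
                h, w, _ = parent_shapes[action.target]
                dout = cp["W"].shape[1]
                W3 = cp["W"].reshape(h * w, old, dout)
                pad = np.zeros((h * w, new - old, dout), dtype=np.float32)
                cp["W"] = np.concatenate([W3, pad], axis=1).reshape(h * w * new, dout)

    elif action.kind == "add_skip":
        proj_name = next(
            l.name for l in child_arch.layers
            if l.kind == "conv" and l.name not in {p.name for p in parent.layers}
        )
        (src_shape,) = [child.shapes[s] for s in child_arch.layer(proj_name).inbound]
        c_out = child_arch.layer(proj_name).p["filters"]
        child.params[proj_name] = {
            "W": np.zeros((1, 1, src_shape[2], c_out), dtype=np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
    return child


def _legal_actions(arch: ArchitectureSpec, space: SearchSpace) -> list[MorphismAction]:
    actions: list[MorphismAction] = []
    convs = [l for l in arch.layers if l.kind == "conv"]
    shapes = arch.output_shapes()
    if "deepen" in space.morphisms and len(convs) < space.max_depth:
        actions += [MorphismAction("deepen", l.name) for l in convs]
    if "widen" in space.morphisms:
        for l in convs:
            cur = _conv_defaults(l.p)["filters"]
            for width in space.width_menu:
                if width > cur:
                    try:
                        _parametric_consumers(arch, l.name)
                    except ValueError:
                        break
                    actions.append(MorphismAction("widen", l.name, magnitude=width))
    if "add_skip" in space.morphisms:
        names = [l.name for l in arch.layers]
        candidates = [l.name for l in arch.layers if l.kind in ("conv", "add", "concat")]
        for i, src in enumerate(candidates):
            for dst in candidates[i + 1 :]:
                if names.index(src) < names.index(dst) and shapes[src][:2] == shapes[dst][:2]:
                    actions.append(MorphismAction("add_skip", src, dest=dst))
    return actions


# ---------------------------------------------------------------------------
# surrogate
# ---------------------------------------------------------------------------

def _layer_signature(arch: ArchitectureSpec) -> list[tuple[str, int | None]]:
    sig = []
    for layer in arch.layers:
        if layer.kind == "conv":
            sig.append(("conv", _conv_defaults(layer.p)["filters"]))
        elif layer.kind in ("dense", "regression_head"):
            sig.append((layer.kind, layer.p.get("units", 1)))
        else:
            sig.append((layer.kind, None))
    return sig


def architecture_distance(a: ArchitectureSpec, b: ArchitectureSpec) -> float:
    """Edit distance over the layer sequences: insertions and deletions cost
    1, matching same-kind layers cost the normalized width difference
    ``|w_a - w_b| / max(w_a, w_b)``, and kind substitutions cost 1.
    Symmetric with ``d(a, a) = 0``."""
    sa, sb = _layer_signature(a), _layer_signature(b)
    n, m = len(sa), len(sb)
    D = np.zeros((n + 1, m + 1))
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            (ka, wa), (kb, wb) = sa[i - 1], sb[j - 1]
            if ka == kb:
                sub = 0.0 if wa == wb else abs((wa or 0) - (wb or 0)) / max(wa or 1, wb or 1)
            else:
                sub = 1.0
            D[i, j] = min(D[i - 1, j] + 1, D[i, j - 1] + 1, D[i - 1, j - 1] + sub)
    return float(D[n, m])


@dataclass
class SurrogateState:
    """Gaussian-process posterior over architectures.

    Kernel: ``kappa(a, b) = exp(-rho * d(a, b)^2) + noise * 1[a == b]``
    with ``d`` the architecture edit distance and structural identity for
    the indicator.  The prior mean is the mean of the observations and the
    prior variance the kernel amplitude (1 + noise).
    """

    rho: float = 0.5
    noise: float = 1e-4
    archs: list[ArchitectureSpec] = field(default_factory=list)
    objectives: list[float] = field(default_factory=list)
    _dist: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.noise <= 0:
            raise ValueError("rho and noise must be positive")


def surrogate_update(state: SurrogateState, arch: ArchitectureSpec, objective: float) -> SurrogateState:
    """Add (or refresh) one observation; keeps one entry per distinct
    architecture and the pairwise-distance cache."""
    if not np.isfinite(objective):
        raise ValueError("objective must be finite")
    key = arch.structural_key()
    for i, known in enumerate(state.archs):
        if known.structural_key() == key:
            state.objectives[i] = float(objective)
            return state
    new_d = np.array([architecture_distance(arch, other) for other in state.archs])
    n = len(state.archs)
    dist = np.zeros((n + 1, n + 1))
    dist[:n, :n] = state._dist
    dist[n, :n] = new_d
    dist[:n, n] = new_d
    state._dist = dist
    state.archs.append(arch)
    state.objectives.append(float(objective))
    return state


def _solve_spd(K: np.ndarray, y: np.ndarray):
    jitter = 0.0
    for _ in range(6):
        try:
            factor = cho_factor(K + jitter * np.eye(len(K)), lower=True)
            return factor
        except np.linalg.LinAlgError:
            jitter = 1e-10 if jitter == 0 else jitter * 100
    raise np.linalg.LinAlgError("kernel matrix not positive definite even with jitter")


def surrogate_predict(state: SurrogateState, arch: ArchitectureSpec) -> tuple[float, float]:
    """Posterior mean and variance of the objective at ``arch``."""
    amplitude = 1.0 + state.noise
    if not state.archs:
        return 0.0, amplitude
    y = np.asarray(state.objectives)
    m = float(y.mean())
    K = np.exp(-state.rho * state._dist**2) + state.noise * np.eye(len(y))
    key = arch.structural_key()
    d_star = np.array([architecture_distance(arch, other) for other in state.archs])
    k_star = np.exp(-state.rho * d_star**2)
    for i, known in enumerate(state.archs):
        if known.structural_key() == key:
            k_star[i] += state.noise
    factor = _solve_spd(K, y)
    alpha = cho_solve(factor, y - m)
    mean = m + float(k_star @ alpha)
    var = amplitude - float(k_star @ cho_solve(factor, k_star))
    return mean, max(var, 0.0)


def acquisition(mean: float, variance: float, beta: float) -> float:
    """Lower confidence bound (objective is minimized); smaller is better."""
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    return mean - beta * math.sqrt(variance)


def anneal_accept(
    candidate_score: float,
    incumbent_score: float,
    temperature: float,
    rng: np.random.Generator,
) -> bool:
    """Metropolis rule: always accept improvements, otherwise accept with
    probability ``exp(-(candidate - incumbent) / temperature)``."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    delta = candidate_score - incumbent_score
    if delta <= 0:
        return True
    return bool(rng.random() < math.exp(-delta / temperature))


def early_stop(history: list[float], patience: int) -> bool:
    """True iff the objective has not improved for the last ``patience``
    consecutive entries."""
    if patience < 1:
        raise ValueError("patience must be >= 1")
    best = math.inf
    last_improve = -1
    for i, value in enumerate(history):
        if value < best:
            best = value
            last_improve = i
    return len(history) - 1 - last_improve >= patience


# ---------------------------------------------------------------------------
# proposal and search loop
# ---------------------------------------------------------------------------

def propose(
    surrogate: SurrogateState,
    history: list[TrialRecord],
    space: SearchSpace,
    rng: np.random.Generator,
    *,
    beta: float = 2.5,
    temperature: float = 1.0,
    max_retries: int = 64,
) -> ArchitectureSpec:
    """Generate the next architecture to train.

    Random morphisms are drawn from annealing-accepted parents; candidates
    are scored by the acquisition on the surrogate posterior; the
    best-scoring candidate that is structurally distinct from every prior
    trial wins.  The returned spec carries ``provenance`` naming its parent
    trial and morphism so trained weights can be transferred.
    """
    completed = [t for t in history if not t.is_retrain]
    if not completed:
        raise ValueError("propose requires at least one completed trial")
    incumbent = min(t.objective for t in completed)
    seen = {t.arch.structural_key() for t in completed}

    best_arch: ArchitectureSpec | None = None
    best_score = math.inf
    found = 0
    for _ in range(max_retries):
        parent = completed[int(rng.integers(len(completed)))]
        if not anneal_accept(parent.objective, incumbent, temperature, rng):
            continue
        actions = _legal_actions(parent.arch, space)
        if not actions:
            continue
        action = actions[int(rng.integers(len(actions)))]
        try:
            child = morph_architecture(parent.arch, action)
        except ValueError:
            continue
        if child.structural_key() in seen:
            continue
        mean, var = surrogate_predict(surrogate, child)
        score = acquisition(mean, var, beta)
        found += 1
        if score < best_score:
            best_score = score
            best_arch = replace(
                child,
                provenance=(("parent", parent.trial_id), ("action", action)),
            )
    if best_arch is None:
        raise RuntimeError(f"no novel architecture found within {max_retries} retries")
    return best_arch


def search(
    space: SearchSpace,
    arrays: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    config: SearchConfig,
) -> tuple[ArchitectureSpec, Network, list[TrialRecord]]:
    """Run the full loop: seeds → trial training with early stopping →
    surrogate update → morphism proposals → final full retrain.

    Returns ``(best architecture, fully retrained network, trial log)``;
    the log holds ``max_trials`` search records plus one retrain record.
    Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    trial_seeds = ss.generate_state(config.max_trials + 1) % (2**31)
    rng = np.random.default_rng(ss.spawn(1)[0])

    def trial_config(epochs: int, seed: int) -> TrainConfig:
        return TrainConfig(
            epochs=epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            loss_weights=config.loss_weights,
            weight_decay=config.weight_decay,
            validation_fraction=config.validation_fraction,
            seed=seed,
        )

    def run_trial(trial_id: int, net: Network, parent_id: int | None) -> TrialRecord:
        net, hist = train(net, arrays, trial_config(config.epochs_per_trial, int(trial_seeds[trial_id])),
                          patience=config.patience)
        objective = min(h["val_loss"] for h in hist)
        if not np.isfinite(objective):
            raise RuntimeError(f"trial {trial_id} diverged; history: {hist[-3:]}")
        record = TrialRecord(
            trial_id=trial_id,
            arch=net.arch,
            objective=float(objective),
            epochs_run=len(hist),
            stopped_early=len(hist) < config.epochs_per_trial,
            parent_id=parent_id,
            n_parameters=net.n_parameters(),
        )
        models[trial_id] = net
        return record

    models: dict[int, Network] = {}
    records: list[TrialRecord] = []
    surrogate = SurrogateState()

    n_seeds = min(len(space.families), config.max_trials)
    for i, seed_arch in enumerate(initialize_seeds(space, n_seeds, config.seed)):
        record = run_trial(i, build(seed_arch, seed=int(trial_seeds[i])), parent_id=None)
        records.append(record)
        surrogate = surrogate_update(surrogate, record.arch, record.objective)

    while len(records) < config.max_trials:
        t = len(records)
        beta_t = config.beta * config.gamma**t
        temp_t = config.t0 * config.gamma**t
        proposal = propose(surrogate, records, space, rng, beta=beta_t, temperature=temp_t)
        prov = dict(proposal.provenance)
        child = apply_morphism(models[prov["parent"]], prov["action"])
        record = run_trial(t, child, parent_id=prov["parent"])
        records.append(record)
        surrogate = surrogate_update(surrogate, record.arch, record.objective)

    best = min(records, key=lambda r: r.objective)
    final = build(best.arch, seed=int(trial_seeds[config.max_trials]))
    final, hist = train(final, arrays, trial_config(config.retrain_epochs, int(trial_seeds[config.max_trials])))
    records.append(
        TrialRecord(
            trial_id=len(records),
            arch=best.arch,
            objective=float(min(h["val_loss"] for h in hist)),
            epochs_run=len(hist),
            stopped_early=False,
            parent_id=best.trial_id,
            n_parameters=final.n_parameters(),
            is_retrain=True,
        )
    )
    return best.arch, final, records


def trial_log_to_csv(records: list[TrialRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["trial_id", "parent_id", "objective", "epochs_run", "stopped_early", "n_parameters", "is_retrain"]
        )
        for r in records:
            writer.writerow(
                [r.trial_id, "" if r.parent_id is None else r.parent_id,
                 f"{r.objective:.6f}", r.epochs_run, r.stopped_early, r.n_parameters, r.is_retrain]
            )
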