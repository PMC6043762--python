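"""Model assembly, training, cross-validation, transfer retraining and
gradient saliency for the spherical-mesh CNN.

The default architecture mirrors the reference design for cortical
thickness classification: five convolution complexes (mesh convolution ->
batch normalization -> ReLU -> mesh mean pooling), each pooling one
icosphere level down, followed by a fully connected hidden layer of 50
units and a 2-class softmax. On the 40,962-node input mesh (level 6; two
hemisphere channels, 5x5 patches = 25 filter points) the pre-classifier
feature map is 42 nodes x 36 features.

Training follows the published schedule: semi-batch SGD (batch 50) at
learning rate 0.02, dropped to 0.001 for fine tuning once the training
error curve saturates; runs extend from 40 to at most 70 epochs if
unsaturated; early stopping returns the epoch with the lowest validation
error. Cross-validation is stratified 10-fold with a shared held-out test
set. Transfer retraining freezes the convolution complexes (20 layers for
the 5-complex model) and retrains only the classifier head, without fine
tuning of the reused layers.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .icosphere import IcosphereMesh, icosphere, pooling_map
from .layers import (
    BatchNormLayer,
    DenseLayer,
    FlattenLayer,
    MeshConvLayer,
    MeshPoolLayer,
    ReLULayer,
    SGD,
    Sequential,
    SoftmaxCrossEntropy,
)
from .patch_sampling import (
    SamplingMap,
    build_sampling_map,
    circular_template,
    rectangular_template,
)

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "FoldResult",
    "Model",
    "TrainingError",
    "build_model",
    "train",
    "cross_validate",
    "transfer_retrain",
    "evaluate",
    "saliency",
    "group_saliency",
    "load_model",
]

LAYERS_PER_COMPLEX = 4  # conv, batch norm, ReLU, pool


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    ``patch`` is ("rect", Sx, Sy) or ("circ", n_rings, points_per_ring);
    ``spacing`` of None uses each level's mean 1-ring edge length.
    """

    input_level: int = 6  # 40,962-node icosphere
    input_channels: int = 2
    n_complexes: int = 5
    filters_per_layer: tuple = (36, 36, 36, 36, 36)
    patch: tuple = ("rect", 5, 5)
    spacing: float | None = None
    hidden_units: int = 50
    n_classes: int = 2
    pool_mode: str = "mean"
    pool_include_self: bool = True
    conv_bias: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_complexes > self.input_level:
            raise ValueError(
                f"{self.n_complexes} complexes cannot pool below level 0 "
                f"from level {self.input_level}"
            )
        if len(self.filters_per_layer) != self.n_complexes:
            raise ValueError("need one filter count per complex")

    @property
    def output_level(self) -> int:
        return self.input_level - self.n_complexes


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule (defaults follow the published protocol)."""

    batch_size: int = 50
    lr_initial: float = 0.02
    lr_fine: float = 0.001
    max_epochs: int = 40
    extended_epochs: int = 70
    folds: int = 10
    seed: int = 0
    early_stopping: bool = True
    momentum: float = 0.9
    weight_decay: float = 0.0
    saturation_window: int = 5
    saturation_tol: float = 0.1  # percentage points
    stop_patience: int | None = None  # optional early abort on stalled validation

    def __post_init__(self):
        if not 0 < self.lr_fine < self.lr_initial:
            raise ValueError("need 0 < lr_fine < lr_initial")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class FoldResult:
    """Outcome of training one model (one fold)."""

    fold: int
    best_epoch: int
    val_accuracy: float
    test_accuracy: float | None
    train_err: list[float] = field(default_factory=list)
    val_err: list[float] = field(default_factory=list)


class _NetRunner:
    """Forward/predict/checkpoint plumbing shared by full models and the
    detached classifier head used during transfer retraining."""

    def __init__(self, net: Sequential):
        self.net = net
        self.loss = SoftmaxCrossEntropy()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).argmax(axis=1)

    def state(self) -> dict:
        st = {}
        for i, layer in enumerate(self.net.layers):
            for k, v in layer.params.items():
                st[f"layer{i}.{k}"] = v.copy()
            if isinstance(layer, BatchNormLayer):
                st[f"layer{i}.running_mean"] = layer.running_mean.copy()
                st[f"layer{i}.running_var"] = layer.running_var.copy()
        return st

    def load_state(self, st: dict) -> None:
        for i, layer in enumerate(self.net.layers):
            for k in layer.params:
                layer.params[k] = st[f"layer{i}.{k}"].copy()
            if isinstance(layer, BatchNormLayer):
                layer.running_mean = st[f"layer{i}.running_mean"].copy()
                layer.running_var = st[f"layer{i}.running_var"].copy()


class Model(_NetRunner):
    """A layer stack plus the geometry it was built on."""

    def __init__(self, spec: ModelSpec, net: Sequential, meshes, smaps):
        super().__init__(net)
        self.spec = spec
        self.meshes = meshes
        self.sampling_maps = smaps

    def feature_map_shapes(self, batch: int = 1) -> list[tuple]:
        """Shapes after each complex for one forward probe (diagnostics)."""
        x = np.zeros((batch, self.meshes[0].n_nodes, self.spec.input_channels))
        shapes = []
        for i, layer in enumerate(self.net.layers):
            x = layer.forward(x, train=False)
            if (i + 1) % LAYERS_PER_COMPLEX == 0 and i < LAYERS_PER_COMPLEX * self.spec.n_complexes:
                shapes.append(x.shape[1:])
        return shapes

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: architecture spec + all weights and
        running statistics (npz with an embedded JSON header)."""
        st = self.state()
        st["__spec__"] = np.frombuffer(
            json.dumps(asdict(self.spec)).encode(), dtype=np.uint8
        )
        np.savez(path, **st)


def load_model(path: str | Path, cache_dir=None) -> Model:
    with np.load(path) as data:
        spec_d = json.loads(bytes(data["__spec__"]).decode())
        spec_d["filters_per_layer"] = tuple(spec_d["filters_per_layer"])
        spec_d["patch"] = tuple(spec_d["patch"])
        spec = ModelSpec(**spec_d)
        model = build_model(spec, cache_dir=cache_dir)
        model.load_state({k: data[k] for k in data.files if k != "__spec__"})
    return model


def _template_for(spec: ModelSpec, mesh: IcosphereMesh):
    spacing = spec.spacing if spec.spacing is not None else mesh.mean_edge_angle()
    kind, a, b = spec.patch
    if kind == "rect":
        return rectangular_template(a, b, spacing)
    if kind == "circ":
        return circular_template(a, b, spacing)
    raise ValueError(f"unknown patch kind {kind!r}")


def build_model(
    spec: ModelSpec,
    meshes: list[IcosphereMesh] | None = None,
    sampling_maps: list[SamplingMap] | None = None,
    cache_dir=None,
) -> Model:
    """Assemble the full network from an architecture spec.

    ``meshes`` (fine to coarse, levels input_level .. output_level) and
    ``sampling_maps`` (one per complex) are built on demand when omitted.
    """
    if meshes is None:
        meshes = [
            icosphere(spec.input_level - i) for i in range(spec.n_complexes + 1)
        ]
    expect = [spec.input_level - i for i in range(spec.n_complexes + 1)]
    if [m.level for m in meshes] != expect:
        raise ValueError(f"mesh levels {[m.level for m in meshes]} != {expect}")
    if sampling_maps is None:
        sampling_maps = [
            build_sampling_map(_template_for(spec, meshes[i]), meshes[i], cache_dir)
            for i in range(spec.n_complexes)
        ]
    for i, sm in enumerate(sampling_maps):
        if sm.n_nodes != meshes[i].n_nodes:
            raise ValueError(f"sampling map {i} does not match mesh level {meshes[i].level}")

    rng = np.random.default_rng(spec.seed)
    layers = []
    c_in = spec.input_channels
    for i in range(spec.n_complexes):
        f = spec.filters_per_layer[i]
        layers.append(MeshConvLayer(sampling_maps[i], c_in, f, rng, bias=spec.conv_bias))
        layers.append(BatchNormLayer(f))
        layers.append(ReLULayer())
        pm = pooling_map(meshes[i], meshes[i + 1], include_self=spec.pool_include_self)
        layers.append(MeshPoolLayer(pm, mode=spec.pool_mode))
        c_in = f
    layers.append(FlattenLayer())
    flat = meshes[-1].n_nodes * c_in
    layers.append(DenseLayer(flat, spec.hidden_units, rng))
    layers.append(ReLULayer())
    layers.append(DenseLayer(spec.hidden_units, spec.n_classes, rng))
    return Model(spec, Sequential(layers), meshes, sampling_maps)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        idx = order[start : start + batch_size]
        if len(idx) >= 2:  # batch norm needs at least 2 samples
            yield idx


def _saturated(train_err: list[float], window: int, tol: float) -> bool:
    """Moving-average training error improved < tol points over `window`
    epochs: the trigger for the learning-rate drop."""
    if len(train_err) < 2 * window:
        return False
    recent = np.mean(train_err[-window:])
    earlier = np.mean(train_err[-2 * window : -window])
    return earlier - recent < tol


def train(
    model: Model,
    dataset: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    cfg: TrainConfig,
    fold: int = 0,
) -> FoldResult:
    """SGD training with the two-stage learning-rate schedule and early
    stopping on the validation error.

    ``dataset`` is (X_train, y_train, X_val, y_val) with inputs of shape
    (S, N, C). Restores and returns the checkpoint of the best validation
    epoch.
    """
    X_tr, y_tr, X_val, y_val = dataset
    if len(X_tr) < 2 or len(X_val) == 0:
        raise ValueError("training split needs >= 2 samples and a non-empty validation split")
    rng = np.random.default_rng(cfg.seed + 7919 * fold)
    opt = SGD(model.net, momentum=cfg.momentum, weight_decay=cfg.weight_decay)

    lr = cfg.lr_initial
    fine = False
    train_err: list[float] = []
    val_err: list[float] = []
    best = (np.inf, -1, None)  # (val error, epoch, state)
    epoch = 0
    while True:
        correct = 0
        seen = 0
        for idx in _batches(len(X_tr), cfg.batch_size, rng):
            logits = model.forward(X_tr[idx], train=True)
            loss, probs = model.loss.forward(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, lr={lr}; "
                    f"logit range [{logits.min():.3g}, {logits.max():.3g}]"
                )
            model.net.backward(model.loss.backward())
            opt.step(lr)
            correct += int((probs.argmax(axis=1) == y_tr[idx]).sum())
            seen += len(idx)
        train_err.append(100.0 * (1 - correct / seen))

        acc_val, _ = evaluate(model, X_val, y_val)
        val_err.append(100.0 - acc_val)
        if val_err[-1] < best[0]:
            best = (val_err[-1], epoch, model.state())

        if not fine and _saturated(train_err, cfg.saturation_window, cfg.saturation_tol):
            lr = cfg.lr_fine
            fine = True

        epoch += 1
        if epoch >= cfg.max_epochs:
            saturated = fine or _saturated(
                train_err, cfg.saturation_window, cfg.saturation_tol
            )
            if saturated or epoch >= cfg.extended_epochs:
                break
        if (
            cfg.stop_patience is not None
            and epoch - best[1] > cfg.stop_patience
        ):
            break

    if cfg.early_stopping and best[2] is not None:
        model.load_state(best[2])
        best_epoch = best[1]
        val_acc = 100.0 - best[0]
    else:
        best_epoch = epoch - 1
        val_acc = 100.0 - val_err[-1]
    return FoldResult(
        fold=fold,
        best_epoch=best_epoch,
        val_accuracy=val_acc,
        test_accuracy=None,
        train_err=train_err,
        val_err=val_err,
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    cfg: TrainConfig,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    cache_dir=None,
) -> tuple[list[FoldResult], dict]:
    """Stratified k-fold cross-validation with a shared held-out test set.

    Each fold trains a fresh model on 90% of the train-validation data,
    early-stops on its 10% validation split, and is evaluated on the test
    set. Returns per-fold results and a mean/SD summary of test (or, absent
    a test set, validation) accuracy.
    """
    if len(X) < cfg.folds:
        raise ValueError(f"{len(X)} samples cannot form {cfg.folds} folds")
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    meshes = None
    smaps = None
    results: list[FoldResult] = []
    models: list[Model] = []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        fold_spec = ModelSpec(**{**asdict(spec), "seed": spec.seed + fold})
        model = build_model(fold_spec, meshes, smaps, cache_dir=cache_dir)
        meshes, smaps = model.meshes, model.sampling_maps  # reuse geometry
        res = train(model, (X[tr], y[tr], X[va], y[va]), cfg, fold=fold)
        if X_test is not None:
            res.test_accuracy, _ = evaluate(model, X_test, y_test)
        results.append(res)
        models.append(model)
    accs = [
        r.test_accuracy if r.test_accuracy is not None else r.val_accuracy
        for r in results
    ]
    summary = {
        "mean_accuracy": float(np.mean(accs)),
        "std_accuracy": float(np.std(accs, ddof=1)),
        "per_fold": accs,
    }
    return results, {"summary": summary, "models": models}


def transfer_retrain(
    model: Model,
    new_dataset: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    cfg: TrainConfig,
    n_frozen_layers: int | None = None,
) -> tuple[Model, FoldResult]:
    """Freeze the convolution complexes of a trained model and retrain only
    the classifier head on a new dataset.

    The default freeze depth is all complexes (4 layers each: conv, batch
    norm, ReLU, pool — 20 layers for the 5-complex model). Frozen layers
    receive no gradient and no fine tuning; frozen batch-norm layers keep
    using their stored running statistics.
    """
    new_model = copy.deepcopy(model)
    if n_frozen_layers is None:
        n_frozen_layers = LAYERS_PER_COMPLEX * model.spec.n_complexes
    new_model.net.freeze(n_frozen_layers)

    # The frozen prefix is deterministic in inference mode, so its features
    # are computed once and only the head sees the optimizer.
    X_tr, y_tr, X_val, y_val = new_dataset
    prefix = Sequential(new_model.net.layers[:n_frozen_layers])
    head = _NetRunner(Sequential(new_model.net.layers[n_frozen_layers:]))

    def features(X: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [prefix.forward(X[i : i + 200], train=False) for i in range(0, len(X), 200)]
        )

    result = train(head, (features(X_tr), y_tr, features(X_val), y_val), cfg)
    return new_model, result


def evaluate(
    model: Model, X: np.ndarray, y: np.ndarray, batch_size: int = 200
) -> tuple[float, np.ndarray]:
    """Accuracy (percent) and per-sample predictions, inference mode."""
    if len(X) != len(y):
        raise ValueError(f"{len(X)} samples vs {len(y)} labels")
    preds = np.concatenate(
        [
            model.predict(X[i : i + batch_size])
            for i in range(0, len(X), batch_size)
        ]
    )
    return 100.0 * float(np.mean(preds == y)), preds


def saliency(model: Model, x: np.ndarray, label: int | None = None) -> np.ndarray:
    """Gradient saliency: |d score_class / d input| per node and channel.

    The score is the pre-softmax logit of ``label`` (the predicted class
    when label is None), differentiated with respect to the input map by a
    full backward pass in inference mode.
    """
    xb = x[None] if x.ndim == 2 else x
    logits = model.forward(xb, train=False)
    if label is None:
        label = int(logits[0].argmax())
    g = np.zeros_like(logits)
    g[:, label] = 1.0
    grad_in = model.net.backward(g, to_input=True)
    return np.abs(grad_in[0])


def group_saliency(
    model: Model, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Mean of individual true-class saliency maps over a group."""
    maps = [saliency(model, X[i], int(y[i])) for i in range(len(X))]
    return np.mean(maps, axis=0)
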