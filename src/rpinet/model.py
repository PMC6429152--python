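"""The four basic interaction modules and the ensemble head.

Four "basic modules" each score an (RNA, protein) pair from its k-mer
feature vectors:

* Conjoint-CNN / Conjoint-SAE read the sequence-only (ictf) encodings
  (RNA 340, protein 399);
* Conjoint-Struct-CNN / Conjoint-Struct-SAE read the structure-augmented
  (isctf) encodings (RNA 370, protein 438).

A CNN module treats each feature vector as a length-D single-channel signal
and runs it through three convolution layers with 45, 64 and 45 filters
(max-pooling between convolutions, batch norm + ReLU throughout), flattens,
and embeds to a 128-unit dense layer per branch.  An SAE module embeds each
branch through dense layers of 256, 128 and 64 units, pretrained greedily
layer-by-layer as auto-encoders before supervised fine-tuning.  Both module
kinds concatenate the two branch embeddings into a Dense-128-64-2 softmax
head.  The ensemble model concatenates the four modules' two-class outputs
(8 values) and feeds a Dense-16-8-2 softmax head trained with the basic
modules frozen.

Training minimizes binary cross-entropy in two phases — Adam for fast
convergence, then SGD for fine-tuning — recording training accuracy after
every epoch, checkpointing whenever it beats the running best, and stopping
once the best has not improved for ``patience`` epochs, after which the best
checkpoint is restored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .dataset import InteractionPair, RPIDataset
from .encoding import (IMPROVED_CTF, IMPROVED_STRUCT_CTF, PROTEIN, RNA,
                       encode_records, get_scheme)

logger = logging.getLogger(__name__)

#: canonical order of the four basic modules
MODULE_NAMES = ("conjoint-cnn", "conjoint-sae", "conjoint-struct-cnn",
                "conjoint-struct-sae")


class ModelError(ValueError):
    """Configuration or input error in model construction/training."""


class MissingFeatureError(KeyError):
    """A pair references an ID absent from the feature store."""


@dataclass
class ModuleConfig:
    """Hyperparameters for the basic modules and ensemble head.

    Layer widths default to the published architecture; optimizer and
    regularization settings are exposed knobs with conventional defaults.
    """

    conv_filters: tuple[int, int, int] = (45, 64, 45)
    conv_kernel: int = 6
    pool_size: int = 2
    branch_dense: int = 128
    sae_widths: tuple[int, int, int] = (256, 128, 64)
    head_widths: tuple[int, int, int] = (128, 64, 2)
    ensemble_widths: tuple[int, int, int] = (16, 8, 2)
    dropout_rate: float = 0.2
    adam_lr: float = 1e-3
    sgd_lr: float = 1e-4
    batch_size: int = 64
    max_epochs_adam: int = 50
    max_epochs_sgd: int = 50
    patience: int = 10
    sae_pretrain_epochs: int = 20
    standardize: bool = True
    # the ensemble head is a tiny network over 8 probability inputs; its
    # training is nearly free, so it gets its own (longer, larger-step)
    # schedule independent of however the basic modules are budgeted
    ensemble_adam_lr: float = 1e-2
    ensemble_sgd_lr: float = 1e-3
    ensemble_max_epochs_adam: int = 50
    ensemble_max_epochs_sgd: int = 10
    ensemble_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ModelError("dropout_rate must be in [0, 1)")
        for name in ("adam_lr", "sgd_lr", "ensemble_adam_lr", "ensemble_sgd_lr"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be nonnegative")
        for name in ("conv_kernel", "pool_size", "batch_size", "max_epochs_adam",
                     "max_epochs_sgd", "patience", "sae_pretrain_epochs",
                     "ensemble_max_epochs_adam", "ensemble_max_epochs_sgd",
                     "ensemble_patience"):
            if getattr(self, name) < 1:
                raise ModelError(f"{name} must be positive")

    @classmethod
    def quick(cls, seed: int = 0) -> "ModuleConfig":
        """Scaled-down schedule for mid-sized planted-rule benchmarks.

        The planted signal is strong, so a few Adam epochs plus one SGD
        fine-tuning epoch converge; larger batches amortize per-step cost.
        """
        return cls(max_epochs_adam=4, max_epochs_sgd=1, patience=2,
                   sae_pretrain_epochs=10, batch_size=128, seed=seed)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                if isinstance(value, bool):
                    value = int(value)
                elif isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                fh.write(f"{key}={value}\n")

    @classmethod
    def from_file(cls, path) -> "ModuleConfig":
        kwargs = {}
        types = cls.__dataclass_fields__
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ModelError(f"unknown config key {key!r}")
            default = getattr(cls, key, types[key].default)
            if isinstance(default, bool):
                kwargs[key] = bool(int(raw))
            elif isinstance(default, tuple):
                kwargs[key] = tuple(int(v) for v in raw.split(","))
            elif isinstance(default, float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = int(raw)
        return cls(**kwargs)


@dataclass
class TrainingReport:
    losses: list[float] = field(default_factory=list)
    accuracies: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False
    optimizer_phases: list[tuple[str, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Feature store
# ---------------------------------------------------------------------------

class PairFeatures:
    """Precomputed encodings for every record, under both coding schemes."""

    def __init__(self, rna_index: dict[str, int], protein_index: dict[str, int],
                 matrices: dict[tuple[str, str], np.ndarray]):
        self.rna_index = rna_index
        self.protein_index = protein_index
        self.matrices = matrices  # (scheme_name, molecule) -> (n, d) float32

    @classmethod
    def from_dataset(cls, dataset: RPIDataset,
                     include_structure: bool | None = None) -> "PairFeatures":
        """Encode all records; structure features are included when every
        record has a structure string (or as forced by ``include_structure``)."""
        if include_structure is None:
            include_structure = dataset.has_structures()
        schemes = [IMPROVED_CTF] + ([IMPROVED_STRUCT_CTF] if include_structure else [])
        matrices = {}
        rna_recs = list(dataset.rnas.values())
        prot_recs = list(dataset.proteins.values())
        rna_index = {r.id: i for i, r in enumerate(rna_recs)}
        protein_index = {p.id: i for i, p in enumerate(prot_recs)}
        for scheme_name in schemes:
            for molecule, recs in ((RNA, rna_recs), (PROTEIN, prot_recs)):
                _, mat = encode_records(recs, get_scheme(scheme_name, molecule))
                matrices[(scheme_name, molecule)] = mat.astype(np.float32)
        return cls(rna_index, protein_index, matrices)

    def scheme_for(self, use_structure: bool) -> str:
        return IMPROVED_STRUCT_CTF if use_structure else IMPROVED_CTF

    def dims(self, use_structure: bool) -> tuple[int, int]:
        s = self.scheme_for(use_structure)
        return (self.matrices[(s, RNA)].shape[1],
                self.matrices[(s, PROTEIN)].shape[1])

    def pair_matrices(self, pairs: Sequence[InteractionPair],
                      use_structure: bool) -> tuple[np.ndarray, np.ndarray]:
        s = self.scheme_for(use_structure)
        if (s, RNA) not in self.matrices:
            raise MissingFeatureError(
                "structure-augmented features were not computed for this dataset")
        try:
            ri = [self.rna_index[p.rna_id] for p in pairs]
            pi = [self.protein_index[p.protein_id] for p in pairs]
        except KeyError as exc:
            raise MissingFeatureError(f"no features for id {exc.args[0]!r}") from None
        return self.matrices[(s, RNA)][ri], self.matrices[(s, PROTEIN)][pi]

    def entity_matrix(self, molecule: str, use_structure: bool) -> np.ndarray:
        return self.matrices[(self.scheme_for(use_structure), molecule)]


# ---------------------------------------------------------------------------
# Module builders
# ---------------------------------------------------------------------------

def _cnn_branch(dim: int, config: ModuleConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    c_in = 1
    length = dim
    for i, filters in enumerate(config.conv_filters):
        layers += [nn.Conv1D(c_in, filters, config.conv_kernel, rng),
                   nn.BatchNorm(filters), nn.ReLU()]
        c_in = filters
        if i < len(config.conv_filters) - 1:  # pooling between convolutions
            layers.append(nn.MaxPool1D(config.pool_size))
            length //= config.pool_size
    layers += [nn.Flatten(),
               nn.Dense(length * c_in, config.branch_dense, rng),
               nn.BatchNorm(config.branch_dense), nn.ReLU(),
               nn.Dropout(config.dropout_rate, rng)]
    return nn.Sequential(layers)


def _sae_branch(dim: int, config: ModuleConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    n_in = dim
    for width in config.sae_widths:
        layers += [nn.Dense(n_in, width, rng), nn.ReLU()]
        n_in = width
    return nn.Sequential(layers)


def _dense_head(n_in: int, widths: Sequence[int], config: ModuleConfig,
                rng: np.random.Generator, dropout: bool = True) -> nn.Sequential:
    layers: list[nn.Layer] = []
    for width in widths[:-1]:
        layers += [nn.Dense(n_in, width, rng), nn.BatchNorm(width), nn.ReLU()]
        if dropout:
            layers.append(nn.Dropout(config.dropout_rate, rng))
        n_in = width
    layers.append(nn.Dense(n_in, widths[-1], rng))  # logits; softmax in the loss
    return nn.Sequential(layers)


class BasicModule:
    """One CNN or SAE pair scorer emitting two-class probabilities."""

    def __init__(self, kind: str, use_structure: bool, net: nn.PairNet,
                 input_dims: tuple[int, int], config: ModuleConfig):
        if kind not in ("cnn", "sae"):
            raise ModelError(f"unknown module kind {kind!r}")
        self.kind = kind
        self.use_structure = use_structure
        self.net = net
        self.input_dims = input_dims
        self.config = config
        self.pretraining_log: list[dict] = []
        # optional per-feature standardization fitted on training data:
        # (mean_rna, std_rna, mean_protein, std_protein)
        self.scalers: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def name(self) -> str:
        return f"conjoint-{'struct-' if self.use_structure else ''}{self.kind}"

    def fit_scalers(self, x_rna: np.ndarray, x_protein: np.ndarray) -> None:
        """Fit per-feature z-score parameters (constant features left unscaled)."""

        def stats(x):
            mean = x.mean(axis=0).astype(np.float32)
            std = x.std(axis=0).astype(np.float32)
            std[std < 1e-8] = 1.0
            return mean, std

        self.scalers = (*stats(x_rna), *stats(x_protein))

    def _prepare(self, x_rna: np.ndarray, x_protein: np.ndarray):
        if x_rna.shape[1] != self.input_dims[0] or x_protein.shape[1] != self.input_dims[1]:
            raise ModelError(
                f"{self.name}: input dims {(x_rna.shape[1], x_protein.shape[1])} "
                f"!= expected {self.input_dims}")
        xr = x_rna.astype(np.float32)
        xp = x_protein.astype(np.float32)
        if self.scalers is not None:
            mr, sr, mp, sp = self.scalers
            xr = (xr - mr) / sr
            xp = (xp - mp) / sp
        if self.kind == "cnn":
            xr = xr[:, :, None]
            xp = xp[:, :, None]
        return xr, xp

    def forward_logits(self, x_rna, x_protein, training: bool) -> np.ndarray:
        return self.net.forward(self._prepare(x_rna, x_protein), training)

    def predict_proba(self, x_rna: np.ndarray, x_protein: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
        """(n, 2) softmax probabilities, deterministic given weights."""
        outs = []
        for start in range(0, len(x_rna), batch_size):
            sl = slice(start, start + batch_size)
            outs.append(nn.softmax(self.forward_logits(x_rna[sl], x_protein[sl],
                                                       training=False)))
        return np.concatenate(outs).astype(np.float64)


def build_cnn_module(config: ModuleConfig, d_rna: int, d_protein: int,
                     use_structure: bool = False,
                     rng: np.random.Generator | None = None) -> BasicModule:
    """Conjoint(-Struct)-CNN: Conv-45-64-45 branches + Dense-128-64-2 head."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    net = nn.PairNet(
        _cnn_branch(d_rna, config, rng),
        _cnn_branch(d_protein, config, rng),
        _dense_head(2 * config.branch_dense, config.head_widths, config, rng),
    )
    return BasicModule("cnn", use_structure, net, (d_rna, d_protein), config)


def build_sae_module(config: ModuleConfig, d_rna: int, d_protein: int,
                     use_structure: bool = False,
                     rng: np.random.Generator | None = None) -> BasicModule:
    """Conjoint(-Struct)-SAE: Dense-256-128-64 branches + Dense-128-64-2 head."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    net = nn.PairNet(
        _sae_branch(d_rna, config, rng),
        _sae_branch(d_protein, config, rng),
        _dense_head(2 * config.sae_widths[-1], config.head_widths, config, rng),
    )
    return BasicModule("sae", use_structure, net, (d_rna, d_protein), config)


# ---------------------------------------------------------------------------
# SAE greedy layer-wise pretraining
# ---------------------------------------------------------------------------

def _pretrain_branch(branch: nn.Sequential, x: np.ndarray, config: ModuleConfig,
                     rng: np.random.Generator) -> list[dict]:
    """Train each dense layer of ``branch`` in turn as an auto-encoder.

    Layer i is paired with a throwaway linear decoder back to its input
    width and optimized on mean-squared reconstruction error; the trained
    encodings feed layer i+1.  The supervised head is untouched.
    """
    log = []
    dense_layers = [l for l in branch.layers if isinstance(l, nn.Dense)]
    for layer in dense_layers:
        n_in = layer.W.shape[0]
        decoder = nn.Dense(layer.W.shape[1], n_in, rng)
        params = layer.params() + decoder.params()
        grads = layer.grads() + decoder.grads()
        opt = nn.Adam(params, grads, lr=config.adam_lr)
        relu = nn.ReLU()

        def reconstruction_mse(data):
            h = relu.forward(layer.forward(data, training=False), training=False)
            recon = decoder.forward(h, training=False)
            return float(np.mean((recon - data) ** 2))

        initial = reconstruction_mse(x)
        n = len(x)
        for _ in range(config.sae_pretrain_epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                batch = x[order[start:start + config.batch_size]]
                h = relu.forward(layer.forward(batch, training=True), training=True)
                recon = decoder.forward(h, training=True)
                grad = (2.0 / recon.size) * (recon - batch)
                layer.backward(relu.backward(decoder.backward(grad.astype(np.float32))))
                opt.step()
        final = reconstruction_mse(x)
        log.append({"n_in": n_in, "initial_mse": initial, "final_mse": final})
        x = relu.forward(layer.forward(x, training=False), training=False)
    return log


def pretrain_sae(module: BasicModule, x_rna: np.ndarray,
                 x_protein: np.ndarray) -> BasicModule:
    """Greedy layer-wise auto-encoder pretraining of both SAE branches."""
    if module.kind != "sae":
        raise ModelError("pretrain_sae requires an SAE module")
    if len(x_rna) == 0 or len(x_protein) == 0:
        raise ModelError("empty feature matrix")
    config = module.config
    if config.standardize and module.scalers is None:
        module.fit_scalers(x_rna, x_protein)
    xr = x_rna.astype(np.float32)
    xp = x_protein.astype(np.float32)
    if module.scalers is not None:
        mr, sr, mp, sp = module.scalers
        xr = (xr - mr) / sr
        xp = (xp - mp) / sp
    rng = np.random.default_rng(config.seed + 101)
    module.pretraining_log = [
        {"branch": "rna",
         "layers": _pretrain_branch(module.net.branch_rna, xr, config, rng)},
        {"branch": "protein",
         "layers": _pretrain_branch(module.net.branch_protein, xp, config, rng)},
    ]
    return module


# ---------------------------------------------------------------------------
# Supervised training loop
# ---------------------------------------------------------------------------

def _accuracy(net: nn.Layer, make_input, n: int, labels: np.ndarray,
              batch_size: int = 512) -> float:
    correct = 0
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        logits = net.forward(make_input(sl), training=False)
        correct += int((logits.argmax(axis=1) == labels[sl]).sum())
    return correct / n


def fit_network(net: nn.Layer, make_input, n: int, labels: np.ndarray,
                config: ModuleConfig, rng: np.random.Generator) -> TrainingReport:
    """Two-phase (Adam then SGD) minibatch training with best-checkpoint
    early stopping on training accuracy.

    ``make_input(index_array_or_slice)`` materializes the network input for
    those rows — a tuple for :class:`nn.PairNet`, an array otherwise.
    """
    report = TrainingReport()
    best_acc = -np.inf
    best_snapshot = nn.snapshot_params(net)
    since_best = 0
    stop = False
    for phase_name, lr, max_epochs in (("adam", config.adam_lr, config.max_epochs_adam),
                                       ("sgd", config.sgd_lr, config.max_epochs_sgd)):
        if stop:
            break
        opt_cls = nn.Adam if phase_name == "adam" else nn.SGD
        opt = opt_cls(net.params(), net.grads(), lr=lr)
        phase_epochs = 0
        for _ in range(max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                logits = net.forward(make_input(idx), training=True)
                loss, grad = nn.softmax_cross_entropy_grad(logits, labels[idx])
                net.backward(grad)
                opt.step()
                epoch_loss += loss * len(idx)
            phase_epochs += 1
            acc = _accuracy(net, make_input, n, labels)
            report.losses.append(epoch_loss / n)
            report.accuracies.append(acc)
            if acc > best_acc:
                best_acc = acc
                best_snapshot = nn.snapshot_params(net)
                report.best_epoch = len(report.accuracies) - 1
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    report.stopped_early = True
                    stop = True
                    break
        report.optimizer_phases.append((phase_name, phase_epochs))
    nn.restore_params(net, best_snapshot)
    return report


def train_module(module: BasicModule, train_pairs: Sequence[InteractionPair],
                 features: PairFeatures,
                 config: ModuleConfig | None = None) -> tuple[BasicModule, TrainingReport]:
    """Supervised training of one basic module on labeled pairs."""
    config = config or module.config
    labels = np.array([p.label for p in train_pairs])
    if len(np.unique(labels)) < 2:
        raise ModelError("training pairs contain a single class")
    x_rna, x_protein = features.pair_matrices(train_pairs, module.use_structure)
    if config.standardize and module.scalers is None:
        module.fit_scalers(x_rna, x_protein)
    xr, xp = module._prepare(x_rna, x_protein)
    rng = np.random.default_rng(config.seed + 17)
    report = fit_network(module.net, lambda idx: (xr[idx], xp[idx]), len(labels),
                         labels, config, rng)
    logger.info("%s trained: best train acc %.4f at epoch %d (%s)",
                module.name, max(report.accuracies), report.best_epoch,
                report.optimizer_phases)
    return module, report


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

class EnsembleModel:
    """Four frozen basic modules + a Dense-16-8-2 head over their outputs."""

    def __init__(self, modules: Sequence[BasicModule], head: nn.Sequential,
                 config: ModuleConfig):
        if len(modules) != 4:
            raise ModelError("ensemble requires exactly four basic modules")
        self.modules = tuple(modules)
        self.head = head
        self.config = config

    def module_outputs(self, pairs: Sequence[InteractionPair],
                       features: PairFeatures) -> np.ndarray:
        """Concatenated (n, 8) probability outputs of the four basic modules."""
        outs = []
        for module in self.modules:
            xr, xp = features.pair_matrices(pairs, module.use_structure)
            outs.append(module.predict_proba(xr, xp))
        return np.concatenate(outs, axis=1).astype(np.float32)

    def predict_proba(self, pairs: Sequence[InteractionPair],
                      features: PairFeatures) -> np.ndarray:
        x = self.module_outputs(pairs, features)
        return nn.softmax(self.head.forward(x, training=False)).astype(np.float64)


def build_ensemble_head(config: ModuleConfig,
                        rng: np.random.Generator | None = None) -> nn.Sequential:
    rng = rng if rng is not None else np.random.default_rng(config.seed + 23)
    return _dense_head(8, config.ensemble_widths, config, rng, dropout=False)


def train_ensemble(dataset: RPIDataset, config: ModuleConfig = ModuleConfig(),
                   features: PairFeatures | None = None,
                   ) -> tuple[EnsembleModel, dict[str, TrainingReport]]:
    """Train the full hierarchical model on a labeled dataset.

    Each basic module is trained once on the training pairs (SAE modules are
    pretrained first on the unlabeled entity feature matrices); the ensemble
    head is then trained on the concatenated module outputs for the same
    pairs, with the basic modules frozen.
    """
    if features is None:
        features = PairFeatures.from_dataset(dataset)
    if (IMPROVED_STRUCT_CTF, RNA) not in features.matrices:
        raise ModelError("structure-augmented modules need structure strings "
                         "for every record")
    seed_seq = np.random.SeedSequence(config.seed)
    module_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seed_seq.spawn(5)]

    modules: list[BasicModule] = []
    reports: dict[str, TrainingReport] = {}
    specs = [("cnn", False), ("sae", False), ("cnn", True), ("sae", True)]
    for (kind, use_structure), mod_seed in zip(specs, module_seeds[:4]):
        mod_config = ModuleConfig(**{**asdict(config), "seed": mod_seed})
        builder = build_cnn_module if kind == "cnn" else build_sae_module
        module = builder(mod_config, *features.dims(use_structure),
                         use_structure=use_structure)
        if kind == "sae":
            pretrain_sae(module,
                         features.entity_matrix(RNA, use_structure),
                         features.entity_matrix(PROTEIN, use_structure))
        _, report = train_module(module, dataset.pairs, features, mod_config)
        modules.append(module)
        reports[module.name] = report

    head_config = ModuleConfig(**{
        **asdict(config), "seed": module_seeds[4],
        "adam_lr": config.ensemble_adam_lr,
        "sgd_lr": config.ensemble_sgd_lr,
        "max_epochs_adam": config.ensemble_max_epochs_adam,
        "max_epochs_sgd": config.ensemble_max_epochs_sgd,
        "patience": config.ensemble_patience,
    })
    head = build_ensemble_head(head_config)
    ensemble = EnsembleModel(modules, head, config)
    x_head = ensemble.module_outputs(dataset.pairs, features)
    labels = np.array([p.label for p in dataset.pairs])
    rng = np.random.default_rng(head_config.seed + 17)
    reports["ensemble"] = fit_network(head, lambda idx: x_head[idx], len(labels),
                                      labels, head_config, rng)
    return ensemble, reports


def predict(model: BasicModule | EnsembleModel, pairs: Sequence[InteractionPair],
            features: PairFeatures) -> np.ndarray:
    """Positive-class probability per pair, in input order."""
    if isinstance(model, EnsembleModel):
        return model.predict_proba(pairs, features)[:, 1]
    xr, xp = features.pair_matrices(pairs, model.use_structure)
    return model.predict_proba(xr, xp)[:, 1]


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: EnsembleModel, outdir) -> None:
    """Write weights (one .npz per component) plus a key-value manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model.config.to_file(outdir / "config.txt")
    manifest = {"modules": [], "format": 1}
    for module in model.modules:
        fname = f"{module.name}.npz"
        arrays = {f"p{i}": p for i, p in enumerate(_all_state(module.net))}
        if module.scalers is not None:
            arrays.update({f"s{i}": s for i, s in enumerate(module.scalers)})
        np.savez(outdir / fname, **arrays)
        manifest["modules"].append({"name": module.name, "kind": module.kind,
                                    "use_structure": module.use_structure,
                                    "d_rna": module.input_dims[0],
                                    "d_protein": module.input_dims[1],
                                    "weights": fname})
    np.savez(outdir / "ensemble-head.npz",
             **{f"p{i}": p for i, p in enumerate(_all_state(model.head))})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _all_state(net: nn.Layer) -> list[np.ndarray]:
    """Trainable parameters plus batch-norm running statistics, in layer order."""
    return net.state()


def load_model(indir) -> EnsembleModel:
    indir = Path(indir)
    config = ModuleConfig.from_file(indir / "config.txt")
    manifest = json.loads((indir / "manifest.json").read_text())
    modules = []
    for entry in manifest["modules"]:
        builder = build_cnn_module if entry["kind"] == "cnn" else build_sae_module
        module = builder(config, entry["d_rna"], entry["d_protein"],
                         use_structure=entry["use_structure"])
        scalers = _load_state(module.net, indir / entry["weights"])
        if scalers:
            module.scalers = tuple(scalers)
        modules.append(module)
    head = build_ensemble_head(config)
    _load_state(head, indir / "ensemble-head.npz")
    return EnsembleModel(modules, head, config)


def _load_state(net: nn.Layer, path) -> list[np.ndarray]:
    with np.load(path) as data:
        n_params = sum(1 for f in data.files if f.startswith("p"))
        arrays = [data[f"p{i}"] for i in range(n_params)]
        scalers = [data[f"s{i}"] for i in range(len(data.files) - n_params)]
    state = _all_state(net)
    if len(state) != len(arrays):
        raise ModelError(f"weight file {path} does not match architecture")
    for dst, src in zip(state, arrays):
        dst[...] = src
    return scalers
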