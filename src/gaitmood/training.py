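"""Training recipe: RMSprop (m=0.5, rho=0.3, eps=1e-7, lr=1e-4), categorical
cross-entropy, batch 64, 75 epochs, stratified 80:10:10 splitting.

Everything is seeded: split membership, weight initialization, per-epoch
batch shuffling and dropout masks all derive from the single
``TrainingConfig.seed``, so identical configs reproduce identical histories
(bitwise, since the NumPy backend is deterministic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _backend
from .errors import ConfigError, ContractError, StratificationError, VersionError
from .evaluation import EvalReport, confusion_matrix, evaluate, micro_map
from .geometric_features import FeatureConfig, assemble_input, feature_dim
from .model_core import NetworkConfig, build_model
from .skeleton_data import GaitDataset, stratified_split


@dataclass(frozen=True)
class OptimizerConfig:
    name: str = "rmsprop"
    momentum: float = 0.5
    rho: float = 0.3
    epsilon: float = 1e-7
    learning_rate: float = 1e-4

    def __post_init__(self) -> None:
        if self.name.lower() != "rmsprop":
            raise ConfigError(f"only RMSprop is supported, got {self.name!r}")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError(f"rho must be in [0, 1), got {self.rho}")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigError(f"momentum must be in [0, 1), got {self.momentum}")

    def to_dict(self) -> dict:
        return {
            "name": self.name, "momentum": self.momentum, "rho": self.rho,
            "epsilon": self.epsilon, "learning_rate": self.learning_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OptimizerConfig":
        return cls(**d)


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 64
    epochs: int = 75
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    shuffling: str = "stratified"  # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.shuffling not in ("stratified", "random"):
            raise ConfigError(f"unknown shuffling mode {self.shuffling!r}")

    def to_dict(self) -> dict:
        return {
            "batch_size": self.batch_size, "epochs": self.epochs,
            "split_fractions": list(self.split_fractions),
            "shuffling": self.shuffling, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        d = dict(d)
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        return cls(**d)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    train_micro_map: float
    val_micro_map: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class TrainingHistory:
    records: list[EpochRecord]
    model: _backend.SequentialModel
    manifest: dict
    split_ids: dict[str, list[str]]  # train/val/test sequence ids

    def history_rows(self) -> list[dict]:
        return [r.to_dict() for r in self.records]


def categorical_cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    """-log(probability of the true class), probabilities clipped to
    [1e-12, 1] before the log."""
    probs = np.asarray(probs, dtype=np.float64)
    onehot = np.asarray(onehot)
    if probs.shape != onehot.shape:
        raise ContractError("probs and onehot must share one shape")
    if not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ContractError(f"probs must sum to 1, got {probs.sum()!r}")
    ones = np.flatnonzero(onehot == 1)
    if len(ones) != 1 or not np.all(np.isin(onehot, (0, 1))):
        raise ContractError("onehot must contain exactly one 1 and else 0")
    p = np.clip(probs[ones[0]], 1e-12, 1.0)
    return float(-np.log(p))


def _random_split(dataset: GaitDataset, fractions, seed: int):
    """Unstratified shuffled split (same allocation rule, no per-class
    grouping); used when TrainingConfig.shuffling == 'random'."""
    from .skeleton_data import largest_remainder_allocation

    rng = np.random.default_rng(seed)
    idx = np.arange(len(dataset))
    rng.shuffle(idx)
    counts = largest_remainder_allocation(len(idx), fractions)
    parts = []
    start = 0
    for n_k in counts:
        parts.append(sorted(idx[start : start + n_k].tolist()))
        start += n_k
    return tuple(dataset.subset(p) for p in parts)


def assemble_dataset_features(
    dataset: GaitDataset, feature_config: FeatureConfig, dtype=np.float32
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-sequence feature matrices and integer labels: (N, T, D), (N,)."""
    class_index = {c: i for i, c in enumerate(dataset.class_names)}
    xs, ys = [], []
    for s in dataset.sequences:
        if s.label is None:
            raise StratificationError(
                f"sequence {s.sequence_id!r} is unlabeled; training requires labels"
            )
        xs.append(
            assemble_input(s, dataset.topology, feature_config).values.astype(dtype)
        )
        ys.append(class_index[s.label])
    return np.stack(xs), np.array(ys, dtype=np.int64)


def train(
    dataset: GaitDataset,
    feature_config: FeatureConfig,
    net_config: NetworkConfig,
    opt: OptimizerConfig = OptimizerConfig(),
    tc: TrainingConfig = TrainingConfig(),
    dtype=np.float32,
) -> TrainingHistory:
    """Split, assemble features once per sequence, and train for a fixed
    epoch budget with per-epoch validation metrics.

    No early stopping and no checkpoint selection: the final-epoch model is
    returned with the full history.
    """
    expected_d = feature_dim(dataset.topology, feature_config)
    if net_config.input_dim != expected_d:
        raise ConfigError(
            f"net_config.input_dim {net_config.input_dim} does not match the "
            f"assembled feature width {expected_d} for the active flags"
        )
    if tc.shuffling == "stratified":
        train_ds, val_ds, test_ds = stratified_split(
            dataset, tc.split_fractions, seed=tc.seed
        )
    else:
        train_ds, val_ds, test_ds = _random_split(
            dataset, tc.split_fractions, seed=tc.seed
        )
    for name, split in (("train", train_ds), ("validation", val_ds)):
        counts = split.class_counts()
        missing = [c for c, n in counts.items() if n == 0]
        if missing:
            raise StratificationError(
                f"{name} split received zero samples of classes {missing}"
            )

    x_train, y_train = assemble_dataset_features(train_ds, feature_config, dtype)
    x_val, y_val = assemble_dataset_features(val_ds, feature_config, dtype)
    k = len(dataset.class_names)
    eye = np.eye(k, dtype=dtype)

    model = build_model(net_config, seed=tc.seed, dtype=dtype)
    optimizer = _backend.RMSprop(
        learning_rate=opt.learning_rate, rho=opt.rho,
        momentum=opt.momentum, epsilon=opt.epsilon,
    )

    n = len(x_train)
    records: list[EpochRecord] = []
    for epoch in range(1, tc.epochs + 1):
        rng = np.random.default_rng([tc.seed, epoch])
        order = rng.permutation(n)
        batch_losses, batch_sizes = [], []
        train_preds = np.empty(n, dtype=np.int64)
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            loss, probs = model.loss_and_grad(x_train[idx], eye[y_train[idx]], rng)
            optimizer.step(model)
            batch_losses.append(loss)
            batch_sizes.append(len(idx))
            train_preds[idx] = np.argmax(probs, axis=1)
        train_loss = float(np.average(batch_losses, weights=batch_sizes))
        train_cm = confusion_matrix(train_preds, y_train, k)

        val_probs = model.predict_proba(x_val)
        clipped = np.clip(val_probs[np.arange(len(y_val)), y_val], 1e-12, 1.0)
        val_loss = float(-np.log(clipped).mean())
        val_cm = confusion_matrix(np.argmax(val_probs, axis=1), y_val, k)
        records.append(EpochRecord(
            epoch=epoch,
            train_loss=train_loss,
            val_loss=val_loss,
            train_micro_map=micro_map(train_cm),
            val_micro_map=micro_map(val_cm),
        ))

    manifest = {
        "feature_config": feature_config.to_dict(),
        "network_config": net_config.to_dict(),
        "optimizer_config": opt.to_dict(),
        "training_config": tc.to_dict(),
        "class_names": list(dataset.class_names),
        "topology": dataset.topology.to_dict(),
        "dtype": np.dtype(dtype).name,
        "initializer": "glorot_uniform+zero_output",
    }
    split_ids = {
        "train": [s.sequence_id for s in train_ds.sequences],
        "val": [s.sequence_id for s in val_ds.sequences],
        "test": [s.sequence_id for s in test_ds.sequences],
    }
    return TrainingHistory(
        records=records, model=model, manifest=manifest, split_ids=split_ids
    )


def evaluate_history(
    history: TrainingHistory, split: GaitDataset
) -> EvalReport:
    """Evaluate the trained model on a split using its manifest's feature
    flags (so feature sets cannot be mixed)."""
    fc = FeatureConfig.from_dict(history.manifest["feature_config"])
    return evaluate(history.model, split, fc)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(history: TrainingHistory, run_dir: str | Path) -> None:
    """Write weights.npz + manifest.json + history.csv + split lists."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    np.savez(run_dir / "weights.npz", **history.model.state_arrays())
    (run_dir / "manifest.json").write_text(json.dumps(history.manifest, indent=1))
    (run_dir / "splits.json").write_text(json.dumps(history.split_ids, indent=1))
    rows = history.history_rows()
    if rows:
        import pandas as pd

        pd.DataFrame(rows).to_csv(run_dir / "history.csv", index=False)


def load_model(
    run_dir: str | Path, expected_input_dim: int | None = None
) -> tuple[_backend.SequentialModel, dict]:
    """Rebuild the model from a run directory; guards input width and
    feature flags via the manifest."""
    run_dir = Path(run_dir)
    try:
        manifest = json.loads((run_dir / "manifest.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise VersionError(f"cannot read manifest in {run_dir}: {exc}") from exc
    net_config = NetworkConfig.from_dict(manifest["network_config"])
    if expected_input_dim is not None and expected_input_dim != net_config.input_dim:
        raise VersionError(
            f"model was trained with input_dim {net_config.input_dim}, "
            f"requested {expected_input_dim}"
        )
    dtype = np.dtype(manifest.get("dtype", "float64"))
    model = build_model(net_config, seed=0, dtype=dtype)
    with np.load(run_dir / "weights.npz") as npz:
        state = {k: npz[k] for k in npz.files}
    model.load_state_arrays(state)
    return model, manifest
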