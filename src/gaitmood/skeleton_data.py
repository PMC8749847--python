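"""Skeleton gait data model, CSV/JSON I/O and stratified splitting.

A gait sequence is a ``T x V x C`` coordinate tensor (frames x joints x
axes).  On disk a sequence is a plain CSV (header ``j00_x,j00_y,j00_z,...``,
one row per frame) plus a JSON sidecar ``<stem>.json`` carrying the label,
sequence id, frame rate and topology metadata.  Datasets are described by a
JSON manifest listing member CSV paths.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, FormatError, StratificationError

AXIS_NAMES = ("x", "y", "z")

DEFAULT_JOINT_NAMES = (
    "root",
    "spine",
    "neck",
    "head",
    "left_shoulder",
    "left_elbow",
    "left_hand",
    "right_shoulder",
    "right_elbow",
    "right_hand",
    "left_hip",
    "left_knee",
    "left_foot",
    "right_hip",
    "right_knee",
    "right_foot",
)

DEFAULT_CLASS_NAMES = ("angry", "happy", "sad", "neutral")


@dataclass(frozen=True)
class SkeletonTopology:
    """Joint layout of a skeleton: names, coordinate dimensionality, the
    designated relative (mid-spine) joint and the capture frame rate."""

    joint_names: tuple[str, ...] = DEFAULT_JOINT_NAMES
    n_coords: int = 3
    relative_joint: int = 1
    fps: float = 60.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "joint_names", tuple(self.joint_names))
        if self.n_joints < 2:
            raise ConfigError(f"need at least 2 joints, got {self.n_joints}")
        if self.n_coords not in (2, 3):
            raise ConfigError(f"n_coords must be 2 or 3, got {self.n_coords}")
        if not 0 <= self.relative_joint < self.n_joints:
            raise ConfigError(
                f"relative_joint {self.relative_joint} out of range for "
                f"{self.n_joints} joints"
            )
        if len(set(self.joint_names)) != self.n_joints:
            raise ConfigError("joint_names contains duplicates")
        if self.fps <= 0:
            raise ConfigError(f"fps must be positive, got {self.fps}")

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    @property
    def axes(self) -> tuple[str, ...]:
        return AXIS_NAMES[: self.n_coords]

    def column_names(self) -> list[str]:
        """CSV header columns: zero-padded joint index + axis suffix."""
        return [
            f"j{v:02d}_{ax}" for v in range(self.n_joints) for ax in self.axes
        ]

    def to_dict(self) -> dict:
        return {
            "joint_names": list(self.joint_names),
            "n_coords": self.n_coords,
            "relative_joint": self.relative_joint,
            "fps": self.fps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SkeletonTopology":
        return cls(
            joint_names=tuple(d["joint_names"]),
            n_coords=int(d["n_coords"]),
            relative_joint=int(d["relative_joint"]),
            fps=float(d["fps"]),
        )


@dataclass
class GaitSequence:
    """One gait recording: coordinates, optional emotion label, identifier."""

    coords: np.ndarray  # (T, V, C)
    label: str | None = None
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3:
            raise ContractError(
                f"coords must be T x V x C, got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ContractError("sequence must have at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ContractError(
                f"sequence {self.sequence_id!r} contains non-finite coordinates"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_joints(self) -> int:
        return self.coords.shape[1]

    @property
    def n_coords(self) -> int:
        return self.coords.shape[2]


@dataclass
class GaitDataset:
    """A labeled collection of uniform-length gait sequences."""

    topology: SkeletonTopology
    sequences: list[GaitSequence] = field(default_factory=list)
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self) -> None:
        self.class_names = tuple(self.class_names)
        lengths = {s.n_frames for s in self.sequences}
        if len(lengths) > 1:
            raise ContractError(
                f"ragged dataset: sequence lengths {sorted(lengths)}; "
                "all sequences must share one T"
            )
        for s in self.sequences:
            if s.n_joints != self.topology.n_joints or s.n_coords != self.topology.n_coords:
                raise ContractError(
                    f"sequence {s.sequence_id!r} shape ({s.n_joints} joints, "
                    f"{s.n_coords} coords) does not match topology "
                    f"({self.topology.n_joints}, {self.topology.n_coords})"
                )
            if s.label is not None and s.label not in self.class_names:
                raise ContractError(
                    f"sequence {s.sequence_id!r} label {s.label!r} not in "
                    f"class_names {self.class_names}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_frames(self) -> int:
        if not self.sequences:
            raise ContractError("empty dataset has no frame count")
        return self.sequences[0].n_frames

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_names}
        for s in self.sequences:
            if s.label is not None:
                counts[s.label] += 1
        return counts

    def subset(self, indices: Sequence[int]) -> "GaitDataset":
        return GaitDataset(
            topology=self.topology,
            sequences=[self.sequences[i] for i in indices],
            class_names=self.class_names,
        )


# ---------------------------------------------------------------------------
# CSV + sidecar I/O
# ---------------------------------------------------------------------------


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def read_gait_csv(path: str | Path, topology: SkeletonTopology) -> GaitSequence:
    """Read one gait sequence from CSV, merging the JSON sidecar if present.

    Raises :class:`FormatError` naming the offending column or row when the
    header does not match the topology or a cell is not numeric.
    """
    path = Path(path)
    expected = topology.column_names()
    try:
        df = pd.read_csv(path, header=0, dtype=str)
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    got = list(df.columns)
    missing = [c for c in expected if c not in got]
    extra = [c for c in got if c not in expected]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing columns {missing}")
        if extra:
            parts.append(f"unexpected columns {extra}")
        raise FormatError(f"{path}: " + "; ".join(parts))
    raw = df[expected].to_numpy()
    try:
        values = raw.astype(np.float64)
    except ValueError:
        for t in range(raw.shape[0]):
            for j, col in enumerate(expected):
                try:
                    float(raw[t, j])
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric value {raw[t, j]!r} in column "
                        f"{col!r}, data row {t}"
                    ) from None
        raise  # pragma: no cover - unreachable
    coords = values.reshape(len(df), topology.n_joints, topology.n_coords)

    label: str | None = None
    sequence_id = path.stem
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("label")
        sequence_id = meta.get("sequence_id", sequence_id)
    return GaitSequence(coords=coords, label=label, sequence_id=sequence_id)


def write_gait_csv(
    seq: GaitSequence, path: str | Path, topology: SkeletonTopology
) -> None:
    """Write a gait sequence as CSV plus a JSON sidecar with its metadata."""
    path = Path(path)
    if seq.n_joints != topology.n_joints or seq.n_coords != topology.n_coords:
        raise ContractError("sequence shape does not match topology")
    flat = flatten_frames(seq)
    df = pd.DataFrame(flat, columns=topology.column_names())
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "label": seq.label,
        "sequence_id": seq.sequence_id,
        "fps": topology.fps,
        "joint_names": list(topology.joint_names),
        "relative_joint": topology.relative_joint,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def write_dataset(dataset: GaitDataset, out_dir: str | Path) -> Path:
    """Write every sequence as CSV+sidecar and a ``manifest.json`` index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, seq in enumerate(dataset.sequences):
        name = seq.sequence_id or f"seq{i:05d}"
        csv_path = out_dir / f"{name}.csv"
        write_gait_csv(seq, csv_path, dataset.topology)
        files.append(csv_path.name)
    manifest = {
        "topology": dataset.topology.to_dict(),
        "class_names": list(dataset.class_names),
        "sequences": files,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def load_dataset(manifest_path: str | Path) -> GaitDataset:
    """Load a dataset from its manifest; validates uniform sequence length."""
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read manifest {manifest_path}: {exc}") from exc
    topology = SkeletonTopology.from_dict(manifest["topology"])
    base = manifest_path.parent
    sequences = [read_gait_csv(base / f, topology) for f in manifest["sequences"]]
    return GaitDataset(
        topology=topology,
        sequences=sequences,
        class_names=tuple(manifest["class_names"]),
    )


# ---------------------------------------------------------------------------
# Frame flattening
# ---------------------------------------------------------------------------


def flatten_frames(seq: GaitSequence) -> np.ndarray:
    """Return the ``T x (V*C)`` matrix: joints in topology order, axes
    fastest-varying.  Inverse of :func:`unflatten_frames`."""
    t, v, c = seq.coords.shape
    return seq.coords.reshape(t, v * c)


def unflatten_frames(matrix: np.ndarray, topology: SkeletonTopology) -> np.ndarray:
    """Invert :func:`flatten_frames` back to a ``T x V x C`` tensor."""
    matrix = np.asarray(matrix)
    t, d = matrix.shape
    v, c = topology.n_joints, topology.n_coords
    if d != v * c:
        raise ContractError(f"width {d} does not factor as {v} joints x {c} axes")
    return matrix.reshape(t, v, c)


def center_on_relative_joint(
    seq: GaitSequence, topology: SkeletonTopology
) -> GaitSequence:
    """Optional utility: subtract the relative joint per frame (off by
    default everywhere; raw coordinates are the canonical input)."""
    centered = seq.coords - seq.coords[:, [topology.relative_joint], :]
    return replace(seq, coords=centered)


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

# remainder ties resolved in favor of test, then validation, then train
_SPLIT_PRIORITY = (2, 1, 0)


def largest_remainder_allocation(n: int, fractions: Sequence[float]) -> list[int]:
    """Allocate ``n`` items to splits by largest-remainder rounding.

    Leftover units go to the splits with the largest fractional remainders;
    ties favor the test split, then validation, then train.
    """
    exact = [n * f for f in fractions]
    base = [math.floor(e) for e in exact]
    leftover = n - sum(base)
    order = sorted(
        range(len(fractions)),
        key=lambda i: (-(exact[i] - base[i]), _SPLIT_PRIORITY.index(i)),
    )
    for i in order[:leftover]:
        base[i] += 1
    return base


def stratified_split(
    dataset: GaitDataset,
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[GaitDataset, GaitDataset, GaitDataset]:
    """Per-class shuffled split into (train, val, test) by largest-remainder
    allocation of ``class_count x fraction``.

    The three splits partition the dataset; per-class realized counts deviate
    from ``fraction x class_count`` by less than one sample.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3:
        raise ConfigError(f"need exactly 3 fractions, got {len(fractions)}")
    if any(f <= 0 for f in fractions):
        raise ConfigError(f"fractions must be positive, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got sum {sum(fractions)!r}")

    by_class: dict[str, list[int]] = {c: [] for c in dataset.class_names}
    for i, s in enumerate(dataset.sequences):
        if s.label is None:
            raise StratificationError(
                f"sequence {s.sequence_id!r} is unlabeled; stratified split "
                "requires labels"
            )
        by_class[s.label].append(i)
    empty = [c for c, idx in by_class.items() if not idx]
    if empty:
        raise StratificationError(f"classes with zero samples: {empty}")

    rng = np.random.default_rng(seed)
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for c in dataset.class_names:
        idx = np.array(by_class[c])
        rng.shuffle(idx)
        counts = largest_remainder_allocation(len(idx), fractions)
        start = 0
        for k, n_k in enumerate(counts):
            parts[k].extend(idx[start : start + n_k].tolist())
            start += n_k
    return tuple(dataset.subset(sorted(p)) for p in parts)  # type: ignore[return-value]
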