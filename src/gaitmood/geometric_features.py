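"""Handcrafted geometric gait features.

Two per-frame feature families are computed relative to the skeleton's
designated mid-spine joint S:

* joint relative angles (JRA) — the angle at S between the vectors to two
  other joints; C(V-1, 2) values per frame, each in [0, pi];
* joint relative distances (JRD) — Euclidean distance between a joint pair;
  C(V, 2) values per frame, non-negative.

``assemble_input`` concatenates flattened raw coordinates with the enabled
feature blocks into the network input of width (V*C) + F.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, GeometryError
from .skeleton_data import GaitSequence, SkeletonTopology, flatten_frames


@dataclass(frozen=True)
class FeatureConfig:
    """Which handcrafted feature blocks to append to the raw coordinates."""

    use_jra: bool = True
    use_jrd: bool = True
    relative_joint: int | None = None  # None -> take it from the topology

    def resolve_relative_joint(self, topology: SkeletonTopology) -> int:
        s = self.relative_joint if self.relative_joint is not None else topology.relative_joint
        if not 0 <= s < topology.n_joints:
            raise ContractError(
                f"relative_joint {s} out of range for {topology.n_joints} joints"
            )
        return s

    def to_dict(self) -> dict:
        return {
            "use_jra": self.use_jra,
            "use_jrd": self.use_jrd,
            "relative_joint": self.relative_joint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            use_jra=bool(d.get("use_jra", True)),
            use_jrd=bool(d.get("use_jrd", True)),
            relative_joint=d.get("relative_joint"),
        )


@dataclass
class FeatureMatrix:
    """Assembled per-frame network input with column provenance."""

    values: np.ndarray  # (T, D)
    column_labels: list[str]
    n_degenerate: int = 0  # JRA evaluations with a zero-length vector

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ContractError(f"values must be 2-D, got shape {self.values.shape}")
        if self.values.shape[1] != len(self.column_labels):
            raise ContractError(
                f"{self.values.shape[1]} columns vs {len(self.column_labels)} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ContractError("feature matrix contains non-finite values")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, columns=self.column_labels).to_csv(
            path, index=False, float_format="%.17g"
        )


def feature_dim(topology: SkeletonTopology, config: FeatureConfig) -> int:
    """Closed-form assembled input width (V*C) + F."""
    v, c = topology.n_joints, topology.n_coords
    d = v * c
    if config.use_jra:
        d += comb(v - 1, 2)
    if config.use_jrd:
        d += comb(v, 2)
    return d


def joint_relative_angle(
    frame: np.ndarray, relative_joint: int, a: int, b: int
) -> float:
    """Angle at the relative joint S between vectors S->a and S->b, in
    radians in [0, pi].  Degenerate geometry (a joint coincident with S)
    yields 0 by convention."""
    if a == b:
        raise ContractError("joint indices a and b must differ")
    if relative_joint in (a, b):
        raise ContractError("a and b must differ from the relative joint")
    frame = np.asarray(frame, dtype=np.float64)
    va = frame[a] - frame[relative_joint]
    vb = frame[b] - frame[relative_joint]
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    cos = float(np.dot(va, vb) / (na * nb))
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def jra_pairs(topology: SkeletonTopology, relative_joint: int) -> list[tuple[int, int]]:
    """Unordered pairs of non-relative joints, lexicographic order."""
    others = [v for v in range(topology.n_joints) if v != relative_joint]
    return list(combinations(others, 2))


def jrd_pairs(topology: SkeletonTopology) -> list[tuple[int, int]]:
    """All unordered joint pairs, lexicographic order."""
    return list(combinations(range(topology.n_joints), 2))


def jra_features(
    seq: GaitSequence,
    topology: SkeletonTopology,
    relative_joint: int | None = None,
    return_degenerate_count: bool = False,
):
    """Per-frame joint relative angles: ``T x C(V-1, 2)`` matrix.

    Vectorized over frames and pairs; zero-length vectors give angle 0 and
    are tallied in the optional degenerate count.
    """
    if topology.n_joints < 3:
        raise GeometryError("JRA needs at least 3 joints")
    s = topology.relative_joint if relative_joint is None else relative_joint
    pairs = jra_pairs(topology, s)
    vec = seq.coords - seq.coords[:, [s], :]  # (T, V, C)
    others = [v for v in range(topology.n_joints) if v != s]
    vec = vec[:, others, :]  # (T, V-1, C)
    norms = np.linalg.norm(vec, axis=2)  # (T, V-1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = vec / safe[:, :, None]
    gram = np.einsum("tic,tjc->tij", unit, unit)  # (T, V-1, V-1)
    # map pair (a, b) in original joint indices to positions within `others`
    pos = {v: i for i, v in enumerate(others)}
    ia = np.array([pos[a] for a, _ in pairs])
    ib = np.array([pos[b] for _, b in pairs])
    cos = np.clip(gram[:, ia, ib], -1.0, 1.0)
    angles = np.arccos(cos)
    degenerate = (norms[:, ia] == 0) | (norms[:, ib] == 0)
    angles[degenerate] = 0.0
    n_degenerate = int(degenerate.sum())
    if return_degenerate_count:
        return angles, n_degenerate
    return angles


def joint_relative_distance(frame: np.ndarray, a: int, b: int) -> float:
    """Euclidean distance between joints ``a`` and ``b`` in one frame."""
    if a == b:
        raise ContractError("joint indices a and b must differ")
    frame = np.asarray(frame, dtype=np.float64)
    return float(np.linalg.norm(frame[b] - frame[a]))


def jrd_features(seq: GaitSequence, topology: SkeletonTopology) -> np.ndarray:
    """Per-frame joint relative distances: ``T x C(V, 2)`` matrix."""
    if topology.n_joints < 2:
        raise GeometryError("JRD needs at least 2 joints")
    pairs = jrd_pairs(topology)
    ia = np.array([a for a, _ in pairs])
    ib = np.array([b for _, b in pairs])
    diff = seq.coords[:, ib, :] - seq.coords[:, ia, :]
    return np.linalg.norm(diff, axis=2)


def assemble_input(
    seq: GaitSequence, topology: SkeletonTopology, config: FeatureConfig
) -> FeatureMatrix:
    """Concatenate per frame: flattened raw coordinates, then JRA columns
    (if enabled), then JRD columns (if enabled)."""
    blocks = [flatten_frames(seq)]
    labels = [
        f"raw_j{v:02d}_{ax}"
        for v in range(topology.n_joints)
        for ax in topology.axes
    ]
    n_degenerate = 0
    s = config.resolve_relative_joint(topology)
    if config.use_jra:
        angles, n_degenerate = jra_features(
            seq, topology, relative_joint=s, return_degenerate_count=True
        )
        blocks.append(angles)
        labels.extend(f"jra_j{a:02d}_j{b:02d}" for a, b in jra_pairs(topology, s))
    if config.use_jrd:
        blocks.append(jrd_features(seq, topology))
        labels.extend(f"jrd_j{a:02d}_j{b:02d}" for a, b in jrd_pairs(topology))
    return FeatureMatrix(
        values=np.concatenate(blocks, axis=1),
        column_labels=labels,
        n_degenerate=n_degenerate,
    )


def jrta_features(*args, **kwargs):
    """Joint relative triangle areas — recognized extension point, not
    implemented (evaluated and rejected upstream; formula not available)."""
    raise NotImplementedError("JRTA is a named extension point, not implemented")


def jrcd_features(*args, **kwargs):
    """Joint relative cosine dissimilarities — recognized extension point,
    not implemented (evaluated and rejected upstream)."""
    raise NotImplementedError("JRCD is a named extension point, not implemented")
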