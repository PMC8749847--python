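"""Evaluation metrics: confusion counts, per-class average precision,
micro- and macro-averaged mean average precision.

Micro-mAP pools true/false positives over classes,
(sum_i TP_i) / (sum_i TP_i + sum_i FP_i); for single-label prediction this
equals trace(confusion)/n.  Macro-mAP is the unweighted mean of per-class
average precision.  Because the per-class "AP" can be read either as ranked
average precision or as confusion-matrix precision, both are computed:
``class_ap`` (ranked, the headline value) and ``class_precision``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ContractError, UndefinedMetricError
from .geometric_features import FeatureConfig, assemble_input
from .model_core import forward as model_forward
from .skeleton_data import GaitDataset


@dataclass
class EvalReport:
    class_names: tuple[str, ...]
    confusion: np.ndarray  # rows = true, cols = predicted
    class_ap: dict[str, float | None]
    class_precision: dict[str, float | None]
    micro_map: float
    macro_map: float
    n_samples: int
    headline_ap: str = "ranked"  # which reading of "class AP" class_ap uses

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "class_ap": self.class_ap,
            "class_precision": self.class_precision,
            "micro_map": self.micro_map,
            "macro_map": self.macro_map,
            "n_samples": self.n_samples,
            "headline_ap": self.headline_ap,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def confusion_matrix(
    predictions: Sequence[int], truths: Sequence[int], n_classes: int
) -> np.ndarray:
    """Integer matrix with entry (i, j) = samples of true class i predicted
    as class j."""
    predictions = np.asarray(predictions, dtype=np.int64)
    truths = np.asarray(truths, dtype=np.int64)
    if predictions.shape != truths.shape:
        raise ContractError(
            f"{len(predictions)} predictions vs {len(truths)} truths"
        )
    for name, arr in (("prediction", predictions), ("truth", truths)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ContractError(f"{name} label outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (truths, predictions), 1)
    return cm


def micro_map(confusion: np.ndarray) -> float:
    """Pooled precision (sum TP) / (sum TP + sum FP); TP_i is the diagonal
    entry, FP_i the off-diagonal column sum."""
    confusion = np.asarray(confusion)
    n = int(confusion.sum())
    if n == 0:
        raise UndefinedMetricError("micro-mAP undefined for zero samples")
    tp = np.diag(confusion).sum()
    fp = confusion.sum(axis=0).sum() - tp  # column sums minus diagonals
    return float(tp / (tp + fp))


def macro_map(class_ap: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-class average precision values."""
    values = [v for v in class_ap if v is not None]
    if not values:
        raise UndefinedMetricError("macro-mAP undefined with no class values")
    return float(np.mean(values))


def class_average_precision(
    scores: Sequence[float], truths: Sequence[bool]
) -> float:
    """Ranked average precision for one class: sort samples by descending
    score (stable, so ties keep input order) and average precision@k over
    the positive ranks k."""
    scores = np.asarray(scores, dtype=np.float64)
    truths = np.asarray(truths, dtype=bool)
    if scores.shape != truths.shape:
        raise ContractError("scores and truths must have equal length")
    if not truths.any():
        raise UndefinedMetricError("AP undefined for a class with no positives")
    order = np.argsort(-scores, kind="stable")
    rel = truths[order]
    ranks = np.arange(1, len(rel) + 1)
    cum_pos = np.cumsum(rel)
    precision_at_k = cum_pos / ranks
    return float(precision_at_k[rel].mean())


def evaluate(
    model, dataset: GaitDataset, feature_config: FeatureConfig
) -> EvalReport:
    """Assemble features for every labeled sequence, run the model and fill
    an :class:`EvalReport`.

    Classes with no positive samples in the split get ``None`` AP and are
    excluded from the macro mean with a warning.
    """
    labeled = [s for s in dataset.sequences if s.label is not None]
    if not labeled:
        raise UndefinedMetricError("no labeled sequences to evaluate")
    class_names = dataset.class_names
    class_index = {c: i for i, c in enumerate(class_names)}
    x = np.stack([
        assemble_input(s, dataset.topology, feature_config).values for s in labeled
    ])
    if x.shape[2] != model.input_dim:
        raise ContractError(
            f"feature width {x.shape[2]} does not match model input_dim "
            f"{model.input_dim}; check feature flags against the run manifest"
        )
    probs = model_forward(model, x)
    preds = np.argmax(probs, axis=1)
    truths = np.array([class_index[s.label] for s in labeled])
    cm = confusion_matrix(preds, truths, len(class_names))

    class_ap: dict[str, float | None] = {}
    class_precision: dict[str, float | None] = {}
    for i, c in enumerate(class_names):
        positives = truths == i
        if not positives.any():
            warnings.warn(
                f"class {c!r} has no positive samples; excluded from macro-mAP",
                stacklevel=2,
            )
            class_ap[c] = None
            class_precision[c] = None
            continue
        class_ap[c] = class_average_precision(probs[:, i], positives)
        predicted_i = int(cm[:, i].sum())
        class_precision[c] = (
            float(cm[i, i] / predicted_i) if predicted_i else None
        )
    return EvalReport(
        class_names=class_names,
        confusion=cm,
        class_ap=class_ap,
        class_precision=class_precision,
        micro_map=micro_map(cm),
        macro_map=macro_map(list(class_ap.values())),
        n_samples=len(labeled),
    )
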