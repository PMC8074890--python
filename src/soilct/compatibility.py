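"""Cross-model compatibility: RMSE matrix and greedy representative selection.

Every trained model is applied to every sample's surrogate dataset,
producing an n_models x n_samples RMSE matrix. A model is compatible
with a sample when its RMSE is strictly below a threshold (default
0.04). Representatives are then chosen greedily: pick the model covering
the most remaining samples, remove those samples, repeat. The output is
a summary table of (model, number of similar datasets) plus any samples
no model covers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surrogate import evaluate_rmse

DEFAULT_THRESHOLD = 0.04

__all__ = ["RMSEMatrix", "CompatibilityReport", "rmse_matrix",
           "select_representatives", "DEFAULT_THRESHOLD"]


@dataclass
class RMSEMatrix:
    """Complete matrix of evaluate_rmse(model_i, dataset_j)."""

    values: np.ndarray                 # (n_models, n_samples), all >= 0
    model_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("matrix must be 2D")
        if self.values.shape != (len(self.model_ids), len(self.sample_ids)):
            raise ValueError("matrix shape must match id lists")
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise ValueError("entries must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.model_ids,
                            columns=self.sample_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="model")


@dataclass
class CompatibilityReport:
    """Greedy selection rounds plus the samples nothing covered."""

    rounds: list[tuple[str, frozenset[str]]]   # (model id, covered sample ids)
    uncovered: frozenset[str]
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        seen: set[str] = set()
        for _, covered in self.rounds:
            if seen & covered:
                raise ValueError("covered sets must be disjoint across rounds")
            seen |= covered

    def summary(self) -> pd.DataFrame:
        rows = [{"model": model, "n_similar_datasets": len(covered)}
                for model, covered in self.rounds]
        return pd.DataFrame(rows, columns=["model", "n_similar_datasets"])

    def to_text(self) -> str:
        lines = [f"RMSE(model(data index)) < {self.threshold}",
                 f"{'model (sample)':<24}number of similar datasets"]
        for model, covered in self.rounds:
            lines.append(f"{model:<24}{len(covered)}")
        if self.uncovered:
            lines.append(f"uncovered samples: {', '.join(sorted(self.uncovered))}")
        return "\n".join(lines)


def rmse_matrix(models: dict, sample_datasets: dict) -> RMSEMatrix:
    """Apply each model to each sample's full surrogate dataset.

    `models` maps model id -> object with a ``predict(images)`` method
    (usually a trained RegressionModel); `sample_datasets` maps sample
    id -> TrainingDataset.
    """
    model_ids = list(models)
    sample_ids = list(sample_datasets)
    if not model_ids or not sample_ids:
        raise ValueError("need at least one model and one sample")
    values = np.empty((len(model_ids), len(sample_ids)))
    for i, mid in enumerate(model_ids):
        for j, sid in enumerate(sample_ids):
            values[i, j] = evaluate_rmse(models[mid], sample_datasets[sid])
    return RMSEMatrix(values, model_ids, sample_ids)


def select_representatives(matrix: RMSEMatrix,
                           threshold: float = DEFAULT_THRESHOLD,
                           include_self: bool = True) -> CompatibilityReport:
    """Iteratively pick the model compatible with the most remaining samples.

    Compatibility is strict: RMSE < threshold. Ties are broken by lowest
    mean RMSE over the would-be covered set, then by model id. With
    ``include_self=False`` a model's own sample (matching id) never
    counts toward its coverage. Stops when no remaining sample is
    covered by any model; those samples are reported as uncovered.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if matrix.values.size == 0:
        raise ValueError("empty matrix")

    compatible = matrix.values < threshold
    if not include_self:
        for i, mid in enumerate(matrix.model_ids):
            for j, sid in enumerate(matrix.sample_ids):
                if mid == sid:
                    compatible[i, j] = False

    remaining = set(range(len(matrix.sample_ids)))
    rounds: list[tuple[str, frozenset[str]]] = []
    while remaining:
        best = None  # (coverage, -mean_rmse handled separately)
        for i, mid in enumerate(matrix.model_ids):
            covered = {j for j in remaining if compatible[i, j]}
            if not covered:
                continue
            mean_rmse = float(np.mean([matrix.values[i, j] for j in covered]))
            key = (-len(covered), mean_rmse, mid)
            if best is None or key < best[0]:
                best = (key, i, covered)
        if best is None:
            break
        _, i, covered = best
        rounds.append((matrix.model_ids[i],
                       frozenset(matrix.sample_ids[j] for j in covered)))
        remaining -= covered

    uncovered = frozenset(matrix.sample_ids[j] for j in remaining)
    return CompatibilityReport(rounds, uncovered, threshold=threshold)
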