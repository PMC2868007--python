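"""Evaluation baselines for binary contexts.

Two deterministic references frame any encoder comparison:

* the minimum accepted value (MAV) — the accuracy obtained by assigning
  every sequence to the dataset's biggest class, the floor any useful
  classifier must beat;
* leave-one-out nearest-neighbour accuracy — each instance is classified
  by its nearest neighbour among the remaining ones, repeated over all n
  instances. Leave-one-out yields identical results regardless of run
  count, unlike hold-out or cross-validation splits.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .context import BinaryContext

__all__ = ["EvalReport", "mav", "loo_nn"]


@dataclass(frozen=True)
class EvalReport:
    """Accuracy summary of a leave-one-out run."""

    accuracy: float  # percentage in [0, 100]
    correct: int
    total: int
    per_class: dict[str, tuple[int, int]]  # label -> (correct, total)

    def to_tsv(self) -> str:
        lines = ["class\tcorrect\ttotal"]
        lines += [f"{c}\t{k}\t{n}" for c, (k, n) in sorted(self.per_class.items())]
        lines.append(f"ALL\t{self.correct}\t{self.total}")
        return "\n".join(lines) + "\n"


def mav(labels) -> float:
    """Minimum accepted value: biggest class share as a percentage.

    Truncated (not rounded) to one decimal, matching how such floors are
    conventionally printed: 335/717 -> 46.7.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    biggest = max(Counter(labels).values())
    return math.floor(1000.0 * biggest / len(labels)) / 10.0


def _distances(x: np.ndarray, metric: str) -> np.ndarray:
    n = x.shape[0]
    xi = x.astype(np.int32)
    if metric == "hamming":
        # pairwise count of differing bits
        return np.abs(xi[:, None, :] - xi[None, :, :]).sum(axis=2)
    if metric == "jaccard":
        inter = xi @ xi.T
        row = xi.sum(axis=1)
        union = row[:, None] + row[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - inter / union
        d[union == 0] = 0.0  # two all-zero rows are identical
        return d
    raise ValueError(f"unknown metric {metric!r}")


def loo_nn(c: BinaryContext, metric: str = "hamming") -> EvalReport:
    """Leave-one-out 1-nearest-neighbour accuracy on a binary context.

    For every instance the label of the closest other instance is
    predicted; distance ties are broken toward the earlier instance in
    input order, so repeated runs give identical reports.
    """
    n = c.matrix.shape[0]
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 instances")
    if len(set(c.labels)) < 2:
        raise ValueError("leave-one-out needs at least 2 classes")
    if not c.matrix.any():
        warnings.warn("context has no 1 entries; distances are degenerate")

    dist = _distances(c.matrix, metric).astype(float)
    np.fill_diagonal(dist, np.inf)
    neighbour = dist.argmin(axis=1)  # argmin takes the first minimum: earliest index

    correct = 0
    per_class: dict[str, list[int]] = {}
    for i in range(n):
        truth = c.labels[i]
        pred = c.labels[neighbour[i]]
        stats = per_class.setdefault(truth, [0, 0])
        stats[1] += 1
        if pred == truth:
            stats[0] += 1
            correct += 1
    return EvalReport(
        accuracy=100.0 * correct / n,
        correct=correct,
        total=n,
        per_class={k: (v[0], v[1]) for k, v in per_class.items()},
    )
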