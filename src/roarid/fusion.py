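"""Sum-rule score fusion and exhaustive 2-/3-member ensemble search.

Member scores are softmax posteriors (a deliberate choice: posteriors
put members on a common scale, making fusion backbone-agnostic), summed
elementwise and renormalised per row.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .classify import ScoreMatrix
from .errors import AlignmentError
from .evaluation import accuracy_fraction, eer_from_binary_scores

__all__ = ["EnsembleSpec", "sum_rule", "search_ensembles"]


@dataclass(frozen=True)
class EnsembleSpec:
    """An ensemble of 2 or 3 distinct members fused by sum rule."""

    members: tuple
    rule: str = "sum"

    def __post_init__(self) -> None:
        if len(self.members) not in (2, 3):
            raise ValueError("ensembles have 2 or 3 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError("ensemble members must be distinct")


def sum_rule(matrices: list[ScoreMatrix]) -> ScoreMatrix:
    """Elementwise sum of aligned score matrices, rows renormalised to 1."""
    if not matrices:
        raise ValueError("need at least one score matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.sample_ids != first.sample_ids:
            raise AlignmentError("score matrices disagree on sample ids/order")
        if m.class_labels != first.class_labels:
            raise AlignmentError("score matrices disagree on class labels")
    total = np.sum([m.values for m in matrices], axis=0)
    total = total / total.sum(axis=1, keepdims=True)
    return ScoreMatrix(total, list(first.sample_ids), list(first.class_labels),
                       first.true_labels)


def _score(matrix: ScoreMatrix, metric: str, eer_target: str | None) -> float:
    if matrix.true_labels is None:
        raise ValueError("metric evaluation needs true_labels on the matrices")
    if metric == "accuracy":
        return accuracy_fraction(matrix, matrix.true_labels)
    if metric == "eer":
        target = eer_target or matrix.class_labels[0]
        return eer_from_binary_scores(matrix, target).eer_percent
    raise ValueError(f"unknown metric {metric!r}")


def search_ensembles(score_store: dict, k: int, metric: str = "accuracy",
                     eer_target: str | None = None,
                     ) -> list[tuple[EnsembleSpec, float]]:
    """Exhaustively rank all C(m, k) sum-rule ensembles.

    ``score_store`` maps a member key (e.g. a (backbone, representation,
    scaling) triple or a plain name) to that member's pooled ScoreMatrix
    (or list of per-fold matrices, concatenated here).  Ranking is
    descending for accuracy, ascending for EER; ties break on the
    lexicographic member names, so reruns are deterministic.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    if len(score_store) < k:
        raise ValueError(f"need at least {k} members, got {len(score_store)}")
    pooled: dict = {}
    for key, val in score_store.items():
        if isinstance(val, list):
            ids = [sid for m in val for sid in m.sample_ids]
            vals = np.vstack([m.values for m in val])
            true = None
            if all(m.true_labels is not None for m in val):
                true = [t for m in val for t in m.true_labels]
            val = ScoreMatrix(vals, ids, list(val[0].class_labels), true)
        pooled[key] = val

    results = []
    for combo in combinations(sorted(pooled, key=str), k):
        fused = sum_rule([pooled[key] for key in combo])
        results.append((EnsembleSpec(tuple(combo)), _score(fused, metric, eer_target)))
    reverse = metric == "accuracy"
    results.sort(key=lambda r: ((-r[1] if reverse else r[1]),
                                tuple(str(m) for m in r[0].members)))
    return results
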