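"""Consensus prediction: strict intersection of the three model calls.

Each accepted model scores every candidate pair and thresholds at its
own operating point; a pair is a consensus interaction only when all
models call it positive, and pairs already reported as interacting are
excluded from the final novel set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .pairs import Pair

log = logging.getLogger("autoppi")


def predict_positives(model, table: pd.DataFrame, feature_cols: list[str],
                      threshold: float) -> tuple[set[Pair], dict[Pair, float]]:
    """Score a featurized candidate table; keep pairs with score >= threshold.

    Returns the positive pair set and the per-pair scores (all pairs,
    for reporting).  Raises if the table lacks the feature columns or a
    pair's features could not be assembled (row of all-NaN identifiers).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    missing = [c for c in ("protein_a", "protein_b", *feature_cols) if c not in table.columns]
    if missing:
        raise ValueError(f"candidate table lacks columns: {missing}")
    X = table[feature_cols].to_numpy(dtype=float)
    scores = model.predict_proba(X)[:, 1]
    pair_scores: dict[Pair, float] = {}
    positives: set[Pair] = set()
    for (a, b), s in zip(table[["protein_a", "protein_b"]].itertuples(index=False),
                         scores):
        pair = (a, b)
        pair_scores[pair] = float(s)
        if s >= threshold:
            positives.add(pair)
    return positives, pair_scores


@dataclass
class ConsensusResult:
    per_model: dict[str, set[Pair]]
    intersection: set[Pair]
    venn: dict[str, int] = field(default_factory=dict)
    excluded_known: int = 0

    def counts(self) -> dict:
        out = {f"{name}_positives": len(s) for name, s in self.per_model.items()}
        out["consensus"] = len(self.intersection)
        out["excluded_known"] = self.excluded_known
        return out


def venn_counts(sets: dict[str, set[Pair]]) -> dict[str, int]:
    """Exclusive region counts for 2 or 3 sets, keyed by membership pattern.

    Keys are '+'-joined sorted model names, e.g. ``"NB"``, ``"DT+NB"``,
    ``"DT+KNN+NB"``; each pair is counted in exactly one region, so the
    region counts sum to the size of the union.
    """
    names = sorted(sets)
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            regions["+".join(combo)] = len(inside - outside)
    return regions


def intersect_predictions(sets: dict[str, set[Pair]]) -> ConsensusResult:
    """Strict intersection of per-model positive sets with Venn breakdown."""
    if len(sets) < 2:
        raise ValueError("need at least 2 prediction sets to intersect")
    intersection = set.intersection(*sets.values())
    result = ConsensusResult(per_model={k: set(v) for k, v in sets.items()},
                             intersection=intersection,
                             venn=venn_counts(sets))
    log.info("intersect_predictions: %s -> consensus %d",
             {k: len(v) for k, v in sets.items()}, len(intersection))
    return result


def exclude_known(predictions: set[Pair], known: set[Pair]) -> tuple[set[Pair], int]:
    """Remove already-reported interactions; returns (novel set, removed count)."""
    novel = predictions - known
    removed = len(predictions) - len(novel)
    log.info("exclude_known: removed %d already-known pairs, %d novel remain",
             removed, len(novel))
    return novel, removed


def recovery_metrics(predicted: set[Pair], truth: set[Pair],
                     candidates: set[Pair] | None = None) -> dict[str, float]:
    """Precision/recall of a predicted set against planted interactions.

    Recall is taken over the recoverable truth (truth restricted to the
    candidate pool when one is given).
    """
    recoverable = truth & candidates if candidates is not None else truth
    tp = len(predicted & recoverable)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(recoverable) if recoverable else float("nan")
    return {"precision": precision, "recall": recall,
            "n_predicted": len(predicted), "n_recoverable": len(recoverable)}
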