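"""Consensus-weight optimisation by randomised simplex search with CV.

The four consensus weights live on the probability simplex.  Optimisation
draws ``n_draws`` weight vectors uniformly from the simplex (normalised
i.i.d. exponential variates, i.e. Dirichlet(1,1,1,1)) and keeps the draw
that maximises the number of training spectra whose correct candidate is
ranked top 1 (ties broken by the top-3 count, then first seen).

Cross-validation assigns spectra to folds at random under a seed, fits
weights on each fold's complement — optionally restricted to a subset of
scoring terms, the excluded terms pinned to weight 0 — and pools the
held-out top-k counts.  Setting ``k_folds`` to the number of instances
gives leave-one-out behaviour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import SCORE_NAMES, Weights, average_ranks

__all__ = [
    "TrainingInstance",
    "CVReport",
    "sample_simplex",
    "rank_of_correct",
    "top_counts",
    "optimize_weights",
    "cross_validate",
    "cv_table",
]

TOP_KS = (1, 3, 5, 10)


@dataclass
class TrainingInstance:
    """One spectrum pair's scored candidate list with the truth marked.

    ``scores`` holds the max-normalised score matrix (n_candidates x 4,
    columns in :data:`~hdxrank.scoring.SCORE_NAMES` order).
    """

    scores: np.ndarray
    correct_index: int
    identifier: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(SCORE_NAMES):
            raise ValueError("scores must be (n_candidates, 4)")
        if not (0 <= self.correct_index < self.scores.shape[0]):
            raise ValueError("correct candidate missing from list")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


def sample_simplex(n: int, k: int = 4,
                   seed: int | np.random.Generator | None = None,
                   ) -> np.ndarray:
    """``n`` weight vectors drawn uniformly from the (k-1)-simplex."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    e = rng.exponential(size=(n, k))
    return e / e.sum(axis=1, keepdims=True)


def rank_of_correct(instance: TrainingInstance, w: np.ndarray) -> float:
    """Average-tie rank of the correct candidate under weight vector w."""
    consensus = instance.scores @ w
    return float(average_ranks(consensus)[instance.correct_index])


def top_counts(instances: Sequence[TrainingInstance], w: np.ndarray,
               ks: Sequence[int] = TOP_KS) -> dict[int, int]:
    """Pooled top-k counts (rank <= k, ties averaged) over instances."""
    ranks = [rank_of_correct(inst, w) for inst in instances]
    return {k: sum(1 for r in ranks if r <= k) for k in ks}


def optimize_weights(instances: Sequence[TrainingInstance],
                     n_draws: int = 1000,
                     seed: int | np.random.Generator | None = None,
                     active: Sequence[str] | None = None) -> Weights:
    """Best simplex draw by training top-1 count.

    ``active`` restricts the search to a subset of the four scoring terms;
    excluded terms get weight exactly 0.  Ties between draws are broken by
    the top-3 count, then by draw order (deterministic under the seed).
    """
    if not instances:
        raise ValueError("need at least one training instance")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    names = list(SCORE_NAMES)
    if active is None:
        active_idx = list(range(len(names)))
    else:
        unknown = set(active) - set(names)
        if unknown:
            raise ValueError(f"unknown scoring terms: {sorted(unknown)}")
        active_idx = [i for i, nm in enumerate(names) if nm in set(active)]
        if not active_idx:
            raise ValueError("active term subset is empty")
    draws_small = sample_simplex(n_draws, k=len(active_idx), seed=seed)
    draws = np.zeros((n_draws, len(names)))
    draws[:, active_idx] = draws_small

    best_w = None
    best_key = None
    for w in draws:
        counts = top_counts(instances, w, ks=(1, 3))
        key = (counts[1], counts[3])
        if best_key is None or key > best_key:
            best_key, best_w = key, w
    return Weights.from_array(best_w)


@dataclass
class CVReport:
    """Per-fold weights and pooled held-out top-k performance."""

    fold_assignment: np.ndarray
    fold_weights: list[Weights]
    fold_counts: list[dict[int, int]]
    pooled_counts: dict[int, int]
    n_instances: int
    score_subset: tuple[str, ...] = field(default_factory=lambda: SCORE_NAMES)

    @property
    def pooled_percent(self) -> dict[int, float]:
        return {k: 100.0 * v / self.n_instances
                for k, v in self.pooled_counts.items()}

    def to_json(self) -> str:
        return json.dumps({
            "n_instances": self.n_instances,
            "score_subset": list(self.score_subset),
            "fold_weights": [list(w.as_array()) for w in self.fold_weights],
            "fold_counts": [{str(k): v for k, v in c.items()}
                            for c in self.fold_counts],
            "pooled_counts": {str(k): v for k, v in self.pooled_counts.items()},
            "pooled_percent": {str(k): v
                               for k, v in self.pooled_percent.items()},
        }, indent=2)


def cross_validate(instances: Sequence[TrainingInstance], k_folds: int,
                   n_draws: int = 1000, seed: int | None = None,
                   score_subset: Sequence[str] | None = None) -> CVReport:
    """k-fold CV of the weight search; ``k_folds == n`` is leave-one-out."""
    n = len(instances)
    if k_folds > n:
        raise ValueError(f"more folds ({k_folds}) than instances ({n})")
    if k_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k_folds)):
        assignment[chunk] = fold

    fold_weights: list[Weights] = []
    fold_counts: list[dict[int, int]] = []
    pooled = {k: 0 for k in TOP_KS}
    for fold in range(k_folds):
        test_idx = np.flatnonzero(assignment == fold)
        train = [instances[i] for i in np.flatnonzero(assignment != fold)]
        w = optimize_weights(train, n_draws=n_draws, seed=rng,
                             active=score_subset)
        counts = top_counts([instances[i] for i in test_idx], w.as_array())
        fold_weights.append(w)
        fold_counts.append(counts)
        for k in TOP_KS:
            pooled[k] += counts[k]
    return CVReport(assignment, fold_weights, fold_counts, pooled, n,
                    tuple(score_subset) if score_subset else SCORE_NAMES)


def cv_table(reports: dict[str, CVReport]) -> pd.DataFrame:
    """Summary table: one row per score subset, top-k counts and percents."""
    rows = []
    for label, rep in reports.items():
        row = {"terms": label, "n": rep.n_instances}
        for k in TOP_KS:
            row[f"top{k}"] = rep.pooled_counts[k]
            row[f"top{k}_pct"] = round(rep.pooled_percent[k], 1)
        rows.append(row)
    return pd.DataFrame(rows)
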