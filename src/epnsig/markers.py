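"""Group-specific marker discovery from labelled expression matrices.

The discovery stage takes a quantile-normalized, log2-transformed,
variance-filtered matrix of tumour samples with entity labels and scores
every probe for how well it separates one molecular group from all other
diagnoses.  Robustness against the particular choice of comparison samples
comes from resampling: the target group of size *t* is compared repeatedly
(default 100x) against an equal-sized draw (without replacement) from the
pooled non-target samples, using Student's two-sided equal-variance t-test.
A probe's score is the arithmetic mean p-value and mean linear fold-change
(``2**(mean_target - mean_drawn)``) over the iterations; candidates are the
probes with mean fold >= 5 ranked within the top 20 by mean p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "MarkerScore",
    "SelectionRule",
    "quantile_normalize",
    "variance_filter",
    "resampled_ttest_scores",
    "select_markers",
]


@dataclass
class MarkerScore:
    """Per-probe summary of the resampled t-test scheme.

    ``mean_fold`` is the linear-scale target/comparison ratio averaged over
    iterations; ``max_fold`` is the largest single-iteration ratio.
    ``significance_rank`` 1 is the smallest mean p (ties broken by larger
    mean fold, then probe id).
    """

    probe_id: str
    mean_p: float
    mean_fold: float
    significance_rank: int
    max_fold: float = float("nan")


@dataclass
class SelectionRule:
    """Candidate-marker selection thresholds (defaults: fold >= 5 within the
    top 20 significance positions, after a variance < 0.25 probe filter and
    100 resampling iterations)."""

    min_fold: float = 5.0
    max_rank: int = 20
    n_iterations: int = 100
    variance_threshold: float = 0.25

    def __post_init__(self) -> None:
        if min(self.min_fold, self.max_rank, self.n_iterations) <= 0:
            raise ValueError("selection-rule fields must be strictly positive")
        if self.variance_threshold <= 0:
            raise ValueError("variance_threshold must be strictly positive")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common rank-mean distribution.

    After the call each column holds the same sorted multiset: the per-rank
    mean of the input columns.  Ties within a column receive the mean of the
    reference values of their tied ranks, preserving each column's rank
    order.  The operation is idempotent.
    """
    X = matrix.values
    n_probes, n_samples = X.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize: single-sample matrix left unchanged")
        return ExpressionMatrix(matrix.data.copy(), matrix.scale, matrix.labels)

    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        # runs of tied values share the mean of their ranks' reference values
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_probes]))
        assigned = np.empty(n_probes)
        cumref = np.concatenate(([0.0], np.cumsum(reference)))
        for s, e in zip(starts, ends):
            assigned[s:e] = (cumref[e] - cumref[s]) / (e - s)
        out[order, j] = assigned
    data = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(data, matrix.scale, matrix.labels)


def variance_filter(matrix: ExpressionMatrix, threshold: float = 0.25) -> ExpressionMatrix:
    """Drop probes whose sample variance is below ``threshold`` (log2 scale)."""
    if matrix.scale != "log2":
        raise ValueError("variance_filter expects a log2-scale matrix")
    var = matrix.values.var(axis=1, ddof=1)
    keep = var >= threshold
    if not keep.any():
        raise ValueError(
            f"variance_filter removed every probe; lower the threshold ({threshold})"
        )
    return ExpressionMatrix(matrix.data.loc[keep], matrix.scale, matrix.labels)


def resampled_ttest_scores(
    matrix: ExpressionMatrix,
    target_entity: str,
    n_iterations: int = 100,
    seed: int = 0,
    welch: bool = False,
    stratified: bool = False,
) -> list[MarkerScore]:
    """Score probes by the resampled two-group t-test scheme.

    Per iteration, an equal-sized comparison set is drawn without
    replacement from the pooled non-target samples (``stratified=True``
    allocates the draw proportionally across the other entities instead).
    Deterministic under ``seed``; sample identities are sorted before any
    draw, so scores are invariant to the column order of the matrix.
    """
    if matrix.scale != "log2":
        raise ValueError("resampled_ttest_scores expects a log2-scale matrix")
    if matrix.labels is None:
        raise ValueError("matrix has no entity labels")
    target_ids = sorted(s for s, lab in matrix.labels.items() if lab == target_entity)
    pool_ids = sorted(s for s, lab in matrix.labels.items() if lab != target_entity)
    t = len(target_ids)
    if t < 2:
        raise ValueError(f"target group {target_entity!r} has {t} samples; need >= 2")
    if len(pool_ids) < t:
        raise ValueError(
            f"non-target pool ({len(pool_ids)}) smaller than target group ({t}); "
            "resampling is without replacement"
        )

    col_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    X = matrix.values
    target_X = X[:, [col_index[s] for s in target_ids]]
    mean_target = target_X.mean(axis=1)

    rng = np.random.default_rng(seed)
    pool_entities = [matrix.labels[s] for s in pool_ids]
    sum_p = np.zeros(X.shape[0])
    sum_fold = np.zeros(X.shape[0])
    max_fold = np.full(X.shape[0], -np.inf)
    for _ in range(n_iterations):
        if stratified:
            drawn = _stratified_draw(rng, pool_ids, pool_entities, t)
        else:
            drawn = rng.choice(pool_ids, size=t, replace=False)
        drawn_X = X[:, [col_index[s] for s in drawn]]
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # zero-variance probes yield nan p, mapped to 1 below
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_ind(target_X, drawn_X, axis=1, equal_var=not welch)
        p = np.where(np.isnan(p), 1.0, p)
        fold = 2.0 ** (mean_target - drawn_X.mean(axis=1))
        sum_p += p
        sum_fold += fold
        max_fold = np.maximum(max_fold, fold)

    mean_p = sum_p / n_iterations
    mean_fold = sum_fold / n_iterations
    probes = matrix.probe_ids
    order = sorted(range(len(probes)),
                   key=lambda i: (mean_p[i], -mean_fold[i], probes[i]))
    scores = [
        MarkerScore(
            probe_id=probes[i],
            mean_p=float(mean_p[i]),
            mean_fold=float(mean_fold[i]),
            significance_rank=rank,
            max_fold=float(max_fold[i]),
        )
        for rank, i in enumerate(order, start=1)
    ]
    return scores


def _stratified_draw(rng: np.random.Generator, pool_ids: Sequence[str],
                     pool_entities: Sequence[str], t: int) -> list[str]:
    """Proportional allocation (largest remainder) across non-target entities."""
    entities = sorted(set(pool_entities))
    by_entity = {e: [s for s, pe in zip(pool_ids, pool_entities) if pe == e]
                 for e in entities}
    total = len(pool_ids)
    quotas = {e: t * len(by_entity[e]) / total for e in entities}
    counts = {e: int(np.floor(q)) for e, q in quotas.items()}
    short = t - sum(counts.values())
    for e in sorted(entities, key=lambda e: quotas[e] - counts[e], reverse=True)[:short]:
        counts[e] += 1
    drawn: list[str] = []
    for e in entities:
        k = min(counts[e], len(by_entity[e]))
        if k:
            drawn.extend(rng.choice(by_entity[e], size=k, replace=False))
    return drawn


def select_markers(scores: Sequence[MarkerScore],
                   rule: SelectionRule = SelectionRule()) -> list[str]:
    """Probes passing the fold and significance-rank thresholds, ordered by
    descending mean fold-change."""
    picked = [s for s in scores
              if s.mean_fold >= rule.min_fold and s.significance_rank <= rule.max_rank]
    picked.sort(key=lambda s: (-s.mean_fold, s.probe_id))
    return [s.probe_id for s in picked]
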