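"""Per-split feature rankers and Borda aggregation.

Three rankers are used inside the cross-validated protocol: absolute linear
SVM weights, random-forest Gini importance (both "native" to their
classifier), and the classifier-independent one-way ANOVA F score
("KBest"). The per-split rankings are combined into one consensus list with
the Borda count: each feature receives ``L - position`` points from each
list (L = list length, position 1-based), and features are ordered by
decreasing total. Borda operates on positions, not raw scores, so
heterogeneous score scales across splits cannot bias the aggregate.

Ties are always broken lexicographically on feature id, which makes every
ranking deterministic across platforms.
"""

from __future__ import annotations

import numpy as np
from sklearn.feature_selection import f_classif

from ._utils import DataError, rank_order
from .io import RankedFeatureList

__all__ = ["rank_svm_weights", "rank_gini", "rank_kbest", "borda_aggregate"]


def _ordered(feature_ids, scores, tag) -> RankedFeatureList:
    order = rank_order(list(feature_ids), np.asarray(scores, dtype=float))
    return RankedFeatureList(
        [feature_ids[i] for i in order],
        np.asarray(scores, dtype=float)[order],
        ranker_tag=tag,
    )


def rank_svm_weights(feature_ids, weights) -> RankedFeatureList:
    """Rank by decreasing absolute weight of a fitted linear decision function."""
    weights = np.asarray(weights, dtype=float).ravel()
    if len(feature_ids) != weights.size:
        raise DataError("one weight per feature required")
    if not np.isfinite(weights).all():
        raise DataError("non-finite SVM weight")
    return _ordered(list(feature_ids), np.abs(weights), "svm_weights")


def rank_gini(feature_ids, importances) -> RankedFeatureList:
    """Rank by decreasing mean decrease in Gini impurity from a fitted forest."""
    importances = np.asarray(importances, dtype=float).ravel()
    if len(feature_ids) != importances.size:
        raise DataError("one importance per feature required")
    if not np.isfinite(importances).all() or (importances < 0).any():
        raise DataError("Gini importances must be finite and nonnegative")
    return _ordered(list(feature_ids), importances, "gini")


def rank_kbest(x, y, feature_ids) -> RankedFeatureList:
    """Rank by decreasing one-way ANOVA F statistic between the two classes.

    Features that are constant (or constant within both classes) get F = 0
    and fall to the bottom of the list.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise DataError(f"exactly two classes required, found {classes.size}")
    if counts.min() < 2:
        raise DataError("each class needs at least 2 samples for the F statistic")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_scores, _ = f_classif(x, y)
    f_scores = np.nan_to_num(f_scores, nan=0.0, posinf=np.finfo(float).max)
    return _ordered(list(feature_ids), f_scores, "kbest")


def borda_aggregate(lists, tag: str = "borda") -> RankedFeatureList:
    """Aggregate rankings over the same feature universe by Borda count.

    A feature at 1-based position ``pos`` in a list of length L scores
    ``L - pos`` points there (first place earns L - 1, last place 0);
    totals are summed over lists and sorted decreasingly. Invariant to the
    order of the input lists.
    """
    lists = list(lists)
    if not lists:
        raise DataError("no ranked lists to aggregate")
    universe = sorted(lists[0].feature_ids)
    length = len(universe)
    for rl in lists:
        if sorted(rl.feature_ids) != universe:
            raise DataError("ranked lists cover different feature universes")
    totals = {fid: 0 for fid in universe}
    for rl in lists:
        for pos, fid in enumerate(rl.feature_ids):
            totals[fid] += length - pos - 1
    scores = np.array([float(totals[fid]) for fid in universe])
    return _ordered(universe, scores, tag)
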