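"""Train-set-fitted feature filtering.

Two filters run before any model sees the data: features with any missing
value are dropped, and features with zero or near-zero variance are dropped.
The near-zero-variance rule follows the convention popularized by caret's
``nearZeroVar``: a feature is flagged when the ratio of the most common
value's count to the second most common value's count exceeds ``freq_ratio``
(default 95/5 = 19) AND the percentage of distinct values is at most
``unique_percent`` (default 10). Constant features are always flagged.

Both filters are fitted on the training (TR) rows only and then applied to
TR and TS alike, so test-set values can never influence which features
survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import DataError
from .io import OmicsLayer

__all__ = [
    "NearZeroVarianceFilter",
    "FilterModel",
    "drop_na_features",
    "fit_near_zero_variance_filter",
    "apply_filter",
]


class NearZeroVarianceFilter(BaseEstimator, TransformerMixin):
    """Remove zero- and near-zero-variance features, caret-style.

    Parameters
    ----------
    freq_ratio : float, default=19.0
        Threshold on (count of most common value) / (count of second most
        common value). A constant column has no second value; its ratio is
        treated as infinite, so constants are always removed.
    unique_percent : float, default=10.0
        Threshold on ``100 * n_distinct / n_samples``.

    Attributes
    ----------
    support_ : ndarray of bool, shape (n_features,)
        True for kept features.
    """

    def __init__(self, freq_ratio: float = 19.0, unique_percent: float = 10.0):
        self.freq_ratio = freq_ratio
        self.unique_percent = unique_percent

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DataError("expected a 2-D matrix")
        n, p = X.shape
        if n < 2:
            raise DataError("near-zero-variance filter needs at least 2 samples")
        support = np.ones(p, dtype=bool)
        for j in range(p):
            _, counts = np.unique(X[:, j], return_counts=True)
            n_unique = counts.size
            if n_unique == 1:
                support[j] = False
                continue
            top2 = np.sort(counts)[::-1][:2]
            ratio = np.inf if top2[1] == 0 else top2[0] / top2[1]
            percent_unique = 100.0 * n_unique / n
            if ratio > self.freq_ratio and percent_unique <= self.unique_percent:
                support[j] = False
        self.n_features_in_ = p
        self.support_ = support
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


@dataclass
class FilterModel:
    """A TR-fitted feature filter, re-applicable by feature id."""

    kept_feature_ids: list[str]
    criteria: dict = field(default_factory=dict)


def drop_na_features(layer: OmicsLayer) -> OmicsLayer:
    """Remove every feature column that contains at least one missing value."""
    keep = ~np.isnan(layer.values).any(axis=0)
    if not keep.any():
        raise DataError(f"all features of layer {layer.layer_name!r} contain NA")
    if keep.all():
        return layer
    kept_ids = [f for f, k in zip(layer.feature_ids, keep) if k]
    return layer.subset_features(kept_ids)


def fit_near_zero_variance_filter(
    tr: OmicsLayer, freq_ratio: float = 19.0, unique_percent: float = 10.0
) -> FilterModel:
    """Fit the near-zero-variance filter on TR rows of one layer."""
    if not np.isfinite(tr.values).all():
        raise DataError("near-zero-variance filter requires a finite matrix; drop NA features first")
    nzv = NearZeroVarianceFilter(freq_ratio=freq_ratio, unique_percent=unique_percent).fit(tr.values)
    kept = [f for f, k in zip(tr.feature_ids, nzv.support_) if k]
    if not kept:
        raise DataError(f"all features of layer {tr.layer_name!r} are near-zero-variance")
    return FilterModel(
        kept_feature_ids=kept,
        criteria={
            "na_filter": True,
            "freq_ratio_threshold": freq_ratio,
            "unique_percent_threshold": unique_percent,
            "n_before": tr.n_features,
            "n_after": len(kept),
        },
    )


def apply_filter(model: FilterModel, layer: OmicsLayer) -> OmicsLayer:
    """Restrict a layer to the kept features, in TR-fitted order."""
    return layer.subset_features(model.kept_feature_ids)
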