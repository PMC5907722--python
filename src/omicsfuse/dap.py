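"""The Data Analysis Protocol (DAP): a reproducible, leakage-free
cross-validated classification and feature-selection procedure.

Given a preprocessed training set, the protocol runs a 10x5-fold stratified
cross-validation. In every one of the 50 splits, features are ranked on the
split's training part only (linear-SVM weights, random-forest Gini
importance, or ANOVA F score), the classifier is retrained on an increasing
number of top-ranked features along the grid
``[5, 10, 25, 50, 75, 100, 500, 1000, 5000, 10000, NF]`` (truncated at NF,
the total feature count), and the Matthews correlation coefficient is
recorded on the held-out fold. The 50 per-split rankings are merged into a
consensus list with the Borda count; the grid point maximizing the mean CV
MCC (ties favor the smaller, more compact signature) defines the signature
size. The final model is retrained on the full training set restricted to
the signature and evaluated exactly once on the external test set.

An externally supplied ranking (``ranker_override``, used by the rSNF
integration scheme) replaces the per-split ranking and the Borda step: the
protocol then only evaluates grid points under that fixed ordering.

A "random label" scheme — rerunning the protocol on permuted training
labels — provides a selection-bias check: scrambled runs should score
near-zero MCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from ._utils import DataError, stage_seed
from .io import EndpointLabels, OmicsLayer, RankedFeatureList
from .metrics import mcc_cv_summary, mcc_from_labels
from .ranking import borda_aggregate, rank_gini, rank_kbest, rank_svm_weights

__all__ = [
    "DEFAULT_FEATURE_GRID",
    "DapConfig",
    "DapResult",
    "DapClassifier",
    "run_dap",
    "validate",
    "random_label_check",
]

DEFAULT_FEATURE_GRID = (5, 10, 25, 50, 75, 100, 500, 1000, 5000, 10000)


@dataclass
class DapConfig:
    """Configuration of one protocol run."""

    classifier: str = "lsvm"  # {"lsvm", "rf"}
    ranker: str = "native"  # {"native", "kbest"}
    cv_repeats: int = 10
    cv_folds: int = 5
    feature_grid: tuple = DEFAULT_FEATURE_GRID
    seed: int = 0
    svm_c: float = 1.0
    rf_n_estimators: int = 500
    n_boot: int = 1000

    def estimator_params(self) -> dict:
        return {
            "classifier": self.classifier,
            "ranker": self.ranker,
            "cv_repeats": self.cv_repeats,
            "cv_folds": self.cv_folds,
            "feature_grid": self.feature_grid,
            "random_state": self.seed,
            "svm_c": self.svm_c,
            "rf_n_estimators": self.rf_n_estimators,
            "n_boot": self.n_boot,
        }


class DapClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator running the full protocol in :meth:`fit`.

    Parameters mirror :class:`DapConfig`. After fitting, the estimator
    predicts with the final model trained on the selected signature.

    Attributes
    ----------
    grid_ : list of int
        Feature-grid points actually evaluated (truncated at ``NF``).
    mcc_curve_ : pandas.DataFrame
        Mean CV MCC with bootstrap interval per grid point.
    best_nfeat_ : int
        Grid point maximizing the mean CV MCC (ties -> smaller).
    ranking_ : RankedFeatureList
        Borda-aggregated consensus ranking (or the override ranking).
    signature_ : list of str
        Top ``best_nfeat_`` features of ``ranking_``.
    signature_indices_ : ndarray of int
        Column indices of the signature in the training matrix.
    mcc_cv_ : tuple (mean, lower, upper)
        CV performance at ``best_nfeat_``.
    model_ : fitted classifier
        Final model retrained on the full training set.
    """

    def __init__(
        self,
        classifier: str = "lsvm",
        ranker: str = "native",
        cv_repeats: int = 10,
        cv_folds: int = 5,
        feature_grid=DEFAULT_FEATURE_GRID,
        random_state: int = 0,
        svm_c: float = 1.0,
        rf_n_estimators: int = 500,
        n_boot: int = 1000,
        ranker_override=None,
    ):
        self.classifier = classifier
        self.ranker = ranker
        self.cv_repeats = cv_repeats
        self.cv_folds = cv_folds
        self.feature_grid = feature_grid
        self.random_state = random_state
        self.svm_c = svm_c
        self.rf_n_estimators = rf_n_estimators
        self.n_boot = n_boot
        self.ranker_override = ranker_override

    # ------------------------------------------------------------------
    def _base_estimator(self, seed: int):
        if self.classifier == "lsvm":
            return SVC(kernel="linear", C=self.svm_c)
        if self.classifier == "rf":
            return RandomForestClassifier(
                n_estimators=self.rf_n_estimators, random_state=seed, n_jobs=1
            )
        raise DataError(f"unknown classifier {self.classifier!r}")

    def _rank_fold(self, x, y, feature_ids, seed: int) -> RankedFeatureList:
        if self.ranker == "kbest":
            return rank_kbest(x, y, feature_ids)
        if self.ranker != "native":
            raise DataError(f"unknown ranker {self.ranker!r}")
        est = self._base_estimator(seed).fit(x, y)
        if self.classifier == "lsvm":
            return rank_svm_weights(feature_ids, est.coef_.ravel())
        return rank_gini(feature_ids, est.feature_importances_)

    def _resolve_grid(self, nf: int) -> list[int]:
        grid = sorted({int(g) for g in self.feature_grid if int(g) < nf})
        grid.append(nf)
        return grid

    # ------------------------------------------------------------------
    def fit(self, X, y, feature_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise DataError("X must be 2-D with one label per row")
        if not np.isfinite(X).all():
            raise DataError("training matrix must be finite (preprocess first)")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise DataError("the protocol handles binary endpoints only")
        if counts.min() < self.cv_folds:
            raise DataError(
                f"minority class has {counts.min()} samples, fewer than "
                f"{self.cv_folds} folds: stratification impossible"
            )
        n, nf = X.shape
        if feature_ids is None:
            feature_ids = [f"f{j}" for j in range(nf)]
        feature_ids = [str(f) for f in feature_ids]

        grid = self._resolve_grid(nf)
        override = self.ranker_override
        if override is not None:
            if isinstance(override, RankedFeatureList):
                override_ids = list(override.feature_ids)
            else:
                override_ids = [str(f) for f in override]
            if sorted(override_ids) != sorted(feature_ids):
                raise DataError("ranker_override must cover exactly the feature universe")

        cv = RepeatedStratifiedKFold(
            n_splits=self.cv_folds,
            n_repeats=self.cv_repeats,
            random_state=stage_seed(self.random_state, "cv"),
        )
        col_index = {f: j for j, f in enumerate(feature_ids)}
        split_mcc = np.zeros((self.cv_folds * self.cv_repeats, len(grid)))
        split_lists: list[RankedFeatureList] = []
        for s, (tr_idx, te_idx) in enumerate(cv.split(X, y)):
            x_tr, y_tr = X[tr_idx], y[tr_idx]
            x_te, y_te = X[te_idx], y[te_idx]
            if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
                raise DataError("a CV fold lost a class; re-stratify with fewer folds")
            seed_s = stage_seed(self.random_state, f"split{s}")
            if override is not None:
                ranked_ids = override_ids
            else:
                ranked = self._rank_fold(x_tr, y_tr, feature_ids, seed_s)
                split_lists.append(ranked)
                ranked_ids = ranked.feature_ids
            top_cols = np.array([col_index[f] for f in ranked_ids])
            for g, k in enumerate(grid):
                cols = top_cols[:k]
                est = self._base_estimator(stage_seed(seed_s, f"grid{k}"))
                est.fit(x_tr[:, cols], y_tr)
                split_mcc[s, g] = mcc_from_labels(y_te, est.predict(x_te[:, cols]))

        if override is not None:
            if isinstance(override, RankedFeatureList):
                self.ranking_ = override
            else:
                self.ranking_ = RankedFeatureList(
                    override_ids,
                    np.arange(len(override_ids), 0, -1, dtype=float),
                    ranker_tag="override",
                )
        else:
            self.ranking_ = borda_aggregate(split_lists)

        rows = []
        boot_seed = stage_seed(self.random_state, "bootstrap")
        for g, k in enumerate(grid):
            mean, lo, hi = mcc_cv_summary(split_mcc[:, g], n_boot=self.n_boot, seed=boot_seed)
            rows.append({"nfeat": k, "mcc_mean": mean, "mcc_lower": lo, "mcc_upper": hi})
        self.mcc_curve_ = pd.DataFrame(rows)
        best_g = int(np.argmax(self.mcc_curve_["mcc_mean"].to_numpy()))
        self.grid_ = grid
        self.best_nfeat_ = grid[best_g]
        self.mcc_cv_ = (
            float(self.mcc_curve_.loc[best_g, "mcc_mean"]),
            float(self.mcc_curve_.loc[best_g, "mcc_lower"]),
            float(self.mcc_curve_.loc[best_g, "mcc_upper"]),
        )
        self.signature_ = self.ranking_.top(self.best_nfeat_)
        self.signature_indices_ = np.array([col_index[f] for f in self.signature_])
        self.split_mcc_ = split_mcc
        self.feature_ids_ = feature_ids
        self.classes_ = classes
        self.n_features_in_ = nf
        self.model_ = self._base_estimator(stage_seed(self.random_state, "final")).fit(
            X[:, self.signature_indices_], y
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] == len(self.signature_indices_):
            cols = X  # already restricted to the signature
        else:
            cols = X[:, self.signature_indices_]
        return self.model_.predict(cols)


@dataclass
class DapResult:
    """Outcome of one protocol run on a training set."""

    config: DapConfig
    grid: list
    mcc_curve: pd.DataFrame
    best_nfeat: int
    signature: RankedFeatureList
    mcc_cv: tuple
    estimator: DapClassifier = field(repr=False)
    mcc_val: float | None = None
    predictions: pd.DataFrame | None = None
    random_label_mcc: list | None = None

    @property
    def signature_ids(self) -> list[str]:
        return list(self.signature.feature_ids)


def run_dap(
    tr: OmicsLayer,
    labels: EndpointLabels,
    cfg: DapConfig | None = None,
    ranker_override: RankedFeatureList | None = None,
) -> DapResult:
    """Run the protocol on a preprocessed training layer."""
    cfg = cfg or DapConfig()
    y = labels.loc(tr.sample_ids)
    est = DapClassifier(ranker_override=ranker_override, **cfg.estimator_params())
    est.fit(tr.values, y, feature_ids=tr.feature_ids)
    signature = RankedFeatureList(
        est.signature_,
        np.asarray(est.ranking_.scores[: est.best_nfeat_], dtype=float),
        ranker_tag=est.ranking_.ranker_tag,
    )
    return DapResult(
        config=cfg,
        grid=list(est.grid_),
        mcc_curve=est.mcc_curve_.copy(),
        best_nfeat=est.best_nfeat_,
        signature=signature,
        mcc_cv=est.mcc_cv_,
        estimator=est,
    )


def validate(result: DapResult, ts: OmicsLayer, ts_labels: EndpointLabels) -> DapResult:
    """Evaluate the retrained model once on the external test set.

    The test layer is aligned to the signature by feature id; a missing
    signature feature is a hard error. Fills ``mcc_val`` and per-sample
    predictions on the result.
    """
    if ts.n_samples == 0:
        raise DataError("empty test set")
    ts_sig = ts.subset_features(result.signature_ids)
    y_true = ts_labels.loc(ts.sample_ids)
    y_pred = result.estimator.model_.predict(ts_sig.values)
    result.mcc_val = mcc_from_labels(y_true, y_pred)
    result.predictions = pd.DataFrame(
        {
            "sample_id": ts.sample_ids,
            "y_true": y_true,
            "y_pred": y_pred,
            "correct": y_true == y_pred,
        }
    )
    return result


def random_label_check(
    tr: OmicsLayer,
    labels: EndpointLabels,
    cfg: DapConfig | None = None,
    n_scrambles: int = 10,
) -> list[float]:
    """Selection-bias check: rerun the protocol on permuted labels.

    Each scramble permutes the training labels (class counts preserved) and
    records the best mean CV MCC of the resulting run. With genuine signal
    absent by construction, the scrambled distribution should center near 0.
    """
    cfg = cfg or DapConfig()
    y = labels.loc(tr.sample_ids)
    rng = np.random.RandomState(stage_seed(cfg.seed, "random_label"))
    out = []
    for s in range(n_scrambles):
        y_perm = rng.permutation(y)
        scrambled = EndpointLabels(labels.endpoint_name + "_scrambled", tr.sample_ids, y_perm)
        sub_cfg = DapConfig(**{**cfg.__dict__, "seed": stage_seed(cfg.seed, f"scramble{s}")})
        res = run_dap(tr, scrambled, sub_cfg)
        out.append(res.mcc_cv[0])
    return out
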