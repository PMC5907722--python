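"""Evaluation statistics for integrated classification.

The toolkit's headline metric is the Matthews correlation coefficient
(MCC), a balanced summary of a binary confusion matrix in [-1, 1] that is
robust to class imbalance. Integration benefit is quantified by ΔMCC = the
maximum MCC over the integrated models (juxtaposition, rSNF, INF) minus the
maximum MCC over the two single layers. The composition of an integrated
feature set is quantified by Prop50 ("mixedness"): the percentage of
features contributed by the minority layer, so 50 means both layers
contribute equally and 0 means one layer dominates entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._utils import DataError
from .io import layer_of

__all__ = [
    "ConfusionCounts",
    "IntegrationComparison",
    "MixednessRecord",
    "mcc",
    "mcc_from_labels",
    "confusion_counts",
    "mcc_cv_summary",
    "delta_mcc",
    "prop50",
    "similarity_scenario",
    "compare_set_sizes",
    "consistent_classification",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise DataError(f"negative confusion count {name}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient of a 2x2 confusion table.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).
    When any factor of the denominator is zero (a degenerate margin) the
    coefficient is defined as 0, the standard convention.
    """
    if c.total == 0:
        raise DataError("empty confusion table")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def confusion_counts(y_true, y_pred, positive=1) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise DataError("y_true and y_pred must align")
    pos_t, pos_p = y_true == positive, y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def mcc_from_labels(y_true, y_pred, positive=1) -> float:
    return mcc(confusion_counts(y_true, y_pred, positive=positive))


def mcc_cv_summary(per_split_mcc, n_boot: int = 1000, seed: int = 0):
    """Mean CV MCC with a percentile bootstrap interval over splits.

    Returns ``(mean, lower, upper)`` where the bounds are the 2.5th/97.5th
    percentiles of the bootstrap distribution of the mean (``n_boot``
    resamples, seeded). The interval construction is a repository
    convention and is recorded in output metadata wherever it is printed.
    """
    values = np.asarray(list(per_split_mcc), dtype=float)
    if values.size == 0:
        raise DataError("no CV splits to summarize")
    mean = float(values.mean())
    if values.size < 2:
        return mean, mean, mean
    rng = np.random.RandomState(seed)
    idx = rng.randint(0, values.size, size=(n_boot, values.size))
    boot_means = values[idx].mean(axis=1)
    lower, upper = np.percentile(boot_means, [2.5, 97.5])
    return mean, float(lower), float(upper)


@dataclass
class IntegrationComparison:
    """Single-layer vs integrated MCCs for one endpoint and layer pair."""

    endpoint: str
    layer_pair: tuple[str, str]
    mcc_o1: float
    mcc_o2: float
    mcc_juxt: float | None
    mcc_rsnf: float | None
    mcc_inf: float | None
    context: str = "cv"

    @property
    def mcc_single(self) -> float:
        return max(self.mcc_o1, self.mcc_o2)

    @property
    def mcc_integration(self) -> float:
        avail = [m for m in (self.mcc_juxt, self.mcc_rsnf, self.mcc_inf) if m is not None]
        if not avail:
            raise DataError("no integration MCC available")
        return max(avail)

    @property
    def delta_mcc(self) -> float:
        return self.mcc_integration - self.mcc_single


def delta_mcc(
    mcc_o1: float,
    mcc_o2: float,
    mcc_juxt: float | None,
    mcc_rsnf: float | None,
    mcc_inf: float | None = None,
    endpoint: str = "endpoint",
    layer_pair: tuple[str, str] = ("O1", "O2"),
    context: str = "cv",
) -> IntegrationComparison:
    """Assemble an :class:`IntegrationComparison`.

    A missing INF value (failed run: intersection < 5 features) is allowed;
    the integration maximum is then taken over the available approaches.
    The same definition applies in CV and in validation.
    """
    for v in (mcc_o1, mcc_o2, mcc_juxt, mcc_rsnf, mcc_inf):
        if v is not None and not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
            raise DataError(f"MCC out of range: {v}")
    comp = IntegrationComparison(
        endpoint, layer_pair, mcc_o1, mcc_o2, mcc_juxt, mcc_rsnf, mcc_inf, context
    )
    comp.mcc_integration  # noqa: B018 - raises if all integration MCCs missing
    return comp


@dataclass
class MixednessRecord:
    feature_set: list[str]
    prop50: float
    per_layer_counts: dict = field(default_factory=dict)


def prop50(feature_set) -> MixednessRecord:
    """Mixedness of an integrated feature set.

    ``prop50 = 100 * min(n_layer1, n_layer2) / (n_layer1 + n_layer2)`` based
    on the layer prefixes of the feature ids; 0 when a single layer
    contributes everything, 50 when contributions are balanced.
    """
    feature_set = list(feature_set)
    if not feature_set:
        raise DataError("empty feature set")
    counts: dict[str, int] = {}
    for fid in feature_set:
        counts[layer_of(fid)] = counts.get(layer_of(fid), 0) + 1
    if len(counts) > 2:
        raise DataError(f"more than two layers represented: {sorted(counts)}")
    values = sorted(counts.values())
    minority = 0 if len(values) == 1 else values[0]
    return MixednessRecord(
        feature_set=feature_set,
        prop50=100.0 * minority / len(feature_set),
        per_layer_counts=counts,
    )


def similarity_scenario(
    mcc_inf: float,
    mcc_other: float,
    nfeat_inf: int,
    nfeat_other: int,
    mcc_tol: float = 1e-9,
) -> str:
    """Classify how INF performance relates to another integration approach.

    ``scenario1``: MCC (or the number of selected features) is equal between
    INF and the other approach. ``scenario2``: the MCC difference is within
    0.1 in magnitude (INF performs similarly). Otherwise ``neither``.
    """
    if nfeat_inf == nfeat_other or abs(mcc_inf - mcc_other) < mcc_tol:
        return "scenario1"
    if abs(mcc_inf - mcc_other) < 0.1:
        return "scenario2"
    return "neither"


def compare_set_sizes(sizes_inf, sizes_other):
    """Two-sided Wilcoxon rank-sum test comparing feature-set sizes.

    Returns ``(W, p)`` where W is the rank-sum statistic of the first
    sample. The exact null distribution is used for small tie-free samples
    (both n <= 25); otherwise the normal approximation with tie correction.
    """
    a = np.asarray(list(sizes_inf), dtype=float)
    b = np.asarray(list(sizes_other), dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both size samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return w, float(res.pvalue)


def consistent_classification(per_run_correct: dict):
    """Samples classified consistently across independent runs.

    Parameters
    ----------
    per_run_correct : dict
        Maps a run identifier to a ``{sample_id: bool}`` correctness map.
        Every run must cover the same sample set.

    Returns
    -------
    (always_correct, always_wrong) : tuple of sorted lists
        Samples correct in every run, and wrong in every run. Samples with
        mixed outcomes appear in neither list.
    """
    if not per_run_correct:
        raise DataError("no runs given")
    runs = list(per_run_correct.values())
    universe = set(runs[0])
    for run_id, correctness in per_run_correct.items():
        if set(correctness) != universe:
            raise DataError(f"run {run_id!r} covers a different sample set")
    always_correct = sorted(s for s in universe if all(r[s] for r in runs))
    always_wrong = sorted(s for s in universe if all(not r[s] for r in runs))
    return always_correct, always_wrong
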