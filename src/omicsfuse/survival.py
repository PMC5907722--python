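"""Survival-based screening and stratification of autoencoder meta-features.

Each bottleneck meta-feature is screened with a univariate Cox
proportional-hazards fit; the reported p-value is the score (log-rank)
test of the null coefficient, and the Benjamini-Hochberg procedure
controls the false-discovery rate across the bottleneck, with
``adjusted p < 0.05`` defining the significant set. Patients are then
stratified by K-means on the significant meta-features, with the cluster
count chosen by the mean Silhouette index over k = 2..6, and the resulting
groups (G1, G2, ...) are compared with Kaplan-Meier curves and the
log-rank test. The groups can finally be fed back as a derived endpoint to
the classification protocol ("relabel classification").

The univariate Cox fits use a dedicated Newton solver, vectorized over
meta-features, with Breslow handling of tied event times; meta-features
are standardized (train-fitted) before fitting by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from ._utils import DataError, stage_seed
from .autoencoder import EncodedRepresentation
from .dap import DapConfig, DapResult, run_dap, validate
from .io import EndpointLabels, OmicsLayer, SplitDefinition, SurvivalData

__all__ = [
    "MetaFeatureScreen",
    "PatientGroups",
    "univariate_cox",
    "cox_screen",
    "replication_fraction",
    "stratify",
    "align_groups",
    "km_logrank",
    "relabel_classify",
]


# ---------------------------------------------------------------------------
# univariate Cox


def _risk_set_sums(values: np.ndarray, order_stat) -> np.ndarray:
    """Sum of ``values`` over every risk set {j : t_j >= t_i} (Breslow)."""
    csum = np.cumsum(values[order_stat["desc"]], axis=0)
    return csum[order_stat["tie_last"]]


def _prepare_order(time: np.ndarray):
    """Sort descending by time; map each sample to its tie-group boundary."""
    desc = np.argsort(-time, kind="stable")
    t_desc = time[desc]
    # tie_last[i] = last index (in desc order) sharing sample i's time
    tie_last_desc = np.zeros(len(time), dtype=int)
    j = 0
    while j < len(time):
        j2 = j
        while j2 + 1 < len(time) and t_desc[j2 + 1] == t_desc[j]:
            j2 += 1
        tie_last_desc[j : j2 + 1] = j2
        j = j2 + 1
    inv = np.empty_like(desc)
    inv[desc] = np.arange(len(desc))
    return {"desc": desc, "tie_last": tie_last_desc[inv]}


def univariate_cox(z: np.ndarray, time: np.ndarray, event: np.ndarray,
                   max_iter: int = 50, tol: float = 1e-9):
    """Univariate Cox PH fits for every column of ``z``, vectorized.

    Returns ``(coef, score_p, converged)`` arrays. The partial likelihood
    uses the Breslow convention for ties; the p-value is the score test at
    beta = 0 (chi-square, 1 df), which coincides with the two-sample
    log-rank test when the covariate is binary. A column whose Newton
    iteration fails to converge (e.g. monotone likelihood) keeps its last
    coefficient and is flagged.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.ndim != 2:
        raise DataError("covariates must form a 2-D matrix")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int).astype(bool)
    n, m = z.shape
    if time.shape[0] != n or event.shape[0] != n:
        raise DataError("time/event must align with the covariate rows")
    if not event.any():
        raise DataError("no observed events: Cox fit impossible")

    order = _prepare_order(time)
    beta = np.zeros(m)

    def score_info(beta_vec):
        eta = z * beta_vec  # (n, m)
        # stabilize exponentials per feature
        eta = eta - eta.max(axis=0, keepdims=True)
        r = np.exp(eta)
        s0 = _risk_set_sums(r, order)
        s1 = _risk_set_sums(z * r, order)
        s2 = _risk_set_sums(z**2 * r, order)
        mean = s1 / s0
        var = s2 / s0 - mean**2
        u = (z[event] - mean[event]).sum(axis=0)
        info = var[event].sum(axis=0)
        return u, info

    u0, i0 = score_info(np.zeros(m))
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(i0 > 0, u0**2 / np.where(i0 > 0, i0, 1.0), 0.0)
    score_p = stats.chi2.sf(chi2, df=1)
    score_p = np.where(i0 > 0, score_p, 1.0)  # degenerate covariate -> p = 1

    converged = np.zeros(m, dtype=bool)
    active = i0 > 0
    for _ in range(max_iter):
        if not active.any():
            break
        u, info = score_info(beta)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 0, u / np.where(info > 0, info, 1.0), 0.0)
        step = np.clip(step, -5.0, 5.0)
        beta = np.where(active, beta + step, beta)
        done = np.abs(step) < tol
        converged |= active & done
        active &= ~done
    if (~converged & (i0 > 0)).any():
        warnings.warn(
            f"{int((~converged & (i0 > 0)).sum())} Cox fit(s) did not converge",
            stacklevel=2,
        )
    return beta, score_p, converged


@dataclass
class MetaFeatureScreen:
    """Per-meta-feature univariate Cox screen with FDR selection."""

    table: pd.DataFrame  # columns: feature, coef, p_value, fdr_adjusted_p, selected
    alpha: float
    replication_fraction: float | None = None

    @property
    def selected(self) -> list:
        return list(self.table.loc[self.table["selected"], "feature"])

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())


def cox_screen(
    encoded: EncodedRepresentation,
    surv: SurvivalData,
    alpha: float = 0.05,
    standardize: bool = True,
) -> MetaFeatureScreen:
    """Screen every meta-feature for association with overall survival.

    One univariate Cox PH model per bottleneck unit; score-test p-values
    are Benjamini-Hochberg adjusted across the bottleneck and units with
    adjusted p below ``alpha`` form the selected set. Meta-features are
    standardized (zero mean, unit variance on the given samples) before
    fitting unless ``standardize=False``; a zero-variance unit gets p = 1.
    """
    surv = surv.loc(encoded.sample_ids)
    z = np.asarray(encoded.meta_features, dtype=float)
    if standardize:
        sd = z.std(axis=0)
        sd[sd == 0] = 1.0
        z = (z - z.mean(axis=0)) / sd
    coef, p, converged = univariate_cox(z, surv.time, surv.event)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "feature": np.arange(z.shape[1]),
            "coef": coef,
            "p_value": p,
            "fdr_adjusted_p": p_adj,
            "selected": p_adj < alpha,
            "converged": converged,
        }
    )
    return MetaFeatureScreen(table=table, alpha=alpha)


def replication_fraction(screen_tr: MetaFeatureScreen, screen_ts: MetaFeatureScreen) -> float:
    """Share of TR-selected meta-features also selected on the TS encoding."""
    tr_sel = set(screen_tr.selected)
    if not tr_sel:
        raise DataError("no TR-selected meta-features")
    frac = len(tr_sel & set(screen_ts.selected)) / len(tr_sel)
    screen_tr.replication_fraction = frac
    return frac


# ---------------------------------------------------------------------------
# stratification


@dataclass
class PatientGroups:
    """K-means patient groups over selected meta-features."""

    sample_ids: list[str]
    labels: list[str]  # "G1", "G2", ...
    k_selected: int
    silhouette_values: dict
    centroids: np.ndarray = field(repr=False, default=None)

    def members(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.labels) if g == group]


def stratify(
    selected_meta: np.ndarray,
    sample_ids,
    k_candidates=range(2, 7),
    seed: int = 0,
    n_init: int = 50,
) -> PatientGroups:
    """K-means over candidate cluster counts, picked by mean Silhouette.

    Groups are named G1, G2, ... in decreasing size order (ties broken by
    cluster index) so that naming is deterministic.
    """
    x = np.asarray(selected_meta, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise DataError("need at least one selected meta-feature")
    n = x.shape[0]
    k_candidates = [k for k in k_candidates if k < n]
    if not k_candidates:
        raise DataError("no feasible cluster count below the sample count")
    sil: dict[int, float] = {}
    fits = {}
    for k in k_candidates:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=stage_seed(seed, f"kmeans{k}"))
        lab = km.fit_predict(x)
        if np.unique(lab).size < 2:
            continue
        sil[k] = float(silhouette_score(x, lab, metric="euclidean"))
        fits[k] = (km, lab)
    if not sil:
        raise DataError("clustering degenerated to a single group for every k")
    k_best = max(sil, key=lambda k: (sil[k], -k))
    km, lab = fits[k_best]
    # deterministic, content-based naming: G1 = largest cluster, centroid
    # coordinates break size ties so sample order cannot flip names
    order = sorted(
        range(k_best),
        key=lambda c: (-int(np.sum(lab == c)), tuple(np.round(km.cluster_centers_[c], 10))),
    )
    name = {c: f"G{i + 1}" for i, c in enumerate(order)}
    return PatientGroups(
        sample_ids=list(sample_ids),
        labels=[name[c] for c in lab],
        k_selected=k_best,
        silhouette_values=sil,
        centroids=km.cluster_centers_[order],
    )


def align_groups(tr_groups: PatientGroups, ts_groups: PatientGroups) -> PatientGroups:
    """Rename TS groups to the nearest TR centroid's name.

    Independent K-means runs label clusters arbitrarily; matching cluster
    centroids restores a consistent G1/G2 correspondence across TR and TS.
    """
    if tr_groups.centroids is None or ts_groups.centroids is None:
        raise DataError("centroids required for group alignment")
    if tr_groups.k_selected != ts_groups.k_selected:
        raise DataError("TR and TS selected different cluster counts; cannot align")
    tr_names = sorted(set(tr_groups.labels))
    mapping = {}
    for i, ts_name in enumerate(sorted(set(ts_groups.labels))):
        d = np.linalg.norm(tr_groups.centroids - ts_groups.centroids[i], axis=1)
        mapping[ts_name] = tr_names[int(np.argmin(d))]
    return PatientGroups(
        sample_ids=list(ts_groups.sample_ids),
        labels=[mapping[g] for g in ts_groups.labels],
        k_selected=ts_groups.k_selected,
        silhouette_values=dict(ts_groups.silhouette_values),
        centroids=ts_groups.centroids,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


@dataclass
class KmLogrankResult:
    curves: dict  # group -> DataFrame(time, survival)
    statistic: float
    p_value: float
    group_sizes: dict


def km_logrank(groups: PatientGroups, surv: SurvivalData) -> KmLogrankResult:
    """Kaplan-Meier curves per group and the log-rank group comparison."""
    surv = surv.loc(groups.sample_ids)
    labels = np.asarray(groups.labels)
    names = sorted(set(labels))
    if len(names) < 2:
        raise DataError("need at least two nonempty groups")
    curves = {}
    sizes = {}
    for g in names:
        mask = labels == g
        if not mask.any():
            raise DataError(f"group {g} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[mask], surv.event[mask], label=g)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[g] = sf
        sizes[g] = int(mask.sum())
    res = multivariate_logrank_test(surv.time, labels, surv.event)
    return KmLogrankResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes=sizes,
    )


def relabel_classify(
    juxt: OmicsLayer,
    tr_groups: PatientGroups,
    ts_groups: PatientGroups,
    split: SplitDefinition,
    cfg: DapConfig | None = None,
) -> DapResult:
    """Classify the derived G1/G2 groups from the juxtaposed omics matrix.

    The cluster-derived groups become a binary endpoint; a fresh protocol
    run is trained on TR and validated on TS. Requires exactly two groups
    on each side (TS groups already aligned to TR naming).
    """
    labels_map = dict(zip(tr_groups.sample_ids, tr_groups.labels))
    labels_map.update(zip(ts_groups.sample_ids, ts_groups.labels))
    names = sorted(set(labels_map.values()))
    if len(names) != 2:
        raise DataError(f"relabel classification needs exactly 2 groups, found {names}")
    encode01 = {names[0]: 0, names[1]: 1}
    all_ids = split.train_ids + split.test_ids
    missing = [s for s in all_ids if s not in labels_map]
    if missing:
        raise DataError(f"samples without group label: {missing[:5]}")
    endpoint = EndpointLabels(
        "derived_groups", all_ids, np.array([encode01[labels_map[s]] for s in all_ids])
    )
    cfg = cfg or DapConfig()
    tr = juxt.subset_samples(split.train_ids)
    ts = juxt.subset_samples(split.test_ids)
    res = run_dap(tr, endpoint, cfg)
    return validate(res, ts, endpoint)
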