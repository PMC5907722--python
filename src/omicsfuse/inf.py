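"""Orchestration of the three integration strategies.

For one endpoint and one pair of omics layers the pipeline builds:

* *juxt* — the protocol run on the column-wise concatenation of the two
  layers with an ordinary (native or ANOVA-F) ranking;
* *rSNF* — the protocol run on the same juxtaposed matrix, but with the
  feature ordering fixed to the rSNF ranking derived from clustering the
  SNF-fused patient network of the training samples;
* *INF* — the protocol run on the juxtaposed matrix restricted to the
  intersection of the juxt and rSNF signatures. An intersection smaller
  than 5 features is recorded as a failed run rather than classified.

Per-layer near-zero-variance filtering (and NA removal) is fitted on the
training samples of each layer before juxtaposition; test samples are only
ever transformed. All stage seeds are derived from one master seed by
hashing, so adding a stage never shifts another stage's random stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._utils import DataError, stage_seed
from .dap import DapConfig, DapResult, run_dap, validate
from .io import EndpointLabels, OmicsLayer, SplitDefinition, juxtapose
from .metrics import delta_mcc, prop50, similarity_scenario
from .preprocess import apply_filter, drop_na_features, fit_near_zero_variance_filter
from .snf import build_affinity, cluster_fused, rsnf_rank, snf_fuse

__all__ = ["InfRun", "preprocess_pair", "run_single_layers", "run_inf", "summarize"]

MIN_INTERSECTION = 5


def intersect_signatures(sig_juxt, sig_rsnf):
    """Intersection of the two top signatures and the resulting run status.

    Fewer than 5 shared features makes the intersection too small to
    classify: the run is recorded as failed rather than raised.
    """
    inf_set = sorted(set(sig_juxt) & set(sig_rsnf))
    status = "ok" if len(inf_set) >= MIN_INTERSECTION else "failed_small_intersection"
    return inf_set, status


@dataclass
class InfRun:
    """All artifacts of one endpoint x layer-pair integration run."""

    endpoint: str
    layer_pair: tuple[str, str]
    classifier: str
    ranker: str
    dap_juxt: DapResult
    dap_rsnf: DapResult
    inf_feature_set: list[str]
    dap_inf: DapResult | None
    status: str  # {"ok", "failed_small_intersection"}
    fused_n_clusters: int | None = None


def preprocess_pair(
    o1: OmicsLayer,
    o2: OmicsLayer,
    split: SplitDefinition,
    freq_ratio: float = 19.0,
    unique_percent: float = 10.0,
):
    """Per-layer TR-fitted filtering, then TR/TS juxtaposition.

    Returns ``(tr1, tr2, ts1, ts2, juxt_tr, juxt_ts)``.
    """
    trs, tss = [], []
    for layer in (o1, o2):
        layer = drop_na_features(layer)  # NA features leave the whole dataset
        tr = layer.subset_samples(split.train_ids)
        model = fit_near_zero_variance_filter(tr, freq_ratio, unique_percent)
        trs.append(apply_filter(model, tr))
        tss.append(apply_filter(model, layer.subset_samples(split.test_ids)))
    return (*trs, *tss, juxtapose(trs[0], trs[1]), juxtapose(tss[0], tss[1]))


def run_single_layers(
    o1: OmicsLayer,
    o2: OmicsLayer,
    labels: EndpointLabels,
    split: SplitDefinition,
    cfg: DapConfig | None = None,
):
    """Run the protocol on each layer independently (feeds MCC_single)."""
    cfg = cfg or DapConfig()
    results = []
    for i, layer in enumerate((o1, o2)):
        layer = drop_na_features(layer)
        tr = layer.subset_samples(split.train_ids)
        model = fit_near_zero_variance_filter(tr)
        tr = apply_filter(model, tr)
        ts = apply_filter(model, layer.subset_samples(split.test_ids))
        sub_cfg = DapConfig(**{**cfg.__dict__, "seed": stage_seed(cfg.seed, f"single{i}")})
        res = run_dap(tr, labels, sub_cfg)
        validate(res, ts, labels)
        results.append(res)
    return tuple(results)


def run_inf(
    o1: OmicsLayer,
    o2: OmicsLayer,
    labels: EndpointLabels,
    split: SplitDefinition,
    cfg: DapConfig | None = None,
    snf_k: int = 20,
    snf_mu: float = 0.5,
    snf_iterations: int = 20,
    n_clusters="auto",
) -> InfRun:
    """The full integration pipeline for one layer pair."""
    cfg = cfg or DapConfig()
    tr1, tr2, _, _, juxt_tr, juxt_ts = preprocess_pair(o1, o2, split)

    # (1) juxtaposition with ordinary ranking
    cfg_juxt = DapConfig(**{**cfg.__dict__, "seed": stage_seed(cfg.seed, "juxt")})
    dap_juxt = run_dap(juxt_tr, labels, cfg_juxt)
    validate(dap_juxt, juxt_ts, labels)

    # (2) SNF fusion of the TR networks, clustering, rSNF ranking
    net1 = build_affinity(tr1, k=snf_k, mu=snf_mu)
    net2 = build_affinity(tr2, k=snf_k, mu=snf_mu)
    fused = snf_fuse([net1, net2], k=snf_k, t=snf_iterations)
    fused = cluster_fused(fused, n_clusters, seed=stage_seed(cfg.seed, "fused_clusters"))
    rsnf_list = rsnf_rank(
        juxt_tr, fused.cluster_labels, k=snf_k, mu=snf_mu, seed=stage_seed(cfg.seed, "rsnf")
    )
    cfg_rsnf = DapConfig(**{**cfg.__dict__, "seed": stage_seed(cfg.seed, "rsnf_dap")})
    dap_rsnf = run_dap(juxt_tr, labels, cfg_rsnf, ranker_override=rsnf_list)
    validate(dap_rsnf, juxt_ts, labels)

    # (3) intersection of the two signatures
    inf_set, status = intersect_signatures(dap_juxt.signature_ids, dap_rsnf.signature_ids)
    if status != "ok":
        return InfRun(
            endpoint=labels.endpoint_name,
            layer_pair=(o1.layer_name, o2.layer_name),
            classifier=cfg.classifier,
            ranker=cfg.ranker,
            dap_juxt=dap_juxt,
            dap_rsnf=dap_rsnf,
            inf_feature_set=inf_set,
            dap_inf=None,
            status="failed_small_intersection",
            fused_n_clusters=fused.n_clusters,
        )

    cfg_inf = DapConfig(**{**cfg.__dict__, "seed": stage_seed(cfg.seed, "inf")})
    dap_inf = run_dap(juxt_tr.subset_features(inf_set), labels, cfg_inf)
    validate(dap_inf, juxt_ts.subset_features(inf_set), labels)
    return InfRun(
        endpoint=labels.endpoint_name,
        layer_pair=(o1.layer_name, o2.layer_name),
        classifier=cfg.classifier,
        ranker=cfg.ranker,
        dap_juxt=dap_juxt,
        dap_rsnf=dap_rsnf,
        inf_feature_set=inf_set,
        dap_inf=dap_inf,
        status="ok",
        fused_n_clusters=fused.n_clusters,
    )


def summarize(runs, singles) -> pd.DataFrame:
    """Assemble the per-run comparison table.

    Parameters
    ----------
    runs : list of InfRun
    singles : list of (DapResult, DapResult)
        Single-layer results matching ``runs`` element-wise.

    Returns
    -------
    pandas.DataFrame
        One row per run and context (CV / validation) with single and
        integrated MCCs, ΔMCC, signature sizes, Prop50 mixedness of each
        integrated signature, and the INF-vs-other similarity scenarios.
    """
    rows = []
    for run, (s1, s2) in zip(runs, singles):
        inf_ok = run.status == "ok"
        for context in ("cv", "validation"):
            if context == "cv":
                m1, m2 = s1.mcc_cv[0], s2.mcc_cv[0]
                mj, mr = run.dap_juxt.mcc_cv[0], run.dap_rsnf.mcc_cv[0]
                mi = run.dap_inf.mcc_cv[0] if inf_ok else None
            else:
                m1, m2 = s1.mcc_val, s2.mcc_val
                mj, mr = run.dap_juxt.mcc_val, run.dap_rsnf.mcc_val
                mi = run.dap_inf.mcc_val if inf_ok else None
            comp = delta_mcc(
                m1, m2, mj, mr, mi,
                endpoint=run.endpoint, layer_pair=run.layer_pair, context=context,
            )
            row = {
                "endpoint": run.endpoint,
                "layer_pair": "/".join(run.layer_pair),
                "classifier": run.classifier,
                "ranker": run.ranker,
                "context": context,
                "status": run.status,
                "mcc_o1": m1,
                "mcc_o2": m2,
                "mcc_juxt": mj,
                "mcc_rsnf": mr,
                "mcc_inf": mi,
                "delta_mcc": comp.delta_mcc,
                "nfeat_juxt": run.dap_juxt.best_nfeat,
                "nfeat_rsnf": run.dap_rsnf.best_nfeat,
                "nfeat_inf": run.dap_inf.best_nfeat if inf_ok else None,
                "inf_intersection_size": len(run.inf_feature_set),
                "prop50_juxt": prop50(run.dap_juxt.signature_ids).prop50,
                "prop50_rsnf": prop50(run.dap_rsnf.signature_ids).prop50,
                "prop50_inf": prop50(run.inf_feature_set).prop50 if inf_ok else None,
            }
            if inf_ok:
                row["scenario_vs_juxt"] = similarity_scenario(
                    mi, mj, run.dap_inf.best_nfeat, run.dap_juxt.best_nfeat
                )
                row["scenario_vs_rsnf"] = similarity_scenario(
                    mi, mr, run.dap_inf.best_nfeat, run.dap_rsnf.best_nfeat
                )
            rows.append(row)
    return pd.DataFrame(rows)
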