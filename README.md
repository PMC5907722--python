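# omicsfuse

Integrative network fusion for multi-omics patient classification, with an
autoencoder branch for survival-based patient stratification.

## The problem

Tumor cohorts are increasingly profiled on several molecular layers at once
— for example gene-level expression from RNA-Seq or microarrays together
with gene-level copy number from aCGH. Each layer alone carries predictive
signal for clinical endpoints (event-free survival, overall survival,
extreme disease course), but combining layers is where methods diverge:
naive concatenation inflates the feature space, and ad-hoc integration
easily leaks test information into feature selection. `omicsfuse` is a
toolkit for researchers who want multi-omics classifiers with honest,
reproducible performance estimates and compact, interpretable feature
signatures.

## What it implements

**A reproducible classification protocol.** Every model is developed inside
a fixed Data Analysis Protocol: a 10×5-fold stratified cross-validation on
the training split in which features are re-ranked per split (linear-SVM
weights, random-forest Gini importance, or ANOVA F score), classifiers are
evaluated along the feature grid `[5, 10, 25, 50, 75, 100, 500, 1000, 5000,
10000, NF]`, performance is measured by the Matthews correlation coefficient

```
MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
```

the 50 per-split rankings are merged by the Borda count, the signature size
is the grid point maximizing mean CV MCC (ties favor compactness), and the
retrained model is validated exactly once on the held-out test split. A
random-label scheme guards against selection bias. All fitted artifacts
(near-zero-variance filter, scalers, rankings) are derived from training
data only.

**Three integration strategies.**

* *juxt* — column-wise concatenation of two layers;
* *rSNF* — the layers' patient-similarity networks are fused by Similarity
  Network Fusion (iterative cross-diffusion of k-NN similarity kernels),
  the fused network is spectrally clustered, and features of the
  juxtaposed matrix are ranked by normalized mutual information between
  each feature's own induced partition and the fused clustering;
* *INF* — the protocol rerun on the intersection of the juxt and rSNF
  signatures; an intersection below 5 features is recorded as a failed run.

Integration benefit is summarized by ΔMCC = max(MCC over integrated
models) − max(MCC over single layers), and signature composition by Prop50,
the percentage of features contributed by the minority layer (50 =
balanced, 0 = single-layer).

**An autoencoder integration branch.** A mirrored fully-connected
autoencoder (numpy implementation: ADADELTA, mean-squared-error loss,
softsign/tanh/relu activations, optional L1 activity penalty, min-max
scaling fitted on the training split) compresses the juxtaposed matrix into
bottleneck "meta-features". Each meta-feature is screened with a univariate
Cox proportional-hazards fit (score-test p-values, Benjamini–Hochberg FDR <
0.05); K-means with the Silhouette-selected cluster count stratifies
patients on the significant meta-features into groups G1/G2, compared by
Kaplan–Meier curves and the log-rank test, and the derived groups can be
fed back to the classification protocol as a new endpoint.

**A synthetic-data generator** (`omicsfuse.simulate`) produces two-layer
bundles with planted discriminative features, controllable inter-layer
redundancy, latent survival groups with a designed hazard ratio and
censoring fraction, and injected NA/near-zero-variance pathologies — so the
entire pipeline is exercisable and testable without any external download.

## Worked example

```python
from omicsfuse import SimulationDesign, simulate_multiomics, DapConfig
from omicsfuse.inf import run_inf, run_single_layers, summarize

design = SimulationDesign(
    n_samples=100, n_features=(200, 200), n_informative=(10, 10),
    overlap_informative=5, effect_size=2.0, block_correlation=0.0,
    na_rate=0.02, nzv_rate=0.05, seed=7,
)
o1, o2, labels, split, survival, truth = simulate_multiomics(design)

cfg = DapConfig(classifier="lsvm", ranker="native", seed=7)
singles = run_single_layers(o1, o2, labels, split, cfg)
run = run_inf(o1, o2, labels, split, cfg)
table = summarize([run], [singles])
row = table[table.context == "validation"].iloc[0]
print(f"MCC val  O1/O2    {row.mcc_o1:.3f} / {row.mcc_o2:.3f}")
print(f"MCC val  juxt     {row.mcc_juxt:.3f}  (Nfeat={row.nfeat_juxt})")
print(f"MCC val  rSNF     {row.mcc_rsnf:.3f}  (Nfeat={row.nfeat_rsnf})")
print(f"MCC val  INF      {row.mcc_inf:.3f}  (Nfeat={row.nfeat_inf})")
print(f"delta MCC         {row.delta_mcc:.3f}")
print(f"Prop50 (INF)      {row.prop50_inf:.1f}")
```

prints

```
MCC val  O1/O2    0.961 / 0.920
MCC val  juxt     1.000  (Nfeat=25)
MCC val  rSNF     0.961  (Nfeat=372)
MCC val  INF      1.000  (Nfeat=25)
delta MCC         0.039
Prop50 (INF)      48.0
```

Read: each single layer classifies well on this planted-signal bundle
(MCC 0.96 / 0.92 on the external test split); integrating the layers lifts
validation MCC to 1.0 (ΔMCC = +0.039); INF matches the best integrated
performance with a feature set drawn almost evenly from both layers
(Prop50 = 48, near the balanced bound of 50) while rSNF alone needs the
whole juxtaposed feature space.

The same pipeline is available from the shell:

```
omicsfuse simulate --out bundle --seed 7
omicsfuse inf --layer1 bundle/layer1.tsv --layer2 bundle/layer2.tsv \
    --labels bundle/labels.tsv --split bundle/split.tsv --out run --seed 7
omicsfuse ae --layers bundle/layer1.tsv --layers bundle/layer2.tsv \
    --split bundle/split.tsv --out ae_run --seed 7
omicsfuse survival --encoding-tr ae_run/encoding_tr.tsv \
    --encoding-ts ae_run/encoding_ts.tsv --survival bundle/survival.tsv \
    --out surv_run
```

Every result directory carries a `manifest.json` (config, master seed,
derived stage seeds, package versions, input digests); identical manifests
reproduce identical outputs.

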