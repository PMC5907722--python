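"""Seeded synthetic multi-omics generator.

The generator emulates the statistical structure the rest of the toolkit
assumes: two omics layers (think gene-level expression and gene-level copy
number) over a shared sample set, a binary endpoint planted as a mean
shift in a subset of features of each layer, configurable redundancy
between the layers (features of layer 2 that duplicate layer-1 signal), a
latent survival grouping expressed in both layers with a designed hazard
ratio and censoring fraction, and injected data pathologies (missing
values, near-zero-variance features) for the preprocessing stage to catch.

Every draw derives from one seed, and an identical design regenerates a
bit-identical bundle. The returned truth record lists the planted feature
ids and latent groups, which is what the recovery tests in the other
modules consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._utils import DataError
from .io import EndpointLabels, OmicsLayer, SplitDefinition, SurvivalData

__all__ = ["SimulationDesign", "simulate_multiomics", "worked_fixture"]


@dataclass
class SimulationDesign:
    """Parameters of one synthetic bundle.

    Defaults mirror the matched multi-platform study setting: 145 samples
    split roughly in half, a few hundred features per layer of which a
    small fraction carries the endpoint, partial redundancy between
    layers, and a two-group latent survival structure with a hazard ratio
    of 3 and ~30% censoring.
    """

    n_samples: int = 145
    split_fraction: float = 0.5
    n_features: tuple = (500, 500)
    n_informative: tuple = (20, 20)
    overlap_informative: int = 10
    effect_size: float = 1.5
    noise_sd: float = 1.0
    block_correlation: float = 0.3
    n_survival_groups: int = 2
    n_survival_informative: tuple = (20, 20)
    survival_effect_size: float = 1.5
    hazard_ratio: float = 3.0
    censoring_rate: float = 0.3
    na_rate: float = 0.0
    nzv_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for ni, nf in zip(self.n_informative, self.n_features):
            if ni > nf:
                raise DataError("informative feature count exceeds feature count")
        if self.overlap_informative > min(self.n_informative):
            raise DataError("overlap exceeds the informative count of a layer")
        if self.hazard_ratio < 1:
            raise DataError("hazard ratio must be >= 1")
        for r in (self.split_fraction, self.censoring_rate, self.na_rate, self.nzv_rate):
            if not 0 <= r <= 1:
                raise DataError("rates must lie in [0, 1]")


def _censoring_rate_for(lams: np.ndarray, target: float) -> float:
    """Exponential censoring rate hitting the target censor fraction.

    For event rate lam and censoring rate mu, P(censored) = mu/(lam+mu);
    solve mean_g mu/(lam_g + mu) = target by bisection.
    """
    if target <= 0:
        return 0.0
    lo, hi = 1e-9, 1e9

    def frac(mu):
        return float(np.mean(mu / (lams + mu)))

    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def _informative_block(rng, latent, n_feat, effect, noise_sd, rho):
    """Features = effect * latent + correlated Gaussian noise."""
    n = latent.shape[0]
    shared = rng.normal(size=(n, 1))
    eps = rng.normal(size=(n, n_feat))
    noise = noise_sd * (math.sqrt(rho) * shared + math.sqrt(1 - rho) * eps)
    return effect * latent[:, None] + noise


def simulate_multiomics(design: SimulationDesign):
    """Generate one synthetic two-layer bundle.

    Returns ``(layer1, layer2, labels, split, survival, truth)`` where
    ``truth`` is a dict recording every planted structure.
    """
    d = design
    rng = np.random.RandomState(d.seed % (2**31))
    n = d.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # latent class (balanced) and latent survival group, drawn first
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    y = rng.permutation(y)
    surv_group = rng.randint(0, d.n_survival_groups, size=n)
    class_latent = (y - 0.5) / 1.0  # +-0.5 -> between-class shift = effect_size

    layers = []
    truth: dict = {
        "class_labels": y.tolist(),
        "survival_groups": surv_group.tolist(),
        "informative": {},
        "survival_informative": {},
        "overlap": [],
        "nzv": {},
        "na": {},
    }
    surv_latent = (surv_group - (d.n_survival_groups - 1) / 2.0) / max(
        1, d.n_survival_groups - 1
    )  # two groups -> +-0.5
    for li, (nf, ninf, nsurv) in enumerate(
        zip(d.n_features, d.n_informative, d.n_survival_informative)
    ):
        tag = f"OM{li + 1}"
        n_extra = round(d.nzv_rate * nf)
        blocks = []
        # class-informative block
        blocks.append(
            _informative_block(
                rng, class_latent, ninf, d.effect_size, d.noise_sd, d.block_correlation
            )
        )
        # survival-informative block
        blocks.append(
            _informative_block(
                rng,
                surv_latent,
                nsurv,
                d.survival_effect_size,
                d.noise_sd,
                d.block_correlation,
            )
        )
        n_noise = nf - ninf - nsurv - n_extra
        if n_noise < 0:
            raise DataError("feature budget too small for the designed blocks")
        blocks.append(rng.normal(scale=d.noise_sd, size=(n, n_noise)))
        # near-zero-variance features: overwhelmingly one value, few others
        nzv = np.zeros((n, n_extra))
        for j in range(n_extra):
            k = rng.randint(1, max(2, n // 25))
            idx = rng.choice(n, size=k, replace=False)
            nzv[idx, j] = rng.normal(loc=3.0, scale=0.1, size=k)
        blocks.append(nzv)
        values = np.hstack(blocks)
        feature_ids = [f"{tag}:f{j:05d}" for j in range(values.shape[1])]
        truth["informative"][tag] = feature_ids[:ninf]
        truth["survival_informative"][tag] = feature_ids[ninf : ninf + nsurv]
        truth["nzv"][tag] = feature_ids[ninf + nsurv + n_noise :]
        layers.append(
            OmicsLayer(tag, sample_ids, feature_ids, values)
        )

    # inter-layer redundancy: first `overlap` informative features of layer 2
    # duplicate layer 1's counterparts plus fresh noise
    if d.overlap_informative:
        src = layers[0].values[:, : d.overlap_informative]
        layers[1].values[:, : d.overlap_informative] = src + d.noise_sd * rng.normal(
            size=src.shape
        )
        truth["overlap"] = [
            (truth["informative"]["OM1"][j], truth["informative"]["OM2"][j])
            for j in range(d.overlap_informative)
        ]

    # missing values: na_rate of the features get one NA cell each
    for li, layer in enumerate(layers):
        n_na = round(d.na_rate * layer.n_features)
        cols = rng.choice(layer.n_features, size=n_na, replace=False)
        na_ids = []
        for j in cols:
            layer.values[rng.randint(n), j] = np.nan
            na_ids.append(layer.feature_ids[j])
        truth["na"][layer.layer_name] = na_ids

    # survival: exponential with group-dependent hazard, independent censoring
    base = 1.0
    lam = base * d.hazard_ratio ** (surv_group / max(1, d.n_survival_groups - 1))
    event_time = rng.exponential(1.0 / lam)
    mu = _censoring_rate_for(
        base * d.hazard_ratio ** (np.arange(d.n_survival_groups) / max(1, d.n_survival_groups - 1)),
        d.censoring_rate,
    )
    if mu > 0:
        censor_time = rng.exponential(1.0 / mu, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    # stratified TR/TS split on the class label
    tr_mask = np.zeros(n, dtype=bool)
    for c in (0, 1):
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        n_tr = int(round(d.split_fraction * idx.size))
        tr_mask[idx[:n_tr]] = True
    split = SplitDefinition(
        [s for s, m in zip(sample_ids, tr_mask) if m],
        [s for s, m in zip(sample_ids, tr_mask) if not m],
    )
    labels = EndpointLabels("SIM-CLASS", sample_ids, y)
    survival = SurvivalData(sample_ids, time, event)
    return layers[0], layers[1], labels, split, survival, truth


WORKED_FIXTURE_SEED = 20170


def worked_fixture():
    """Small deterministic bundle for hand-checkable examples.

    30 samples, two 40-feature layers with 6 informative features each
    (4 overlapping), survival groups, one NA feature and two injected
    near-zero-variance features per layer. Regenerates bit-identically.
    """
    design = SimulationDesign(
        n_samples=30,
        split_fraction=0.5,
        n_features=(40, 40),
        n_informative=(6, 6),
        overlap_informative=4,
        effect_size=2.0,
        n_survival_informative=(6, 6),
        survival_effect_size=2.0,
        hazard_ratio=3.0,
        censoring_rate=0.2,
        na_rate=0.025,
        nzv_rate=0.05,
        seed=WORKED_FIXTURE_SEED,
    )
    return simulate_multiomics(design)
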