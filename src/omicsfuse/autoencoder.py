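"""Autoencoder-based integration of a juxtaposed multi-omics matrix.

A mirrored fully-connected autoencoder compresses the juxtaposed
samples x features matrix into a low-dimensional bottleneck whose unit
activations ("meta-features") serve as derived patient-level variables for
downstream survival screening and classification.

The implementation is a self-contained numpy multilayer perceptron trained
with the ADADELTA adaptive-learning-rate rule on a mean-squared-error
reconstruction objective, optionally with an L1 activity penalty on the
bottleneck. Supported activations are tanh, softsign and relu; inputs are
min-max scaled to (0, 1) or (-1, 1) with a scaler fitted on the training
samples only. Depths 1-3 are supported; hidden widths between the input
size and the bottleneck are geometrically interpolated. The default
bottleneck is 1% of the input feature count (clipped to at least 2), and
the default architecture is the two-layer layout with activations
softsign, softsign, softsign, relu and (0, 1) scaling, which won the
architecture grid on reconstruction loss and cosine distance.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted

from ._utils import DataError, NumericalError
from .io import OmicsLayer

__all__ = [
    "AutoencoderSpec",
    "Autoencoder",
    "EncodedRepresentation",
    "train_autoencoder",
    "encode",
    "reconstruction_distance",
    "grid_search",
    "default_grid",
]

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a**2),
    "softsign": (
        lambda z: z / (1.0 + np.abs(z)),
        lambda a: (1.0 - np.abs(a)) ** 2,
    ),
    "relu": (
        lambda z: np.maximum(z, 0.0),
        lambda a: (a > 0).astype(float),
    ),
    "linear": (lambda z: z, lambda a: np.ones_like(a)),
}


@dataclass(frozen=True)
class AutoencoderSpec:
    """One point of the architecture grid.

    ``n_layers`` is the encoder depth (decoder mirrored); ``activations``
    lists one activation per weight layer, encoder first then decoder, so
    its length is ``2 * n_layers``. ``bottleneck=None`` resolves to
    ``ceil(0.01 * n_features)`` (at least 2) for depths 1-2 and to 64 for
    depth 3, capped below the input dimension.
    """

    n_layers: int = 2
    bottleneck: int | None = None
    activations: tuple = ("softsign", "softsign", "softsign", "relu")
    scaling: str = "minmax01"  # {"minmax01", "minmax11"}
    l1_penalty: float = 0.0
    epochs: int = 2500
    batch_size: int = 71
    seed: int = 0

    def __post_init__(self):
        if self.n_layers not in (1, 2, 3):
            raise DataError("encoder depth must be 1, 2 or 3")
        if len(self.activations) != 2 * self.n_layers:
            raise DataError(
                f"need {2 * self.n_layers} activations for depth {self.n_layers}"
            )
        for a in self.activations:
            if a not in _ACTIVATIONS:
                raise DataError(f"unknown activation {a!r}")
        if self.scaling not in ("minmax01", "minmax11"):
            raise DataError(f"unknown scaling {self.scaling!r}")

    def resolve_bottleneck(self, n_features: int) -> int:
        if self.bottleneck is not None:
            b = int(self.bottleneck)
        elif self.n_layers == 3:
            b = 64
        else:
            b = max(2, math.ceil(0.01 * n_features))
        if b >= n_features:
            raise DataError(
                f"bottleneck {b} must be smaller than the input dimension {n_features}"
            )
        return b

    def layer_widths(self, n_features: int) -> list[int]:
        """Geometric interpolation input -> bottleneck, mirrored back."""
        b = self.resolve_bottleneck(n_features)
        d = self.n_layers
        enc = [
            max(b, round(n_features ** (1 - i / d) * b ** (i / d)))
            for i in range(1, d + 1)
        ]
        enc[-1] = b
        return [n_features] + enc + enc[-2::-1] + [n_features]


def default_grid(l1_penalties=(0.0,)) -> list[AutoencoderSpec]:
    """The architecture grid: depths 1-3 x scalings x L1 penalties.

    Activations follow the all-softsign-but-final-relu pattern at every
    depth. Regularization penalties of 1e-6 and above are known to
    destabilize training; the default grid therefore only carries the
    unregularized variant, and callers opt in to the penalty range
    (0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1) explicitly.
    """
    grid = []
    for depth in (1, 2, 3):
        acts = ("softsign",) * (2 * depth - 1) + ("relu",)
        for scaling in ("minmax01", "minmax11"):
            for l1 in l1_penalties:
                grid.append(
                    AutoencoderSpec(
                        n_layers=depth, activations=acts, scaling=scaling, l1_penalty=l1
                    )
                )
    return grid


@dataclass
class EncodedRepresentation:
    """Bottleneck activations per sample (the meta-features)."""

    meta_features: np.ndarray
    sample_ids: list[str]
    origin: str  # {"TR", "TS"}
    spec: AutoencoderSpec


class Autoencoder(BaseEstimator, TransformerMixin):
    """Mirrored MLP autoencoder trained with ADADELTA on MSE.

    Parameters are taken from an :class:`AutoencoderSpec`; ``transform``
    returns the bottleneck encoding, ``inverse_transform`` decodes, and
    ``reconstruct`` chains the two. The min-max scaler is fitted on the
    training data only and reused verbatim for any later matrix.
    """

    def __init__(self, spec: AutoencoderSpec | None = None, rho: float = 0.95, eps: float = 1e-6):
        self.spec = spec
        self.rho = rho
        self.eps = eps

    # ------------------------------------------------------------------
    def _init_weights(self, widths, rng):
        weights, biases = [], []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return weights, biases

    def fit(self, X, y=None):
        spec = self.spec or AutoencoderSpec()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or not np.isfinite(X).all():
            raise DataError("autoencoder input must be a finite 2-D matrix")
        n, p = X.shape
        rng = np.random.RandomState(spec.seed % (2**31))
        feature_range = (0.0, 1.0) if spec.scaling == "minmax01" else (-1.0, 1.0)
        self.scaler_ = MinMaxScaler(feature_range=feature_range).fit(X)
        xs = self.scaler_.transform(X)

        widths = spec.layer_widths(p)
        self.widths_ = widths
        self.bottleneck_ = spec.resolve_bottleneck(p)
        acts = list(spec.activations)
        weights, biases = self._init_weights(widths, rng)

        # ADADELTA state
        eg = [np.zeros_like(w) for w in weights] + [np.zeros_like(b) for b in biases]
        ed = [np.zeros_like(a) for a in eg]
        batch = min(int(spec.batch_size), n)
        loss_trace = []
        bottleneck_idx = spec.n_layers - 1  # index into activation list
        for epoch in range(int(spec.epochs)):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                xb = xs[idx]
                # forward
                activations = [xb]
                for li, (w, b) in enumerate(zip(weights, biases)):
                    z = activations[-1] @ w + b
                    activations.append(_ACTIVATIONS[acts[li]][0](z))
                out = activations[-1]
                diff = out - xb
                loss = float(np.mean(diff**2))
                if spec.l1_penalty:
                    loss += spec.l1_penalty * float(
                        np.mean(np.abs(activations[bottleneck_idx + 1]))
                    )
                epoch_loss += loss * len(idx)
                # backward
                m = xb.shape[0]
                delta = (2.0 / (m * out.shape[1])) * diff
                grads_w, grads_b = [None] * len(weights), [None] * len(biases)
                for li in range(len(weights) - 1, -1, -1):
                    a_out = activations[li + 1]
                    dz = delta * _ACTIVATIONS[acts[li]][1](a_out)
                    grads_w[li] = activations[li].T @ dz
                    grads_b[li] = dz.sum(axis=0)
                    delta = dz @ weights[li].T
                    if li == bottleneck_idx + 1 and spec.l1_penalty:
                        # L1 activity penalty enters at the bottleneck output
                        bn = activations[bottleneck_idx + 1]
                        delta = delta + spec.l1_penalty * np.sign(bn) / (
                            m * bn.shape[1]
                        )
                # ADADELTA update
                params = weights + biases
                grads = grads_w + grads_b
                for i, (prm, g) in enumerate(zip(params, grads)):
                    eg[i] = self.rho * eg[i] + (1 - self.rho) * g**2
                    step = -np.sqrt(ed[i] + self.eps) / np.sqrt(eg[i] + self.eps) * g
                    ed[i] = self.rho * ed[i] + (1 - self.rho) * step**2
                    prm += step
            epoch_loss /= n
            if not np.isfinite(epoch_loss):
                raise NumericalError(
                    f"training loss diverged at epoch {epoch} "
                    f"(spec={spec}); L1 penalties >= 1e-6 are known to "
                    "destabilize training"
                )
            loss_trace.append(epoch_loss)
        self.weights_ = weights
        self.biases_ = biases
        self.activations_ = acts
        self.loss_trace_ = loss_trace
        self.final_loss_ = loss_trace[-1] if loss_trace else float("nan")
        self.spec_ = spec
        self.n_features_in_ = p
        return self

    # ------------------------------------------------------------------
    def _forward(self, xs, n_layers=None):
        a = xs
        stop = len(self.weights_) if n_layers is None else n_layers
        for li in range(stop):
            a = _ACTIVATIONS[self.activations_[li]][0](a @ self.weights_[li] + self.biases_[li])
        return a

    def transform(self, X):
        """Bottleneck encoding of a matrix, scaled with the TR scaler."""
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self._forward(self.scaler_.transform(X), self.spec_.n_layers)

    def reconstruct(self, X):
        """Full encode-decode pass, returned on the scaled data scale."""
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self._forward(self.scaler_.transform(X))


def train_autoencoder(tr_juxt: OmicsLayer, spec: AutoencoderSpec) -> Autoencoder:
    """Fit an autoencoder on the juxtaposed TR matrix."""
    return Autoencoder(spec=spec).fit(tr_juxt.values)


def encode(model: Autoencoder, layer: OmicsLayer, origin: str = "TS") -> EncodedRepresentation:
    """Bottleneck activations of a layer through a fitted model."""
    return EncodedRepresentation(
        meta_features=model.transform(layer.values),
        sample_ids=list(layer.sample_ids),
        origin=origin,
        spec=model.spec_,
    )


def reconstruction_distance(model: Autoencoder, ts_juxt: OmicsLayer, flatten: bool = False) -> float:
    """Mean cosine distance between original and reconstructed samples.

    0 indicates perfect (positively collinear) reconstruction, bounded by 2.
    ``flatten=True`` computes a single cosine distance on the flattened
    matrices instead of the per-sample average. Zero-norm rows are skipped
    with a warning.
    """
    original = model.scaler_.transform(np.asarray(ts_juxt.values, dtype=float))
    recon = model.reconstruct(ts_juxt.values)
    if flatten:
        original, recon = original.reshape(1, -1), recon.reshape(1, -1)
    norm_o = np.linalg.norm(original, axis=1)
    norm_r = np.linalg.norm(recon, axis=1)
    ok = (norm_o > 0) & (norm_r > 0)
    if not ok.all():
        warnings.warn(
            f"skipping {int((~ok).sum())} zero-norm sample(s) in cosine distance",
            stacklevel=2,
        )
    if not ok.any():
        raise DataError("no sample with nonzero norm")
    cos = np.sum(original[ok] * recon[ok], axis=1) / (norm_o[ok] * norm_r[ok])
    return float(np.mean(1.0 - cos))


def grid_search(tr_juxt: OmicsLayer, ts_juxt: OmicsLayer, grid) -> list[dict]:
    """Train every spec of the grid and rank the outcomes.

    Specs are ordered by (final training loss, TS cosine distance); a run
    whose loss diverges is kept, flagged ``diverged`` and ranked last.
    """
    grid = list(grid)
    if not grid:
        raise DataError("empty architecture grid")
    records = []
    for spec in grid:
        try:
            model = train_autoencoder(tr_juxt, spec)
            records.append(
                {
                    "spec": spec,
                    "model": model,
                    "final_loss": model.final_loss_,
                    "cosine_distance": reconstruction_distance(model, ts_juxt),
                    "diverged": False,
                }
            )
        except NumericalError:
            records.append(
                {
                    "spec": spec,
                    "model": None,
                    "final_loss": float("nan"),
                    "cosine_distance": float("nan"),
                    "diverged": True,
                }
            )
    if all(r["diverged"] for r in records):
        raise NumericalError("every architecture in the grid diverged")
    records.sort(
        key=lambda r: (
            r["diverged"],
            r["final_loss"] if np.isfinite(r["final_loss"]) else np.inf,
            r["cosine_distance"] if np.isfinite(r["cosine_distance"]) else np.inf,
        )
    )
    return records
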