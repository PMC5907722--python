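"""Core data containers and text-format readers/writers.

All on-disk formats are UTF-8 tab-separated text with a header row:

* omics matrix — first row feature ids, first column sample ids
  (``orientation="features_rows"`` reads the transposed layout);
* label file — columns ``sample_id``, ``label`` with labels in {0, 1};
* split file — columns ``sample_id``, ``set`` with values ``TR``/``TS``;
* survival file — columns ``sample_id``, ``time``, ``event``;
* ranked feature list — columns ``feature_id``, ``score``, best first.

Samples are always aligned by identifier, never by position. Feature ids
are prefixed with their layer tag (``"LAYER:feature"``) so that layer
membership survives juxtaposition; this is what makes per-layer
contribution statistics (mixedness) computable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import DataError

__all__ = [
    "OmicsLayer",
    "EndpointLabels",
    "SplitDefinition",
    "SurvivalData",
    "RankedFeatureList",
    "read_omics_matrix",
    "write_omics_matrix",
    "juxtapose",
    "read_labels",
    "write_labels",
    "read_split",
    "write_split",
    "read_survival",
    "write_survival",
    "read_ranked_list",
    "write_ranked_list",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    dupes = sorted({i for i in ids if i in seen or seen.add(i)})
    if dupes:
        raise DataError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class OmicsLayer:
    """One samples x features matrix — the unit of integration.

    Feature ids are globally prefixed with ``layer_name`` followed by a
    colon. ``values`` may contain NaN before preprocessing; after NA
    filtering every entry is finite.
    """

    layer_name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if self.values.size == 0:
            raise DataError("empty omics matrix")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.feature_ids, "feature ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, ids: Sequence[str]) -> "OmicsLayer":
        """Row subset aligned to ``ids`` (order taken from ``ids``)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise DataError(f"samples absent from layer {self.layer_name!r}: {missing[:5]}")
        rows = [index[s] for s in ids]
        return OmicsLayer(self.layer_name, list(ids), list(self.feature_ids), self.values[rows])

    def subset_features(self, ids: Sequence[str]) -> "OmicsLayer":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in index]
        if missing:
            raise DataError(f"features absent from layer {self.layer_name!r}: {missing[:5]}")
        cols = [index[f] for f in ids]
        return OmicsLayer(self.layer_name, list(self.sample_ids), list(ids), self.values[:, cols])


@dataclass
class EndpointLabels:
    """Binary endpoint labels (e.g. event-free survival status) per sample."""

    endpoint_name: str
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        _check_unique(self.sample_ids, "sample ids")
        if self.labels.shape != (len(self.sample_ids),):
            raise DataError("one label per sample id required")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise DataError(f"labels must be binary 0/1, found {sorted(bad)}")

    def loc(self, ids: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise DataError(f"samples without label: {missing[:5]}")
        return self.labels[[index[s] for s in ids]]


@dataclass
class SplitDefinition:
    """Disjoint train (TR) and test (TS) sample id sets."""

    train_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        self.train_ids = [str(s) for s in self.train_ids]
        self.test_ids = [str(s) for s in self.test_ids]
        _check_unique(self.train_ids, "train ids")
        _check_unique(self.test_ids, "test ids")
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise DataError(f"TR and TS overlap: {sorted(overlap)[:5]}")


@dataclass
class SurvivalData:
    """Right-censored follow-up: time and event indicator per sample."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        _check_unique(self.sample_ids, "sample ids")
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise DataError("time and event must align with sample ids")
        if np.any(self.time < 0):
            raise DataError("negative follow-up time")
        if set(np.unique(self.event)) - {0, 1}:
            raise DataError("event indicator must be 0/1")

    def loc(self, ids: Sequence[str]) -> "SurvivalData":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise DataError(f"samples without survival data: {missing[:5]}")
        rows = [index[s] for s in ids]
        return SurvivalData(list(ids), self.time[rows], self.event[rows])


@dataclass
class RankedFeatureList:
    """Features ordered best-first with their relevance scores."""

    feature_ids: list[str]
    scores: np.ndarray
    ranker_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.scores = np.asarray(self.scores, dtype=float)
        _check_unique(self.feature_ids, "feature ids")
        if self.scores.shape != (len(self.feature_ids),):
            raise DataError("scores must align with feature ids")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def top(self, k: int) -> list[str]:
        return self.feature_ids[:k]


# ---------------------------------------------------------------------------
# readers / writers


def read_omics_matrix(path, layer_name: str, orientation: str = "samples_rows") -> OmicsLayer:
    """Read a tab-separated omics matrix.

    Non-numeric cells (e.g. ``NA``) are parsed as missing values and left to
    the preprocessing stage. Feature ids are prefixed with ``layer_name``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "features_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"empty omics matrix in {path}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    prefix = f"{layer_name}:"
    feature_ids = [c if c.startswith(prefix) else prefix + c for c in df.columns]
    return OmicsLayer(layer_name, list(df.index), feature_ids, values)


def write_omics_matrix(layer: OmicsLayer, path) -> None:
    layer.to_frame().to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def juxtapose(a: OmicsLayer, b: OmicsLayer) -> OmicsLayer:
    """Column-wise concatenation of two layers aligned on sample ids."""
    sa, sb = set(a.sample_ids), set(b.sample_ids)
    if sa != sb:
        only_a, only_b = sorted(sa - sb), sorted(sb - sa)
        raise DataError(
            f"sample sets differ: only in {a.layer_name!r}: {only_a[:5]}; "
            f"only in {b.layer_name!r}: {only_b[:5]}"
        )
    b_aligned = b.subset_samples(a.sample_ids)
    return OmicsLayer(
        f"{a.layer_name}/{b.layer_name}",
        list(a.sample_ids),
        list(a.feature_ids) + list(b_aligned.feature_ids),
        np.hstack([a.values, b_aligned.values]),
    )


def _read_table(path, columns: tuple[str, ...]):
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[: len(columns)]) != list(columns):
        raise DataError(f"{path}: expected header columns {columns}, found {tuple(df.columns)}")
    return df


def read_labels(path, endpoint_name: str | None = None) -> EndpointLabels:
    df = _read_table(path, ("sample_id", "label"))
    return EndpointLabels(
        endpoint_name or "endpoint", list(df["sample_id"]), df["label"].astype(int).to_numpy()
    )


def write_labels(labels: EndpointLabels, path) -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_split(path) -> SplitDefinition:
    df = _read_table(path, ("sample_id", "set"))
    bad = set(df["set"]) - {"TR", "TS"}
    if bad:
        raise DataError(f"{path}: split values must be TR/TS, found {sorted(bad)}")
    return SplitDefinition(
        list(df.loc[df["set"] == "TR", "sample_id"]),
        list(df.loc[df["set"] == "TS", "sample_id"]),
    )


def write_split(split: SplitDefinition, path) -> None:
    pd.DataFrame(
        {
            "sample_id": split.train_ids + split.test_ids,
            "set": ["TR"] * len(split.train_ids) + ["TS"] * len(split.test_ids),
        }
    ).to_csv(path, sep="\t", index=False)


def read_survival(path) -> SurvivalData:
    df = _read_table(path, ("sample_id", "time", "event"))
    return SurvivalData(
        list(df["sample_id"]),
        df["time"].astype(float).to_numpy(),
        df["event"].astype(int).to_numpy(),
    )


def write_survival(surv: SurvivalData, path) -> None:
    pd.DataFrame(
        {"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event}
    ).to_csv(path, sep="\t", index=False)


def write_ranked_list(ranked: RankedFeatureList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"feature_id\tscore\t# ranker={ranked.ranker_tag}\n")
        for fid, score in zip(ranked.feature_ids, ranked.scores):
            fh.write(f"{fid}\t{float(score)!r}\n")


def read_ranked_list(path) -> RankedFeatureList:
    feature_ids: list[str] = []
    scores: list[float] = []
    ranker_tag = "unknown"
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["feature_id", "score"]:
            raise DataError(f"{path}:1: expected 'feature_id\\tscore' header")
        if len(header) > 2 and header[2].startswith("# ranker="):
            ranker_tag = header[2].split("=", 1)[1]
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected 2 tab-separated fields")
            try:
                score = float(parts[1])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-numeric score {parts[1]!r}") from exc
            if parts[0] in feature_ids:
                raise DataError(f"{path}:{lineno}: duplicated feature {parts[0]!r}")
            feature_ids.append(parts[0])
            scores.append(score)
    return RankedFeatureList(feature_ids, np.array(scores), ranker_tag)


def layer_of(feature_id: str) -> str:
    """Layer tag encoded in a prefixed feature id (``"LAYER:feature"``)."""
    if ":" not in feature_id:
        raise DataError(f"feature id {feature_id!r} carries no layer prefix")
    return feature_id.split(":", 1)[0]
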