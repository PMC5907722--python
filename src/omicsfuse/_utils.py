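"""Shared helpers: seed fan-out, ordering, and error types."""

from __future__ import annotations

import hashlib


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class NumericalError(RuntimeError):
    """A numerical procedure failed, e.g. diverging loss (CLI exit code 4)."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from a master seed.

    Hash-based fan-out: adding a new stage never shifts the random stream of
    any existing stage. The result is always in ``[0, 2**31)``.
    """
    digest = hashlib.blake2b(
        f"{int(master_seed)}:{stage}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def rank_order(feature_ids, scores):
    """Indices sorting features by decreasing score, ties broken by id.

    Lexicographic tie-breaking keeps rankings deterministic across
    platforms and input orderings.
    """
    order = sorted(range(len(feature_ids)), key=lambda i: (-scores[i], feature_ids[i]))
    return order
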