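"""Deterministic hierarchical seeding.

A single run-level seed is split per named stage so that adding a stage (or
running stages separately) never perturbs the random stream of another stage.
Stage seeds are kept below 2**31 so they can be echoed into output metadata
and re-used as plain integers.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(seed: int, *labels: object) -> int:
    """Derive a child seed for a named stage from a run-level seed.

    The derivation is a SHA-256 hash of the label path and the parent seed,
    reduced modulo 2**31 — stable across platforms and Python versions
    (unlike ``hash``).
    """
    key = "/".join(str(x) for x in labels) + f"::{int(seed)}"
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def stage_rng(seed: int, *labels: object) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded for the given stage."""
    return np.random.default_rng(stage_seed(seed, *labels))
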