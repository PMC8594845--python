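"""Deterministic seeding with named child streams.

Every stochastic operation in the package takes a :class:`SimulationSeed`,
a (root seed, stream label) pair. The same pair always yields a
bit-identical random stream, and distinct labels yield statistically
independent streams, so pipeline stages can be re-run in isolation
without perturbing one another.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

__all__ = ["SimulationSeed"]


def _label_entropy(label: str) -> int:
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


@dataclass(frozen=True)
class SimulationSeed:
    """Root seed plus a stream label identifying one random stream."""

    seed: int
    stream_label: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ValueError(f"seed must be a nonnegative integer, got {self.seed!r}")

    def child(self, label: str) -> "SimulationSeed":
        """Derive a sub-stream; labels compose like paths."""
        combined = f"{self.stream_label}/{label}" if self.stream_label else label
        return SimulationSeed(self.seed, combined)

    def rng(self) -> np.random.Generator:
        """A fresh generator for this (seed, label) pair."""
        entropy = [int(self.seed)]
        if self.stream_label:
            entropy.append(_label_entropy(self.stream_label))
        return np.random.default_rng(np.random.SeedSequence(entropy))
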