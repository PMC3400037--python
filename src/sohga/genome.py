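"""Bit-string encoding of model-building decisions and the GA string operators.

Each model decision occupies a fixed slice of the concatenated genome: a
slot with *c* options uses ceil(log2 c) bits and decodes by interpreting
the slice as an integer modulo *c*.  The modulo rule makes decoding
total — every bit pattern assembles into a structurally valid model —
at the cost of slightly overweighting early options of slots whose
option count is not a power of two.

Operators follow the classical single-point-prefix conventions: a
crossover swaps the first N bits of a parent pair with N uniform on
{1, …, L−1}; mutation flips each bit independently at the configured
per-bit rate; the downhill neighborhood of a genome is its L one-bit
flips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Callable

import numpy as np

from .model_spec import CovariateEffect, ModelSpec

__all__ = [
    "DecisionSlot",
    "SearchSpace",
    "decode",
    "encode",
    "crossover",
    "mutate",
    "hamming",
    "one_bit_neighbors",
    "random_genome",
    "build_covariate_space",
]


@dataclass(frozen=True)
class DecisionSlot:
    """One model decision: a named, ordered list of outcomes."""

    name: str
    options: tuple[Any, ...]

    def __post_init__(self) -> None:
        if len(self.options) < 1:
            raise ValueError("a slot needs at least one option")

    @property
    def width(self) -> int:
        return math.ceil(math.log2(len(self.options))) if len(self.options) > 1 else 0

    def decode_index(self, bits: str) -> int:
        if self.width == 0:
            return 0
        return int(bits, 2) % len(self.options)


@dataclass
class SearchSpace:
    """Ordered decision slots plus the rule assembling choices into a model."""

    slots: tuple[DecisionSlot, ...]
    assemble: Callable[[list[Any]], ModelSpec]

    def __post_init__(self) -> None:
        self.slots = tuple(self.slots)
        if self.total_bits == 0:
            raise ValueError("search space has no bits to search over")

    @property
    def total_bits(self) -> int:
        return sum(s.width for s in self.slots)

    def choices(self, genome: str) -> list[int]:
        """Per-slot option indices decoded from the genome."""
        if len(genome) != self.total_bits:
            raise ValueError(
                f"genome length {len(genome)} != search-space width {self.total_bits}")
        out, pos = [], 0
        for slot in self.slots:
            out.append(slot.decode_index(genome[pos:pos + slot.width]))
            pos += slot.width
        return out


def decode(genome: str, space: SearchSpace) -> ModelSpec:
    """Deterministically assemble the candidate model a genome encodes."""
    idx = space.choices(genome)
    return space.assemble([slot.options[i] for slot, i in zip(space.slots, idx)])


def encode(choices: list[int], space: SearchSpace) -> str:
    """Canonical (smallest-code) genome for explicit per-slot choices."""
    if len(choices) != len(space.slots):
        raise ValueError("one choice per slot required")
    parts = []
    for slot, i in zip(space.slots, choices):
        if not 0 <= i < len(slot.options):
            raise ValueError(f"choice {i} out of range for slot {slot.name!r}")
        parts.append(format(i, f"0{slot.width}b") if slot.width else "")
    return "".join(parts)


def crossover(p1: str, p2: str, rng: np.random.Generator) -> tuple[str, str]:
    """Single prefix swap: the first N bits exchanged, N uniform on {1,…,L−1}."""
    if len(p1) != len(p2):
        raise ValueError("parents must have equal length")
    L = len(p1)
    if L < 2:
        raise ValueError("crossover needs at least 2 bits")
    n = int(rng.integers(1, L))
    return p2[:n] + p1[n:], p1[:n] + p2[n:]


def mutate(g: str, rate: float, rng: np.random.Generator) -> str:
    """Flip each bit independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must be a probability")
    flips = rng.random(len(g)) < rate
    if not flips.any():
        return g
    bits = np.frombuffer(g.encode(), dtype=np.uint8).copy()
    bits[flips] ^= 1  # '0' (48) <-> '1' (49)
    return bits.tobytes().decode()


def hamming(g1: str, g2: str) -> int:
    """Number of differing bit positions."""
    if len(g1) != len(g2):
        raise ValueError("genomes must have equal length")
    return sum(a != b for a, b in zip(g1, g2))


def one_bit_neighbors(g: str) -> list[str]:
    """All L genomes differing from ``g`` at exactly one bit."""
    flip = {"0": "1", "1": "0"}
    return [g[:i] + flip[g[i]] + g[i + 1:] for i in range(len(g))]


def random_genome(L: int, rng: np.random.Generator) -> str:
    return "".join("1" if b else "0" for b in rng.integers(0, 2, size=L))


def build_covariate_space(
    base_spec: ModelSpec,
    candidates: list[tuple[str, str, tuple[str, ...], Any]],
    n_categories: dict[str, int] | None = None,
) -> SearchSpace:
    """The standard covariate-identification search space.

    One slot per (structural parameter, covariate) pair with options
    ``("none",) + forms``; the structure, IIV and residual of
    ``base_spec`` are fixed, mirroring a search where only covariate
    inclusion and functional form are open decisions.

    ``candidates`` lists (target, covariate, forms, reference); slot
    order fixes the order in which selected effects apply.
    """
    n_categories = n_categories or {}
    slots = []
    for target, covariate, forms, reference in candidates:
        options: list[CovariateEffect | None] = [None]
        for form in forms:
            options.append(CovariateEffect(
                target=target, covariate=covariate, kind=form,
                reference=reference,
                n_categories=n_categories.get(covariate, 2),
            ))
        slots.append(DecisionSlot(name=f"{target}~{covariate}", options=tuple(options)))

    def assemble(picked: list[CovariateEffect | None]) -> ModelSpec:
        spec = base_spec
        for eff in picked:
            if eff is not None:
                spec = spec.with_effect(eff)
        return spec.fill_defaults()

    return SearchSpace(slots=tuple(slots), assemble=assemble)
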