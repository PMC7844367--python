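"""Directed gene pairs, stable-pair sets and reversal signatures.

A directed pair asserts a within-sample ordering between two genes
("gene_a greater/less than gene_b"). Pairs are stored canonically with
gene_a < gene_b lexicographically; a pair supplied the other way round is
normalized by swapping the ids and flipping the direction, so one unordered
pair has exactly one canonical representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import ValidationError

GREATER = "greater"
LESS = "less"
DIRECTIONS = (GREATER, LESS)


def flip(direction: str) -> str:
    return LESS if direction == GREATER else GREATER


@dataclass(frozen=True)
class DirectedGenePair:
    gene_a: str
    gene_b: str
    direction: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"gene pair with identical genes: {self.gene_a!r}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(
                f"unknown direction {self.direction!r}; accepted tokens: {', '.join(DIRECTIONS)}"
            )
        if self.gene_a > self.gene_b:  # normalize to canonical order
            object.__setattr__(self, "direction", flip(self.direction))
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)

    @property
    def key(self) -> tuple[str, str]:
        """Canonical unordered-pair key."""
        return (self.gene_a, self.gene_b)

    def reversed(self) -> "DirectedGenePair":
        return DirectedGenePair(self.gene_a, self.gene_b, flip(self.direction))


@dataclass(frozen=True)
class StablePairParams:
    """Stability threshold: minimum fraction of evaluable samples that must
    share one ordering for the pair to count as stable. Must exceed 0.5 or
    both directions could qualify simultaneously."""

    threshold: float = 0.9

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold <= 1.0:
            raise ValidationError(
                f"threshold must be in (0.5, 1.0], got {self.threshold}"
            )


@dataclass(frozen=True)
class StablePairEntry:
    pair: DirectedGenePair
    frequency: float
    n_evaluable: int


@dataclass
class StablePairSet:
    """Pairs whose ordering holds in at least ``params.threshold`` of a
    cohort's evaluable samples, with the observed frequencies."""

    cohort_label: str
    params: StablePairParams
    entries: list[StablePairEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [e.pair.key for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate unordered pair in stable set")
        for e in self.entries:
            if e.frequency < self.params.threshold:
                raise ValidationError(
                    f"entry {e.pair.key} frequency {e.frequency} below threshold"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[StablePairEntry]:
        return iter(self.entries)

    def direction_by_key(self) -> dict[tuple[str, str], str]:
        return {e.pair.key: e.pair.direction for e in self.entries}


@dataclass
class ReversalSignature:
    """Directed pairs storing the cancer-class ordering.

    Each entry's direction is the within-sample ordering that characterizes
    the cancer class; a sample agreeing with many entries resembles cancer.
    """

    entries: list[DirectedGenePair] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [p.key for p in self.entries]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate unordered pair in signature")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[DirectedGenePair]:
        return iter(self.entries)

    def direction_by_key(self) -> dict[tuple[str, str], str]:
        return {p.key: p.direction for p in self.entries}

    def genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.entries:
            out.add(p.gene_a)
            out.add(p.gene_b)
        return out

    def sorted(self) -> "ReversalSignature":
        """Deterministic lexicographic ordering for reproducible files."""
        return ReversalSignature(
            sorted(self.entries, key=lambda p: p.key), self.provenance
        )

    def reversed(self) -> "ReversalSignature":
        return ReversalSignature([p.reversed() for p in self.entries], self.provenance)


def signature_from_keys(
    keys: Iterable[tuple[str, str]], directions: dict[tuple[str, str], str], provenance: str = ""
) -> ReversalSignature:
    return ReversalSignature(
        [DirectedGenePair(a, b, directions[(a, b)]) for a, b in keys], provenance
    )
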