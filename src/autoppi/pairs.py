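"""Canonical protein pairs.

A protein pair is undirected: (a, b) and (b, a) denote the same
interaction.  Throughout the package pairs are stored canonically as a
tuple ``(a, b)`` with ``a < b`` under lexicographic string order, and
self-pairs are rejected — the localization negative rule and all four
evidence features are undefined for a protein paired with itself.
"""

from __future__ import annotations

from dataclasses import dataclass

Pair = tuple[str, str]

POSITIVE = "positive"
NEGATIVE = "negative"


class SelfPairError(ValueError):
    """Raised when the two members of a pair are the same protein."""


def canonical_pair(a: str, b: str) -> Pair:
    """Return the canonical (lexicographically ordered) form of a pair.

    Raises
    ------
    SelfPairError
        If ``a == b`` after stripping whitespace.
    ValueError
        If either identifier is empty.
    """
    a, b = str(a).strip(), str(b).strip()
    if not a or not b:
        raise ValueError(f"empty protein identifier in pair ({a!r}, {b!r})")
    if a == b:
        raise SelfPairError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def canonicalize_pairs(pairs) -> set[Pair]:
    """Canonicalize an iterable of 2-tuples, dropping duplicates."""
    return {canonical_pair(a, b) for a, b in pairs}


@dataclass(frozen=True)
class PairRecord:
    """A canonical pair with an optional class label and score."""

    protein_a: str
    protein_b: str
    label: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        a, b = canonical_pair(self.protein_a, self.protein_b)
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)
        if self.label is not None and self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be {POSITIVE!r} or {NEGATIVE!r}, got {self.label!r}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def pair(self) -> Pair:
        return (self.protein_a, self.protein_b)
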