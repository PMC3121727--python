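"""Genome and feature containers shared by every pipeline stage.

Coordinates are 0-based half-open throughout the library; GFF3 output
converts to 1-based closed intervals at the file boundary.  Plant
mitochondrial genomes are circular, so a feature may wrap the origin;
a wrapped feature is stored with ``wraps=True`` and ``end`` giving the
unwrapped endpoint ``start + length`` (which exceeds the genome length).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

FEATURE_CATEGORIES = frozenset(
    {"housekeeping", "iorf", "te_fragment", "background_control", "duplication"}
)


@dataclass(frozen=True)
class Feature:
    """A typed genomic interval (known gene, iORF, TE fragment, ...)."""

    id: str
    start: int
    end: int
    strand: str = "."
    category: str = "iorf"
    wraps: bool = False
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.category not in FEATURE_CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.id}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        """1-bp-or-more overlap with a linear interval [start, end)."""
        return self.start < end and start < self.end

    def contains_interval(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class AnnotatedGenome:
    """A (usually circular) genome sequence plus typed features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("feature ids must be unique")
        n = len(self.sequence)
        for f in self.features:
            if f.start < 0 or f.start >= n:
                raise ValueError(f"feature {f.id} start {f.start} outside genome")
            if not f.wraps and f.end > n:
                raise ValueError(f"feature {f.id} end {f.end} outside linear bounds")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end); wraps the origin on circular genomes."""
        n = len(self.sequence)
        if end <= n and start >= 0:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError(f"interval [{start}, {end}) outside linear genome")
        start %= n
        span = end - (start + n if end <= start else start)
        if end <= start:
            end = start + span
        out = []
        pos = start
        remaining = end - start
        while remaining > 0:
            take = min(remaining, n - pos)
            out.append(self.sequence[pos : pos + take])
            remaining -= take
            pos = 0
        return "".join(out)

    def features_of(self, category: str) -> list[Feature]:
        return [f for f in self.features if f.category == category]

    def with_features(self, features: list[Feature]) -> "AnnotatedGenome":
        g = AnnotatedGenome(self.id, self.sequence, self.circular, list(features))
        return g


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


__all__ = ["AnnotatedGenome", "Feature", "FEATURE_CATEGORIES", "revcomp", "replace"]
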