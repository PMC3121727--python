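"""Probe design over a duplication-masked (non-redundant) genome.

Plant mitochondrial genomes carry large (>10 kb) exact duplications.
Tiling both copies wastes probes and makes signals ambiguous, so the
design stage first collapses every long exact repeat to its leftmost
copy, tiles 60-mers at 2-bp start intervals on both strands over the
concatenated non-redundant sequence, and finally re-maps each probe
onto every genomic copy of its target.

The circular tiling convention places one probe start every ``step``
bases per strand with wrap-around, so an L-bp non-redundant sequence
at step 2 yields exactly L/2 starts per strand and L probes in total
over both strands — the arithmetic that makes a 374,866-bp target
carry 374,866 probes.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .genome import AnnotatedGenome, revcomp

log = logging.getLogger(__name__)

_SEED_K = 64  # seed k-mer for repeat detection; any repeat > min_len >> 64 contains one


class MappingError(ValueError):
    pass


@dataclass(frozen=True)
class DuplicateLink:
    """An exact repeat: the kept (leftmost) interval and one discarded copy."""

    kept_start: int
    kept_end: int
    copy_start: int
    copy_end: int
    orientation: str  # '+' direct repeat, '-' inverted repeat

    @property
    def length(self) -> int:
        return self.kept_end - self.kept_start


@dataclass
class NonRedundantMap:
    """Kept segments of the full genome plus links to discarded repeat copies."""

    genome_length: int
    segments: list[tuple[int, int]]
    links: list[DuplicateLink] = field(default_factory=list)

    def __post_init__(self):
        self.segments = sorted(self.segments)
        for (a0, a1), (b0, b1) in zip(self.segments, self.segments[1:]):
            if b0 < a1:
                raise ValueError("kept segments overlap")
        # offset of each segment in the concatenated non-redundant sequence
        self._nr_offsets = []
        off = 0
        for s, e in self.segments:
            self._nr_offsets.append(off)
            off += e - s
        self._nr_length = off

    @property
    def nr_length(self) -> int:
        return self._nr_length

    @property
    def discarded_length(self) -> int:
        return self.genome_length - self._nr_length

    def nr_sequence(self, genome: AnnotatedGenome) -> str:
        return "".join(genome.sequence[s:e] for s, e in self.segments)

    def nr_to_genome(self, nr_pos: int) -> int:
        """Full-genome coordinate of a non-redundant coordinate."""
        nr_pos %= self._nr_length
        i = bisect_right(self._nr_offsets, nr_pos) - 1
        s, e = self.segments[i]
        return s + (nr_pos - self._nr_offsets[i])

    def genome_positions(self, nr_start: int, length: int) -> list[int]:
        """Every full-genome start of a probe footprint, including repeat copies.

        The footprint is anchored at the genome position of its start; a
        footprint whose start lies inside a linked kept interval is also
        reported at the corresponding position in each discarded copy
        (mirrored for inverted repeats).
        """
        g = self.nr_to_genome(nr_start)
        positions = [g]
        for link in self.links:
            if link.kept_start <= g and g + length <= link.kept_end:
                off = g - link.kept_start
                if link.orientation == "+":
                    positions.append(link.copy_start + off)
                else:
                    positions.append(link.copy_end - off - length)
        return positions


def identity_map(genome: AnnotatedGenome) -> NonRedundantMap:
    return NonRedundantMap(len(genome), [(0, len(genome))], [])


# ---------------------------------------------------------------------------
# Repeat detection


def _maximal_match(seq: str, i: int, j: int) -> tuple[int, int]:
    """Maximal exact direct match around aligned positions i < j.

    Returns (start_at_i, length).
    """
    n = len(seq)
    d = j - i
    a, b = i, j
    while a > 0 and b > 0 and seq[a - 1] == seq[b - 1]:
        a -= 1
        b -= 1
    e = i
    while e < n and e + d < n and seq[e] == seq[e + d]:
        e += 1
    _ = b
    return a, e - a


def _find_direct_repeats(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal exact direct repeats longer than min_len as (posA, posB, length)."""
    n = len(seq)
    k = min(_SEED_K, max(min_len // 2, 8))
    index: dict = {}
    for i in range(0, n - k + 1):
        index.setdefault(hash(seq[i : i + k]), []).append(i)
    found = []
    seen: dict[int, list[tuple[int, int]]] = {}  # diagonal -> covered (start,end)
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                if seq[i : i + k] != seq[j : j + k]:
                    continue  # hash collision
                d = j - i
                covered = seen.get(d, [])
                if any(s <= i < e for s, e in covered):
                    continue
                a, length = _maximal_match(seq, i, j)
                seen.setdefault(d, []).append((a, a + length))
                if length > min_len and d >= length:
                    # d < length would mean the two copies overlap (tandem);
                    # overlapping copies cannot be masked independently
                    found.append((a, a + d, length))
    return found


def _find_inverted_repeats(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """Maximal exact inverted repeats as (posA, posB, length), posA < posB."""
    n = len(seq)
    k = min(_SEED_K, max(min_len // 2, 8))
    rc = revcomp(seq)
    index: dict = {}
    for i in range(0, n - k + 1):
        index.setdefault(hash(seq[i : i + k]), []).append(i)
    found = []
    seen: dict[int, list[tuple[int, int]]] = {}  # anti-diagonal -> covered
    for j in range(0, n - k + 1):
        for i in index.get(hash(rc[j : j + k]), ()):
            if seq[i : i + k] != rc[j : j + k]:
                continue
            # seq[i:i+k] == revcomp(seq)[j:j+k]; extend maximally in (seq, rc)
            a, b = i, j
            while a > 0 and b > 0 and seq[a - 1] == rc[b - 1]:
                a -= 1
                b -= 1
            e = i
            f = j
            while e < n and f < n and seq[e] == rc[f]:
                e += 1
                f += 1
            length = e - a
            anti = a + b
            covered = seen.get(anti, [])
            if any(s <= a < t for s, t in covered):
                continue
            seen.setdefault(anti, []).append((a, e))
            # rc interval [b, b+length) maps to seq interval [n-b-length, n-b)
            other = n - b - length
            lo, hi = sorted((a, other))
            if length > min_len and hi >= lo + length:
                # hi >= lo + length excludes self-matching palindromes and
                # overlapping copies, which cannot be masked independently
                found.append((lo, hi, length))
    return found


def mask_duplications(genome: AnnotatedGenome, min_len: int = 10_000) -> NonRedundantMap:
    """Collapse exact repeats longer than ``min_len`` to their leftmost copy.

    Repeats are found as exact maximal matches in both orientations and
    resolved greedily longest-first; for each resolved repeat the leftmost
    copy is kept and the other copy discarded.  A genome with no long
    repeat returns the identity map.  Repeats spanning the circular origin
    are not searched.
    """
    seq = genome.sequence
    if not seq:
        raise ValueError("empty genome sequence")
    candidates = [(a, b, ln, "+") for a, b, ln in _find_direct_repeats(seq, min_len)]
    candidates += [(a, b, ln, "-") for a, b, ln in _find_inverted_repeats(seq, min_len)]
    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))

    discarded: list[tuple[int, int]] = []
    links: list[DuplicateLink] = []

    def overlaps_discarded(s, e):
        return any(s < de and ds < e for ds, de in discarded)

    for a, b, ln, orient in candidates:
        if overlaps_discarded(a, a + ln) or overlaps_discarded(b, b + ln):
            continue
        discarded.append((b, b + ln))
        links.append(DuplicateLink(a, a + ln, b, b + ln, orient))

    discarded.sort()
    segments = []
    pos = 0
    for s, e in discarded:
        if s > pos:
            segments.append((pos, s))
        pos = e
    if pos < len(seq):
        segments.append((pos, len(seq)))
    if not discarded:
        segments = [(0, len(seq))]
    return NonRedundantMap(len(seq), segments, links)


# ---------------------------------------------------------------------------
# Tiling


def probe_id(nr_start: int, strand: str) -> str:
    return f"p{nr_start:08d}{'f' if strand == '+' else 'r'}"


@dataclass
class ProbeSet:
    """Tiling probes over the non-redundant sequence.

    ``nr_start`` is the 0-based start on the concatenated non-redundant
    sequence; strand '-' probes are the reverse complement of the same
    footprint.  ``genome_positions`` (populated by :func:`remap_probes`)
    lists each probe's footprint start in every copy on the full genome.
    """

    nr_starts: np.ndarray  # int64, one entry per probe
    strands: np.ndarray  # unicode '+'/'-'
    probe_length: int
    step: int
    circular: bool
    nr_sequence: str
    nr_map: NonRedundantMap
    genome_positions: list[list[int]] | None = None

    def __len__(self) -> int:
        return len(self.nr_starts)

    @property
    def probe_ids(self) -> list[str]:
        return [probe_id(int(s), st) for s, st in zip(self.nr_starts, self.strands)]

    def sequence_of(self, i: int) -> str:
        start = int(self.nr_starts[i])
        L = len(self.nr_sequence)
        end = start + self.probe_length
        if end <= L:
            s = self.nr_sequence[start:end]
        else:  # circular wrap
            s = self.nr_sequence[start:] + self.nr_sequence[: end - L]
        return s if self.strands[i] == "+" else revcomp(s)

    def footprint(self, i: int) -> tuple[int, int]:
        start = int(self.nr_starts[i])
        return start, start + self.probe_length


def tile_probes(
    nr_map: NonRedundantMap,
    genome: AnnotatedGenome,
    probe_length: int = 60,
    step: int = 2,
    strands: str = "both",
    circular: bool = True,
) -> ProbeSet:
    """Tile probes at ``step``-bp start intervals over the non-redundant sequence.

    Circular mode wraps probe footprints around the junction, giving one
    start every ``step`` bp per strand (L/step starts for L divisible by
    step).  Linear mode tiles each kept segment independently; a segment
    shorter than ``probe_length`` yields no probes (logged).
    """
    if not (probe_length > step > 0):
        raise ValueError("require probe_length > step > 0")
    strand_list = {"both": ["+", "-"], "+": ["+"], "-": ["-"]}[strands]
    nr_seq = nr_map.nr_sequence(genome)
    L = len(nr_seq)

    if circular:
        starts = np.arange(0, L, step, dtype=np.int64)
    else:
        starts_parts = []
        for seg_idx, (s, e) in enumerate(nr_map.segments):
            off = nr_map._nr_offsets[seg_idx]
            seg_len = e - s
            if seg_len < probe_length:
                log.warning(
                    "segment %d (%d bp) shorter than probe length %d: no probes",
                    seg_idx, seg_len, probe_length,
                )
                continue
            n_probes = (seg_len - probe_length) // step + 1
            starts_parts.append(off + np.arange(n_probes, dtype=np.int64) * step)
        starts = (
            np.concatenate(starts_parts) if starts_parts else np.empty(0, np.int64)
        )

    all_starts = np.concatenate([starts for _ in strand_list]) if len(strand_list) else starts
    all_strands = np.concatenate(
        [np.full(len(starts), st, dtype="<U1") for st in strand_list]
    )
    order = np.lexsort((all_strands, all_starts))
    return ProbeSet(
        nr_starts=all_starts[order],
        strands=all_strands[order],
        probe_length=probe_length,
        step=step,
        circular=circular,
        nr_sequence=nr_seq,
        nr_map=nr_map,
    )


def remap_probes(probe_set: ProbeSet, nr_map: NonRedundantMap | None = None) -> ProbeSet:
    """Populate each probe's full-genome footprint starts (all repeat copies)."""
    nr_map = nr_map or probe_set.nr_map
    positions = []
    for s in probe_set.nr_starts:
        positions.append(nr_map.genome_positions(int(s), probe_set.probe_length))
    probe_set.genome_positions = positions
    return probe_set


__all__ = [
    "DuplicateLink",
    "NonRedundantMap",
    "ProbeSet",
    "MappingError",
    "identity_map",
    "mask_duplications",
    "tile_probes",
    "remap_probes",
    "probe_id",
]
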