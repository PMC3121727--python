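"""Synthetic tiling-array data with known ground truth.

The generator emulates the structure of a plant mitochondrial genome and
its tiling-array readout: a circular genome carrying housekeeping genes,
inter-genic ORF regions, TE fragments, designated untranscribed
background-control regions and large exact duplications; a per-tissue
transcription truth (which genomic intervals are transcribed and how
strongly); and probe intensities equal to a baseline plus a signal
proportional to each probe footprint's overlap with transcribed
intervals, plus additive Gaussian noise.  Sense and antisense probes at
the same start are independent draws around the same expectation, which
is what lets the analysis treat them as experimental replicates.

All randomness flows from one top-level seed, deterministically split
per sub-generator, so identical calls reproduce identical data
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import AnnotatedGenome, Feature
from .matrix import IntensityMatrix

DEFAULT_BASELINE = 10.0
DEFAULT_NOISE_SD = 1.0

# background-control regions are sized so that two of them carry 1124
# fully-contained 60-mer probes at 2-bp tiling on both strands:
# 2 regions x 2 strands x ((620 - 60)/2 + 1) = 1124
BACKGROUND_REGION_LEN = 620

_BASES = np.array(list("ACGT"))


class PackingError(ValueError):
    """Requested features cannot be placed without overlap."""


class TruthError(ValueError):
    """Requested transcription truth violates the feature constraints."""


@dataclass
class TranscriptionTruth:
    """Ground-truth transcription state of one tissue.

    ``intervals`` are non-overlapping (start, end, mean_signal) triples in
    full-genome coordinates; ``mean_signal`` is the added expectation (in
    intensity units) over ``baseline_signal`` for probes fully inside.
    """

    tissue: str
    intervals: list[tuple[int, int, float]]
    baseline_signal: float = DEFAULT_BASELINE
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self):
        ivs = sorted((int(s), int(e), float(m)) for s, e, m in self.intervals)
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise TruthError("truth intervals overlap")
        for s, e, m in ivs:
            if e <= s:
                raise TruthError("empty truth interval")
            if m < 0:
                raise TruthError("mean_signal below baseline offset 0")
        self.intervals = ivs

    @property
    def transcribed_bases(self) -> int:
        return sum(e - s for s, e, _ in self.intervals)

    def covers(self, start: int, end: int) -> bool:
        """Is [start, end) fully inside one transcribed interval?"""
        return any(s <= start and end <= e for s, e, _ in self.intervals)


# ---------------------------------------------------------------------------
# Genome simulation


def _place_features(rng, length, wanted, margin=100):
    """Gap-aware placement of (label, size) blocks, largest first.

    Each block's start is drawn uniformly over every position that fits
    in the current free gaps (with a ``margin`` buffer between blocks).
    Starts are even (probe-step aligned) and blocks never wrap the
    origin.  Fails with an explicit packing error when no gap fits.
    """
    total = sum(size for _, size in wanted)
    if total > length:
        raise PackingError(
            f"requested features need {total} bp but genome is {length} bp"
        )
    occupied: list[tuple[int, int]] = []
    placed_by_label = {}
    for label, size in sorted(wanted, key=lambda w: -w[1]):
        gaps = []
        prev = 0
        for s, e in sorted(occupied):
            if s - prev >= size:
                gaps.append((prev, s))
            prev = e
        if length - prev >= size:
            gaps.append((prev, length))
        # number of even start positions per gap (margin kept where possible)
        choices = []
        for gs, ge in gaps:
            lo = gs + (margin if gs > 0 else 0)
            hi = ge - size - (margin if ge < length else 0)
            if hi < lo:  # tight gap: drop the margin rather than fail
                lo, hi = gs, ge - size
            n_starts = (hi - lo) // 2 + 1
            if n_starts > 0:
                choices.append((lo, n_starts))
        if not choices:
            raise PackingError(
                f"could not place {label} ({size} bp): no free gap fits; "
                "genome too crowded"
            )
        weights = np.array([n for _, n in choices], dtype=float)
        gi = int(rng.choice(len(choices), p=weights / weights.sum()))
        lo, n_starts = choices[gi]
        start = (lo + 1) // 2 * 2 + int(rng.integers(0, n_starts)) * 2
        start = min(start, length - size)
        occupied.append((start, start + size))
        placed_by_label[label] = (start, start + size)
    # report in the originally requested order
    return [(label, *placed_by_label[label]) for label, _ in wanted]


def simulate_genome(
    length: int = 100_000,
    n_housekeeping: int = 8,
    n_iorf: int = 10,
    n_te: int = 4,
    duplication_lengths: list[int] | tuple[int, ...] = (),
    background_regions: int = 2,
    seed: int = 0,
    genome_id: str = "sim_mt",
) -> AnnotatedGenome:
    """Simulate a circular annotated genome.

    Features are mutually non-overlapping; each requested duplication is
    an exact copy of another genomic block (the rightmost copy carries
    the ``duplication`` feature so masking keeps the leftmost).  The same
    seed reproduces the identical genome.
    """
    ss = np.random.SeedSequence([int(seed), 71])
    rng_seq, rng_place, rng_len = [np.random.default_rng(s) for s in ss.spawn(3)]

    wanted = []
    for i in range(n_housekeeping):
        wanted.append((f"hk_{i + 1}", int(rng_len.integers(500, 1750)) * 2))
    for i in range(n_iorf):
        wanted.append((f"iorf_{i + 1}", int(rng_len.integers(105, 450)) * 2))
    for i in range(n_te):
        wanted.append((f"te_{i + 1}", int(rng_len.integers(150, 750)) * 2))
    for i in range(background_regions):
        wanted.append((f"bg_{i + 1}", BACKGROUND_REGION_LEN))
    for i, d in enumerate(duplication_lengths):
        wanted.append((f"dupsrc_{i + 1}", int(d)))
        wanted.append((f"dup_{i + 1}", int(d)))

    placed = _place_features(rng_place, length, wanted)

    seq = rng_seq.choice(_BASES, size=length)
    features = []
    by_label = {label: (s, e) for label, s, e in placed}
    for label, s, e in placed:
        if label.startswith("dupsrc_"):
            continue
        if label.startswith("dup_"):
            src_s, src_e = by_label["dupsrc_" + label.split("_", 1)[1]]
            # make the two blocks exact copies; rightmost block is the
            # duplication feature, so masking keeps the leftmost copy
            lo_s, hi_s = sorted((src_s, s))
            d = e - s
            seq[hi_s : hi_s + d] = seq[lo_s : lo_s + d]
            # force mismatching flanks so the exact repeat has exactly the
            # requested length (a chance flank match would extend it)
            for cpos, spos in ((hi_s - 1, lo_s - 1), (hi_s + d, lo_s + d)):
                if 0 <= cpos < length and 0 <= spos < length and seq[cpos] == seq[spos]:
                    seq[cpos] = _BASES[(np.flatnonzero(_BASES == seq[spos])[0] + 1) % 4]
            features.append(
                Feature(id=label, start=hi_s, end=hi_s + d, strand="+",
                        category="duplication",
                        attributes={"copy_of": f"{lo_s}-{lo_s + d}"})
            )
            continue
        cat = {"hk": "housekeeping", "io": "iorf", "te": "te_fragment",
               "bg": "background_control"}[label[:2]]
        strand = "+" if cat == "background_control" else ("+", "-")[int(rng_len.integers(0, 2))]
        features.append(Feature(id=label, start=s, end=e, strand=strand, category=cat))

    features.sort(key=lambda f: f.start)
    return AnnotatedGenome(genome_id, "".join(seq), circular=True, features=features)


# ---------------------------------------------------------------------------
# Transcription truth


def _merge(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _subtract(intervals, forbidden):
    """Set difference of sorted interval lists."""
    out = []
    for s, e in intervals:
        cur = s
        for fs, fe in forbidden:
            if fe <= cur or fs >= e:
                continue
            if fs > cur:
                out.append((cur, fs))
            cur = max(cur, fe)
        if cur < e:
            out.append((cur, e))
    return out


def simulate_truth(
    genome: AnnotatedGenome,
    tissue_profiles: list[tuple[str, float, float]],
    nested: bool = True,
    seed: int = 0,
    baseline_signal: float = DEFAULT_BASELINE,
    noise_sd: float = DEFAULT_NOISE_SD,
    typical_interval_bp: int = 8_000,
) -> list[TranscriptionTruth]:
    """Generate per-tissue ground-truth transcription maps.

    ``tissue_profiles`` is a list of (tissue, transcribed_fraction,
    effect_size) with effect sizes in multiples of ``noise_sd``.  Every
    housekeeping feature is always transcribed in every tissue; the
    background-control features are never transcribed.  With ``nested``
    set, each tissue's intervals are contained in the previous (larger
    fraction) tissue's intervals, emulating a tissue whose transcription
    is a strict subset of another's.  The covered fraction matches the
    requested fraction to within a base pair.
    """
    L = len(genome)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 137]))
    hk = [(f.start, f.end) for f in genome.features_of("housekeeping")]
    # keep a clear buffer around background controls so their probes stay null
    bg_buffer = 200
    forbidden = _merge(
        [(max(0, f.start - bg_buffer), min(L, f.end + bg_buffer))
         for f in genome.features_of("background_control")]
    )

    profiles = list(tissue_profiles)
    if nested:
        profiles = sorted(profiles, key=lambda p: -p[1])

    truths: list[TranscriptionTruth] = []
    prev: list[tuple[int, int]] | None = None
    for tissue, frac, effect in profiles:
        if not (0.0 <= frac <= 1.0):
            raise TruthError(f"transcribed_fraction {frac} outside [0, 1]")
        if effect < 0:
            raise TruthError("effect_size must be >= 0")
        target = int(round(frac * L))
        mandatory = _merge([(max(0, s - 150), min(L, e + 150)) for s, e in hk])
        mandatory = _subtract(mandatory, forbidden)
        if frac == 0.0 and not hk:
            intervals: list[tuple[int, int]] = []
        else:
            need = sum(e - s for s, e in mandatory)
            if target < need:
                raise TruthError(
                    f"transcribed_fraction {frac} cannot cover the housekeeping "
                    f"features ({need} bp mandatory, {target} bp requested)"
                )
            if prev is None:
                intervals = _grow_intervals(
                    rng, L, mandatory, forbidden, target, typical_interval_bp
                )
            else:
                intervals = _shrink_intervals(rng, prev, mandatory, target)
        truths.append(
            TranscriptionTruth(
                tissue=tissue,
                intervals=[(s, e, effect * noise_sd) for s, e in intervals],
                baseline_signal=baseline_signal,
                noise_sd=noise_sd,
            )
        )
        if nested:
            prev = intervals
    # restore caller's profile order
    by_tissue = {t.tissue: t for t in truths}
    return [by_tissue[t] for t, _, _ in tissue_profiles]


def _grow_intervals(rng, L, mandatory, forbidden, target, typical_bp):
    intervals = list(mandatory)
    covered = sum(e - s for s, e in intervals)
    blocked = _merge(intervals + forbidden)
    tries = 0
    while covered < target and tries < 10_000:
        tries += 1
        free = _subtract([(0, L)], blocked)
        free = [(s, e) for s, e in free if e - s >= 400]
        if not free:
            break
        s, e = free[int(rng.integers(0, len(free)))]
        want = min(
            int(rng.integers(typical_bp // 2, typical_bp * 3 // 2)),
            e - s,
            target - covered,
        )
        if want < 200:
            want = min(200, e - s, target - covered)
        start = s if e - s == want else s + int(rng.integers(0, e - s - want + 1))
        intervals.append((start, start + want))
        covered += want
        blocked = _merge(blocked + [(start, start + want)])
    if covered < target:
        # close the remainder by extending the last interval into free space
        deficit = target - covered
        free = _subtract([(0, L)], _merge(intervals + forbidden))
        for s, e in free:
            take = min(deficit, e - s)
            if take > 0:
                intervals.append((s, s + take))
                deficit -= take
            if deficit == 0:
                break
        if deficit > 0:
            raise TruthError("cannot reach requested transcribed fraction")
    elif covered > target:
        # trim the surplus off the most recently added non-mandatory interval
        surplus = covered - target
        for i in range(len(intervals) - 1, -1, -1):
            s, e = intervals[i]
            if (s, e) in mandatory:
                continue
            cut = min(surplus, e - s - 1)
            intervals[i] = (s, e - cut)
            surplus -= cut
            if surplus == 0:
                break
    return _merge(intervals)


def _shrink_intervals(rng, parent, mandatory, target):
    """Nested truth: sub-intervals of ``parent`` covering all mandatory cores.

    Cores are the mandatory (housekeeping) blocks clipped to the parent
    intervals; the remaining budget is filled from the parent's free
    sub-pieces so every result interval stays inside a parent interval.
    """
    cores = []
    for s, e in parent:
        for ms, me in mandatory:
            if ms < e and s < me:
                cores.append((max(s, ms), min(e, me)))
    covered = sum(e - s for s, e in cores)
    if covered > target:
        raise TruthError("nested fraction too small to cover housekeeping cores")
    free = _subtract(parent, _merge(cores) if cores else [])
    budget = target - covered
    intervals = list(cores)
    order = rng.permutation(len(free)) if free else []
    for idx in order:
        if budget <= 0:
            break
        s, e = free[int(idx)]
        take = min(budget, e - s)
        intervals.append((s, s + take))
        budget -= take
    if budget > 0:
        raise TruthError("nested fraction exceeds parent coverage")
    return _merge(intervals)


# ---------------------------------------------------------------------------
# Intensities


def _signal_profile(truth: TranscriptionTruth, L: int) -> np.ndarray:
    sig = np.zeros(L)
    for s, e, m in truth.intervals:
        sig[s:e] = m
    return sig


def expected_intensity(probe_footprints, truth: TranscriptionTruth, L: int,
                       probe_length: int) -> np.ndarray:
    """Expected intensity per footprint start list (max over genome copies)."""
    sig = _signal_profile(truth, L)
    padded = np.concatenate([sig, sig[:probe_length]])  # circular wrap
    cum = np.concatenate([[0.0], np.cumsum(padded)])
    out = np.empty(len(probe_footprints))
    for i, positions in enumerate(probe_footprints):
        best = 0.0
        for p in positions:
            p %= L
            best = max(best, (cum[p + probe_length] - cum[p]) / probe_length)
        out[i] = truth.baseline_signal + best
    return out


def simulate_intensities(
    probes, truth: TranscriptionTruth, seed: int = 0, genome_length: int | None = None
) -> IntensityMatrix:
    """Noisy intensities for one tissue, sense and antisense as replicates.

    The expected intensity of a probe is the baseline plus the truth's
    mean signal scaled by the fraction of its footprint inside
    transcribed intervals; sense and antisense probes at the same start
    are independent Gaussian draws around that same expectation.
    """
    L = genome_length or probes.nr_map.genome_length
    starts = np.unique(probes.nr_starts)
    if probes.genome_positions is not None:
        by_start: dict[int, list[int]] = {}
        for s, positions in zip(probes.nr_starts, probes.genome_positions):
            by_start.setdefault(int(s), positions)
        footprints = [by_start[int(s)] for s in starts]
    else:
        footprints = [[probes.nr_map.nr_to_genome(int(s))] for s in starts]
    for positions in footprints:
        for p in positions:
            if not (0 <= p < L):
                raise ValueError(f"probe footprint start {p} outside genome")

    mu = expected_intensity(footprints, truth, L, probes.probe_length)
    strands_present = sorted(set(probes.strands.tolist()), reverse=True)  # '+' first
    rep_name = {"+": "sense", "-": "antisense"}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 211]))
    cols = []
    labels = []
    for st in strands_present:
        noise = (
            rng.normal(0.0, truth.noise_sd, size=len(starts))
            if truth.noise_sd > 0
            else np.zeros(len(starts))
        )
        cols.append(mu + noise)
        labels.append((truth.tissue, rep_name[st]))
    return IntensityMatrix(
        positions=starts,
        channels=labels,
        values=np.column_stack(cols),
        stage="raw",
        probe_length=probes.probe_length,
    )


def simulate_experiment(probes, truths: list[TranscriptionTruth], seed: int = 0):
    """One matrix holding every tissue's sense/antisense channels."""
    ss = np.random.SeedSequence([int(seed), 977])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(truths))]
    mats = [
        simulate_intensities(probes, truth, seed=cs)
        for truth, cs in zip(truths, child_seeds)
    ]
    out = mats[0]
    for m in mats[1:]:
        out = out.hstack(m)
    return out


__all__ = [
    "TranscriptionTruth",
    "PackingError",
    "TruthError",
    "simulate_genome",
    "simulate_truth",
    "simulate_intensities",
    "simulate_experiment",
    "expected_intensity",
    "BACKGROUND_REGION_LEN",
]
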