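"""Transcriptional-unit detection and tissue comparison.

A transcriptional unit (TU) is a maximal run of at least ``min_run``
(default 20) consecutive significant probes on the merged, strandless
track.  Probe starts sit every 2 bp, so 20 consecutive probes span at
least ~98 bp plus the final footprint.  TUs overlapping a housekeeping
gene by >= 1 bp are gene-associated; the rest are inter-genic — the
class that carries the newly observed transcription.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionTrack
from .genome import Feature
from .matrix import IntensityMatrix
from .normalize import DegenerateVarianceError

DEFAULT_MIN_RUN = 20


@dataclass
class TranscriptionalUnit:
    tu_id: str
    tissue: str
    start: int
    end: int
    probe_count: int
    min_p: float
    mean_p: float
    tu_class: str = "unclassified"  # gene_associated | inter_genic
    member_orf_ids: list = field(default_factory=list)
    strand: str = "."
    wraps: bool = False

    @property
    def id(self) -> str:  # GFF writer protocol
        return self.tu_id

    @property
    def category(self) -> str:
        return self.tu_class

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def attributes(self) -> dict:
        return {
            "probe_count": self.probe_count,
            "min_p": f"{self.min_p:.3g}",
            "tissue": self.tissue,
        }

    def overlap_bp(self, other: "TranscriptionalUnit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlap_bp_interval(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


def significant_runs(sig: np.ndarray, min_run: int, gap_tolerance: int = 0):
    """Maximal runs (start_idx, end_idx exclusive) of True with >= min_run True.

    ``gap_tolerance`` allows that many consecutive False values inside a
    run; runs never start or end on a gap, and only True probes count
    toward ``min_run``.
    """
    runs = []
    n = len(sig)
    i = 0
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        last_true = i
        gap = 0
        while j < n:
            if sig[j]:
                last_true = j
                gap = 0
            else:
                gap += 1
                if gap > gap_tolerance:
                    break
            j += 1
        count = int(np.count_nonzero(sig[i : last_true + 1]))
        if count >= min_run:
            runs.append((i, last_true + 1))
        i = last_true + 1
        while i < n and not sig[i]:
            i += 1
    return runs


def call_tus(track: ExpressionTrack, min_run: int = DEFAULT_MIN_RUN,
             gap_tolerance: int = 0) -> list[TranscriptionalUnit]:
    """Maximal runs of consecutive significant probes as TUs.

    Consecutive means adjacent in genomic start order on the merged
    track.  The TU span runs from the first probe's start to the end of
    the last probe's footprint.
    """
    runs = significant_runs(track.significant, min_run, gap_tolerance)
    tus = []
    for k, (i, j) in enumerate(runs, 1):
        p_slice = track.p_values[i:j][track.significant[i:j]]
        tus.append(
            TranscriptionalUnit(
                tu_id=f"tu_{track.tissue}_{k}",
                tissue=track.tissue,
                start=int(track.positions[i]),
                end=int(track.positions[j - 1]) + track.probe_length,
                probe_count=int(np.count_nonzero(track.significant[i:j])),
                min_p=float(p_slice.min()) if len(p_slice) else float("nan"),
                mean_p=float(p_slice.mean()) if len(p_slice) else float("nan"),
            )
        )
    return tus


def classify_tus(tus: list[TranscriptionalUnit],
                 features: list[Feature]) -> list[TranscriptionalUnit]:
    """gene_associated iff the TU overlaps a housekeeping feature by >= 1 bp."""
    genes = [f for f in features if f.category == "housekeeping"]
    for tu in tus:
        hit = any(g.overlaps(tu.start, tu.end) for g in genes)
        tu.tu_class = "gene_associated" if hit else "inter_genic"
    return tus


def compare_tissues(tus_a: list[TranscriptionalUnit],
                    tus_b: list[TranscriptionalUnit],
                    min_overlap: float = 0.5,
                    mode: str = "query_cover") -> dict:
    """Is every TU of b also identified in a?

    ``query_cover`` (default): a TU in b counts as contained when a
    single TU in a covers at least ``min_overlap`` of b's span — the
    natural reading of "also identified" when one tissue's units nest
    inside another's longer units.  ``reciprocal`` instead requires the
    overlap to reach ``min_overlap`` of both spans.
    """
    if mode not in {"query_cover", "reciprocal"}:
        raise ValueError(f"unknown containment mode {mode!r}")
    details = []
    contained = 0
    for tb in tus_b:
        best = 0.0
        match = None
        for ta in tus_a:
            ov = tb.overlap_bp(ta)
            if ov == 0:
                continue
            score = (
                ov / tb.length
                if mode == "query_cover"
                else min(ov / tb.length, ov / ta.length)
            )
            if score > best:
                best, match = score, ta.tu_id
        ok = best >= min_overlap
        contained += ok
        details.append({"tu_id": tb.tu_id, "contained": ok,
                        "best_overlap": best, "match": match})
    n = len(tus_b)
    return {
        "n_a": len(tus_a),
        "n_b": n,
        "contained": contained,
        "uncontained": n - contained,
        "fraction_contained": (contained / n) if n else 1.0,
        "details": details,
    }


# ---------------------------------------------------------------------------
# Per-region expression summaries


def region_summary(regions: list[Feature], matrix: IntensityMatrix,
                   per_tissue_mean: bool = True) -> pd.DataFrame:
    """Mean normalized value over all probes fully within each region.

    Returns a tidy table (region, tissue, mean_z, n_probes); a region
    overlapping no probe appears with n_probes 0 and missing mean — it
    is recorded, never silently dropped.
    """
    if matrix.stage != "zscore":
        raise ValueError(f"region_summary expects zscore stage, got {matrix.stage}")
    starts = matrix.positions
    ends = starts + matrix.probe_length
    rows = []
    for f in regions:
        inside = np.flatnonzero((starts >= f.start) & (ends <= f.end))
        for tissue in matrix.tissues:
            cols = matrix.columns_for(tissue)
            if len(inside):
                vals = matrix.values[np.ix_(inside, cols)]
                mean_z = float(vals.mean())
            else:
                mean_z = float("nan")
            rows.append({"region": f.id, "category": f.category, "tissue": tissue,
                         "mean_z": mean_z, "n_probes": int(len(inside))})
    _ = per_tissue_mean
    return pd.DataFrame(rows)


def correlate_regions(summary_a: pd.DataFrame, summary_b: pd.DataFrame
                      ) -> tuple[float, int, float]:
    """Pearson correlation of matched region means between two tissues.

    Returns (r, df, p) with df = n - 2 and the two-tailed p from the
    t transform t = r * sqrt(df / (1 - r^2)).
    """
    a = summary_a.set_index("region")["mean_z"]
    b = summary_b.set_index("region")["mean_z"]
    shared = a.index.intersection(b.index)
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 shared regions, got {n}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise DegenerateVarianceError("zero variance in region means")
    r = float(np.sum((x - x.mean()) * (y - y.mean())) / ((n - 1) * sx * sy))
    df = n - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return r, df, p


__all__ = [
    "TranscriptionalUnit",
    "significant_runs",
    "call_tus",
    "classify_tus",
    "compare_tissues",
    "region_summary",
    "correlate_regions",
    "DEFAULT_MIN_RUN",
]
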