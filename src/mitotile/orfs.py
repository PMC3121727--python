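"""Six-frame ORF prediction and conservation screening.

ORFs of at least 70 amino acids are predicted in all six reading
frames (stop-to-stop by default, matching getorf's default; first-ATG
mode available), on the circular genome so frames may wrap the origin.
ORFs are numbered in genomic order; those overlapping a known gene on
the same strand keep their number but are not given an iORF label, so
iORF numbering skips the known-gene frames.  Conservation is screened
with reciprocal-best-hit (RBH) logic over pairwise protein hit tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import AnnotatedGenome, Feature, revcomp
from .normalize import DegenerateVarianceError

MIN_AA_DEFAULT = 70

# standard genetic code, codon order TTT, TTC, TTA, TTG, CTT, ... GGG
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_ORDER = "TCAG"
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_ORDER)
    for j, b in enumerate(_ORDER)
    for k, c in enumerate(_ORDER)
}


class TranslationError(ValueError):
    pass


def translate(seq: str, strict: bool = True) -> str:
    """Codon-walk translation with the standard code; stops become '*'."""
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        try:
            aa.append(CODON_TABLE[codon])
        except KeyError:
            if strict:
                raise TranslationError(f"non-ACGT codon {codon!r} at {i}")
            aa.append("X")
    return "".join(aa)


@dataclass
class ORF:
    orf_id: str
    frame: int  # +1,+2,+3,-1,-2,-3
    start: int  # 0-based half-open on the forward strand; may wrap
    end: int
    length_aa: int
    protein: str
    category: str = "iorf"  # iorf | known_gene_frame
    number: int = 0
    wraps: bool = False
    attributes: dict = field(default_factory=dict)

    @property
    def id(self) -> str:
        return self.orf_id

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def _frame_segments(aa: str):
    """Between-stop segments as (aa_start, aa_end, start_bounded) triples.

    ``start_bounded`` is True when the segment begins right after a stop
    codon (as opposed to the translation edge).
    """
    stops = [i for i, ch in enumerate(aa) if ch == "*"]
    if not stops:
        return [(0, len(aa), False)] if aa else []
    segs = []
    if stops[0] > 0:
        segs.append((0, stops[0], False))
    for s, e in zip(stops, stops[1:]):
        if e > s + 1:
            segs.append((s + 1, e, True))
    if stops[-1] < len(aa) - 1:
        segs.append((stops[-1] + 1, len(aa), True))
    return segs


def _qualify(aa: str, segments, mode: str, min_aa: int):
    out = []
    for s, e, bounded in segments:
        if mode == "start_to_stop":
            rel = aa[s:e].find("M")
            if rel < 0:
                continue
            s = s + rel
        if e - s >= min_aa:
            out.append((s, e, bounded))
    return out


def six_frame_orfs(genome: AnnotatedGenome, min_aa: int = MIN_AA_DEFAULT,
                   mode: str = "stop_to_stop",
                   circular: bool | None = None) -> list[ORF]:
    """Predict ORFs of >= ``min_aa`` amino acids in all six frames.

    stop_to_stop reports maximal translations between stop codons;
    start_to_stop trims each to its first ATG.  On circular genomes
    ORFs may span the origin and are reported once, capped at one full
    genome length.  Output is deterministically ordered by (start,
    frame).
    """
    if mode not in {"stop_to_stop", "start_to_stop"}:
        raise ValueError(f"unknown ORF mode {mode!r}")
    seq = genome.sequence
    L = len(seq)
    if L < 3:
        raise ValueError("sequence shorter than one codon")
    circ = genome.circular if circular is None else circular

    orfs = []
    seen = set()
    for strand, s_seq in (("+", seq), ("-", revcomp(seq))):
        scan = s_seq + s_seq if circ else s_seq
        for off in range(3):
            aa = translate(scan[off:])
            frame = (off + 1) if strand == "+" else -(off + 1)
            segments = _frame_segments(aa)
            stop_free = circ and len(segments) == 1 and not segments[0][2]
            for a_s, a_e, bounded in _qualify(aa, segments, mode, min_aa):
                if circ and not bounded and not stop_free:
                    # unbounded leading piece of a wrap-around ORF whose
                    # stop-bounded copy appears later in the doubled scan
                    continue
                nt_s = off + 3 * a_s
                nt_e = off + 3 * a_e
                if circ:
                    if nt_s >= L:  # duplicate copy in the doubled sequence
                        continue
                    if nt_e - nt_s > L:  # cap a stop-free circle at one lap
                        nt_e = nt_s + 3 * (L // 3)
                        a_e = a_s + (nt_e - nt_s) // 3
                protein = aa[a_s:a_e]
                if strand == "+":
                    g_s, g_e = nt_s, nt_e
                else:
                    g_s, g_e = L - nt_e, L - nt_s
                    if circ and g_s < 0:
                        g_s += L
                        g_e += L
                wraps = g_e > L
                key = (g_s % L, g_e - g_s, strand)
                if key in seen:
                    continue
                seen.add(key)
                orfs.append(
                    ORF(
                        orf_id="",  # assigned by label_iorfs
                        frame=frame,
                        start=g_s % L if wraps else g_s,
                        end=(g_s % L) + (g_e - g_s) if wraps else g_e,
                        length_aa=len(protein),
                        protein=protein,
                        wraps=wraps,
                    )
                )
    orfs.sort(key=lambda o: (o.start, o.frame))
    for i, o in enumerate(orfs, 1):
        o.number = i
        o.orf_id = f"orf_{i}"
    return orfs


def label_iorfs(orfs: list[ORF], features: list[Feature]) -> list[ORF]:
    """Classify each ORF and assign iORF labels with dense global numbering.

    An ORF overlapping a housekeeping feature on the same strand by
    >= 1 bp is a known-gene frame: it keeps its sequential number but no
    iORF label.  Everything else becomes iORF_<number>, so the iORF
    labels skip the numbers taken by known-gene frames.
    """
    genes = [f for f in features if f.category == "housekeeping"]
    for o in orfs:
        hit = any(
            g.strand == o.strand and g.overlaps(o.start, o.end) for g in genes
        )
        if hit:
            o.category = "known_gene_frame"
            o.orf_id = f"orf_{o.number}"
        else:
            o.category = "iorf"
            o.orf_id = f"iORF_{o.number}"
    return orfs


def intersect_tus_orfs(tus, orfs: list[ORF], containment: str = "full") -> dict:
    """Which inter-genic TUs carry an iORF, and which iORFs sit inside a TU.

    ``containment`` 'full' requires the ORF interval inside the TU span;
    'partial' accepts >= 1 bp overlap.
    """
    if containment not in {"full", "partial"}:
        raise ValueError(f"unknown containment rule {containment!r}")
    inter = [t for t in tus if t.tu_class == "inter_genic"]
    iorfs = [o for o in orfs if o.category == "iorf"]
    tu_members: dict[str, list[str]] = {t.tu_id: [] for t in inter}
    orf_hit: set[str] = set()
    for t in inter:
        for o in iorfs:
            if containment == "full":
                ok = t.start <= o.start and o.end <= t.end
            else:
                ok = o.overlaps(t.start, t.end)
            if ok:
                tu_members[t.tu_id].append(o.orf_id)
                orf_hit.add(o.orf_id)
    for t in inter:
        t.member_orf_ids = tu_members[t.tu_id]
    return {
        "n_intergenic_tus": len(inter),
        "n_iorfs": len(iorfs),
        "tus_with_orf": sum(1 for v in tu_members.values() if v),
        "iorfs_in_tu": len(orf_hit),
        "members": tu_members,
    }


# ---------------------------------------------------------------------------
# Reciprocal best hits


def best_hits(table: pd.DataFrame) -> dict[str, str]:
    """query -> best subject by score; ties broken by subject id order."""
    if len(table) == 0:
        return {}
    t = table.sort_values(
        ["query_id", "score", "subject_id"], ascending=[True, False, True]
    )
    firsts = t.drop_duplicates("query_id", keep="first")
    return dict(zip(firsts["query_id"], firsts["subject_id"]))


def reciprocal_best_hits(ab: pd.DataFrame, ba: pd.DataFrame) -> list[tuple[str, str]]:
    """(a, b) pairs that are each other's best hit in both directions."""
    fwd = best_hits(ab)
    rev = best_hits(ba)
    pairs = [(a, b) for a, b in fwd.items() if rev.get(b) == a]
    return sorted(pairs)


def read_hit_table(path) -> pd.DataFrame:
    """12-column tabular hit format (query, subject, identity, ..., bitscore)."""
    cols = [
        "query_id", "subject_id", "identity", "aln_len", "mismatches",
        "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "score",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    return df[["query_id", "subject_id", "score"]]


def align_hit_table(queries: dict[str, str], subjects: dict[str, str],
                    min_score: float = 40.0) -> pd.DataFrame:
    """Hit table from all-pairs local protein alignment (BLOSUM62).

    A lightweight stand-in for tabular search output when building
    synthetic-species fixtures; production conservation screens ingest
    real 12-column hit tables via :func:`read_hit_table`.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    rows = []
    for q_id, q_seq in queries.items():
        for s_id, s_seq in subjects.items():
            score = float(aligner.score(q_seq, s_seq))
            if score >= min_score:
                rows.append({"query_id": q_id, "subject_id": s_id, "score": score})
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "score"])


def conservation_expression_association(
    rbh_counts: pd.Series, summary: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation between per-iORF species conservation and expression.

    ``rbh_counts`` maps iORF id -> number of species with an RBH;
    ``summary`` is a region_summary table for one tissue.  Returns
    (r, p); the expectation for inter-genic frames is that the null is
    typically retained.
    """
    expr = summary.set_index("region")["mean_z"]
    shared = rbh_counts.index.intersection(expr.index)
    x = rbh_counts.loc[shared].to_numpy(dtype=float)
    y = expr.loc[shared].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError(f"need >= 3 iORFs, got {len(x)}")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise DegenerateVarianceError("zero variance in conservation or expression")
    n = len(x)
    r = float(
        np.sum((x - x.mean()) * (y - y.mean()))
        / ((n - 1) * x.std(ddof=1) * y.std(ddof=1))
    )
    df = n - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df))


__all__ = [
    "ORF",
    "CODON_TABLE",
    "TranslationError",
    "translate",
    "six_frame_orfs",
    "label_iorfs",
    "intersect_tus_orfs",
    "best_hits",
    "align_hit_table",
    "reciprocal_best_hits",
    "read_hit_table",
    "conservation_expression_association",
    "MIN_AA_DEFAULT",
]
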