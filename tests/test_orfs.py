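"""Six-frame ORF prediction, iORF labeling, TU intersection, RBH screening."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from mitotile.genome import AnnotatedGenome, Feature, revcomp
from mitotile.normalize import DegenerateVarianceError
from mitotile.orfs import (
    align_hit_table,
    conservation_expression_association,
    intersect_tus_orfs,
    label_iorfs,
    reciprocal_best_hits,
    six_frame_orfs,
    translate,
)
from mitotile.tu import TranscriptionalUnit
from tests.conftest import random_dna


def _genome(seq, circular=False):
    return AnnotatedGenome("g", seq, circular=circular)


def oracle_linear_orfs(seq, min_aa, mode):
    """Brute force: Biopython translation of each frame, split at stops."""
    out = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for off in range(3):
            frame_nt = s[off : off + 3 * ((L - off) // 3)]
            aa = str(Seq(frame_nt).translate())
            pos = 0
            for segment in aa.split("*"):
                if segment:
                    start_aa, end_aa = pos, pos + len(segment)
                    if mode == "start_to_stop":
                        m = segment.find("M")
                        if m < 0:
                            pos = end_aa + 1
                            continue
                        start_aa += m
                    if end_aa - start_aa >= min_aa:
                        nt_s = off + 3 * start_aa
                        nt_e = off + 3 * end_aa
                        if strand == "+":
                            g_s, g_e = nt_s, nt_e
                        else:
                            g_s, g_e = L - nt_e, L - nt_s
                        out.add((g_s, g_e, strand))
                pos += len(segment) + 1
    return out


class TestTranslate:
    def test_matches_biopython_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for i in range(25):
            n = int(rng.integers(30, 300)) * 3
            seq = random_dna(n, 1000 + i)
            assert translate(seq) == str(Seq(seq).translate())

    def test_non_acgt_rejected_or_masked(self):
        with pytest.raises(Exception):
            translate("ATGNNN")
        assert translate("ATGNNN", strict=False) == "MX"


class TestSixFrameOrfs:
    @pytest.mark.parametrize("mode", ["stop_to_stop", "start_to_stop"])
    def test_matches_brute_force_on_random_sequences(self, mode):
        """100 random 1-2 kb sequences agree with the translate-and-split scan."""
        rng = np.random.default_rng(1)
        for i in range(100):
            n = int(rng.integers(1_000, 2_000))
            seq = random_dna(n, 2_000 + i)
            got = {
                (o.start, o.end, o.strand)
                for o in six_frame_orfs(_genome(seq), min_aa=25, mode=mode)
            }
            assert got == oracle_linear_orfs(seq, 25, mode), f"seq {i}, {mode}"

    def test_poly_a_degenerate_case(self):
        """300-nt poly-A: poly-K forward frames, poly-F reverse, 6 ORFs total."""
        orfs = six_frame_orfs(_genome("A" * 300), min_aa=70, mode="stop_to_stop")
        assert len(orfs) == 6
        fwd = [o for o in orfs if o.strand == "+"]
        rev = [o for o in orfs if o.strand == "-"]
        assert all(set(o.protein) == {"K"} for o in fwd)
        assert all(set(o.protein) == {"F"} for o in rev)

    def test_min_aa_threshold_boundary(self):
        core = "GCT"
        for n_codons, expect in ((70, 1), (69, 0)):
            seq = "TAA" + core * n_codons + "TAA"
            orfs = six_frame_orfs(_genome(seq), min_aa=70, mode="stop_to_stop")
            in_frame1 = [o for o in orfs if o.frame == 1]
            assert len(in_frame1) == expect
        # every reported ORF respects the threshold
        seq = random_dna(3_000, 99)
        assert all(o.length_aa >= 70
                   for o in six_frame_orfs(_genome(seq), min_aa=70))

    def test_reverse_complement_symmetry(self):
        seq = random_dna(1_500, 5)
        L = len(seq)
        fwd = six_frame_orfs(_genome(seq), min_aa=25)
        rev = six_frame_orfs(_genome(revcomp(seq)), min_aa=25)
        mirrored = {(L - o.end, L - o.start, "+-"[o.strand == "+"]) for o in rev}
        assert {(o.start, o.end, o.strand) for o in fwd} == mirrored

    def test_circular_orf_spans_origin(self):
        # place an ORF across the origin: stop | 40 codons | origin | 40 codons | stop
        inner = "GCT" * 40
        seq = inner + random_dna(600, 8) + "TAA" + inner
        # rotate so the poly-A(la) run crosses position 0
        g = _genome(seq, circular=True)
        orfs = six_frame_orfs(g, min_aa=60, mode="stop_to_stop")
        wrapped = [o for o in orfs if o.wraps]
        assert wrapped, "expected at least one origin-spanning ORF"
        for o in wrapped:
            assert o.end > len(seq) >= o.start
            # the wrapped protein re-derives from the circular sequence
            nt = g.fetch(o.start, o.end)
            if o.strand == "-":
                nt = revcomp(nt)
            assert translate(nt) == o.protein
            assert "*" not in o.protein

    def test_circular_reported_once_with_deterministic_order(self):
        seq = random_dna(2_000, 6)
        orfs = six_frame_orfs(_genome(seq, circular=True), min_aa=25)
        keys = [(o.start, o.end, o.strand) for o in orfs]
        assert len(keys) == len(set(keys))
        assert keys == sorted(keys, key=lambda k: k[0])

    def test_proteins_have_no_internal_stop_and_consistent_span(self):
        seq = random_dna(2_000, 7)
        for o in six_frame_orfs(_genome(seq), min_aa=25):
            assert "*" not in o.protein
            assert o.end - o.start == 3 * o.length_aa

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            six_frame_orfs(_genome("AC"))


class TestLabelIorfs:
    def _orfs(self, seq="", n=2_000, seed=3):
        seq = seq or random_dna(n, seed)
        return six_frame_orfs(_genome(seq), min_aa=25), seq

    def test_no_overlap_all_iorfs_dense_numbering(self):
        orfs, _ = self._orfs()
        labeled = label_iorfs(orfs, [])
        assert all(o.category == "iorf" for o in labeled)
        assert [o.number for o in labeled] == list(range(1, len(labeled) + 1))
        assert all(o.orf_id == f"iORF_{o.number}" for o in labeled)

    def test_known_gene_frames_keep_number_but_lose_label(self):
        orfs, seq = self._orfs()
        target = orfs[0]
        gene = Feature("gene", target.start, target.end, target.strand,
                       "housekeeping")
        labeled = label_iorfs(orfs, [gene])
        known = [o for o in labeled if o.category == "known_gene_frame"]
        assert target in known
        taken = {o.number for o in known}
        iorf_numbers = {o.number for o in labeled if o.category == "iorf"}
        assert not (taken & iorf_numbers)  # iORF numbering skips those values
        assert len(known) + len(iorf_numbers) == len(labeled)

    def test_same_strand_rule(self):
        orfs, _ = self._orfs()
        target = orfs[0]
        other = "+" if target.strand == "-" else "-"
        gene = Feature("gene", target.start, target.end, other, "housekeeping")
        labeled = label_iorfs(orfs, [gene])
        assert target.category == "iorf"  # opposite strand does not count
        _ = labeled

    def test_labeling_stable_under_irrelevant_feature(self):
        orfs, _ = self._orfs()
        before = [(o.orf_id, o.category) for o in label_iorfs(orfs, [])]
        far = Feature("x", 0, 1, "+", "housekeeping")
        overlapping_none = [
            o for o in orfs if o.overlaps(0, 1) and o.strand == "+"
        ]
        if not overlapping_none:
            after = [(o.orf_id, o.category) for o in label_iorfs(orfs, [far])]
            assert before == after

    def test_deterministic(self):
        orfs, _ = self._orfs()
        a = [(o.orf_id, o.category) for o in label_iorfs(orfs, [])]
        b = [(o.orf_id, o.category) for o in label_iorfs(orfs, [])]
        assert a == b


def _tu(start, end, cls="inter_genic", tu_id="tu1"):
    return TranscriptionalUnit(tu_id, "t", start, end, 30, 1e-6, 1e-5,
                               tu_class=cls)


class TestIntersectTusOrfs:
    def _iorf(self, start, end, n=1):
        from mitotile.orfs import ORF

        return ORF(f"iORF_{n}", 1, start, end, (end - start) // 3, "A",
                   category="iorf", number=n)

    def test_contained_orf_counted_in_both_summaries(self):
        rep = intersect_tus_orfs([_tu(0, 1_000)], [self._iorf(100, 400)])
        assert rep["tus_with_orf"] == 1
        assert rep["iorfs_in_tu"] == 1

    def test_straddling_orf_excluded_full_included_partial(self):
        tus = [_tu(0, 1_000)]
        orfs = [self._iorf(800, 1_300)]
        assert intersect_tus_orfs(tus, orfs, "full")["iorfs_in_tu"] == 0
        assert intersect_tus_orfs(tus, orfs, "partial")["iorfs_in_tu"] == 1

    def test_gene_associated_tus_ignored(self):
        rep = intersect_tus_orfs([_tu(0, 1_000, cls="gene_associated")],
                                 [self._iorf(100, 400)])
        assert rep["n_intergenic_tus"] == 0
        assert rep["tus_with_orf"] == 0

    def test_empty_tu_list_zero_counts(self):
        rep = intersect_tus_orfs([], [self._iorf(0, 300)])
        assert rep["tus_with_orf"] == 0
        assert rep["iorfs_in_tu"] == 0


def _hits(rows):
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "score"])


class TestReciprocalBestHits:
    def test_identical_sets_pair_with_twins(self):
        ids = ["a", "b", "c"]
        rows = []
        for q in ids:
            for s in ids:
                rows.append((f"A:{q}", f"B:{s}", 100.0 if q == s else 30.0))
        ab = _hits(rows)
        ba = _hits([(s, q, sc) for q, s, sc in rows])
        assert reciprocal_best_hits(ab, ba) == [
            ("A:a", "B:a"), ("A:b", "B:b"), ("A:c", "B:c")
        ]

    def test_empty_tables_empty_result(self):
        assert reciprocal_best_hits(_hits([]), _hits([])) == []

    def test_matches_brute_force_on_random_score_table(self):
        rng = np.random.default_rng(9)
        A = [f"a{i}" for i in range(5)]
        B = [f"b{i}" for i in range(5)]
        S = rng.normal(size=(5, 5))
        ab = _hits([(A[i], B[j], S[i, j]) for i in range(5) for j in range(5)])
        ba = _hits([(B[j], A[i], S[i, j]) for i in range(5) for j in range(5)])
        expect = set()
        for i in range(5):
            j = int(np.argmax(S[i]))
            if int(np.argmax(S[:, j])) == i:
                expect.add((A[i], B[j]))
        assert set(reciprocal_best_hits(ab, ba)) == expect

    def test_role_swap_symmetry(self):
        rng = np.random.default_rng(10)
        ab = _hits([(f"a{i}", f"b{j}", float(rng.normal()))
                    for i in range(4) for j in range(4)])
        ba = _hits([(s, q, sc) for q, s, sc in ab.itertuples(index=False)])
        fwd = set(reciprocal_best_hits(ab, ba))
        rev = {(a, b) for b, a in reciprocal_best_hits(ba, ab)}
        assert fwd == rev

    def test_tie_broken_by_subject_order(self):
        ab = _hits([("q", "b2", 50.0), ("q", "b1", 50.0)])
        ba = _hits([("b1", "q", 50.0), ("b2", "q", 50.0)])
        assert reciprocal_best_hits(ab, ba) == [("q", "b1")]


class TestAlignHitTable:
    def test_self_alignment_scores_highest(self):
        rng = np.random.default_rng(11)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        prots = {
            f"p{i}": "".join(rng.choice(list(aas), size=80)) for i in range(3)
        }
        table = align_hit_table(prots, prots, min_score=0.0)
        for pid in prots:
            rows = table[table.query_id == pid]
            assert rows.loc[rows.score.idxmax(), "subject_id"] == pid


class TestConservationExpression:
    def test_equal_counts_zero_variance_error(self):
        counts = pd.Series([2, 2, 2], index=["a", "b", "c"])
        summary = pd.DataFrame({"region": ["a", "b", "c"],
                                "mean_z": [0.1, 0.5, 0.9]})
        with pytest.raises(DegenerateVarianceError):
            conservation_expression_association(counts, summary)

    def test_linear_relationship_r_near_one(self):
        counts = pd.Series([0, 1, 2, 3, 4], index=list("abcde"))
        summary = pd.DataFrame({"region": list("abcde"),
                                "mean_z": [0.0, 0.5, 1.0, 1.5, 2.0]})
        r, p = conservation_expression_association(counts, summary)
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_independent_data_typically_null(self):
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(40):
            idx = [f"o{i}" for i in range(30)]
            counts = pd.Series(rng.integers(0, 6, size=30), index=idx)
            summary = pd.DataFrame({"region": idx,
                                    "mean_z": rng.normal(size=30)})
            _, p = conservation_expression_association(counts, summary)
            pvals.append(p)
        # under independence p is uniform: the mean sits near 0.5
        assert 0.3 < float(np.mean(pvals)) < 0.7
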