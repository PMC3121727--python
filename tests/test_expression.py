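"""Window t-test calling: t oracle, background pool, assignment, fractions."""

import numpy as np
import pytest
from scipy import stats

from mitotile.expression import (
    BackgroundPool,
    assign_probe_pvalues,
    call_expression,
    select_background,
    sliding_window_test,
    student_t,
    transcribed_fraction,
)
from mitotile.genome import AnnotatedGenome, Feature
from mitotile.normalize import (
    DegenerateVarianceError,
    ReplicateTrack,
    normalize_pipeline,
)
from mitotile.probes import identity_map, tile_probes


class TestStudentT:
    def test_matches_independent_implementation(self):
        """1000 random sample pairs agree with scipy's pooled t to 1e-10."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            na, nb = rng.integers(2, 30, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), na)
            b = rng.normal(0, 1, nb)
            t, df, p = student_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert abs(t - ref.statistic) < 1e-10
            assert abs(p - ref.pvalue) < 1e-10
            assert df == na + nb - 2

    def test_hand_computed_pooled_formula(self):
        a, b = [1.0, 2.0, 3.0], [0.0, 0.0, 0.0, 1.0]
        # explicit arithmetic: ssa = 2, ssb = 0.75, df = 5, sp2 = 0.55
        sp2 = (2.0 + 0.75) / 5
        t_expect = (2.0 - 0.25) / np.sqrt(sp2 * (1 / 3 + 1 / 4))
        p_expect = 2 * stats.t.sf(abs(t_expect), 5)
        t, df, p = student_t(a, b)
        assert t == pytest.approx(t_expect, abs=1e-12)
        assert df == 5
        assert p == pytest.approx(p_expect, abs=1e-12)

    def test_equal_samples_give_t_zero_p_one(self):
        t, _, p = student_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(1, 1, size=5)
        t1, _, p1 = student_t(a, b)
        t2, _, p2 = student_t(b, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_errors(self):
        with pytest.raises(ValueError):
            student_t([1.0], [1.0, 2.0])
        with pytest.raises(DegenerateVarianceError):
            student_t([1.0, 1.0], [1.0, 1.0])


def _toy_track(values_by_tissue, positions=None):
    any_v = next(iter(values_by_tissue.values()))
    if positions is None:
        positions = np.arange(len(any_v)) * 2
    return ReplicateTrack(
        positions=np.asarray(positions),
        values={t: np.asarray(v, dtype=float) for t, v in values_by_tissue.items()},
    )


class TestSelectBackground:
    def test_toy_layout_counts_fully_contained_probes(self):
        # control [100, 400): probes starting 100..340 fit fully (121 starts
        # at step 2); a probe at 98 or 342 straddles the boundary -> excluded
        track = _toy_track({"t": np.zeros((300, 2))})
        features = [Feature("bg", 100, 400, "+", "background_control")]
        pool = select_background(track, features)
        starts = np.array(pool.probe_ids)
        assert starts.min() == 100
        assert starts.max() == 340
        assert pool.size == 121
        assert len(pool.values["t"]) == 242  # replicates flattened

    def test_simulated_default_controls_span_1124_probes(self, sim_bundle):
        """Two 620-bp control regions carry 1124 probes over both strands."""
        pool = select_background(
            sim_bundle["track"], sim_bundle["genome"].features,
            sim_bundle["nr_map"],
        )
        n_strands = 2
        assert pool.size * n_strands == 1124

    def test_no_controls_raises(self):
        track = _toy_track({"t": np.zeros((10, 2))})
        with pytest.raises(ValueError):
            select_background(track, [Feature("g", 0, 100, "+", "housekeeping")])

    def test_control_shorter_than_probe_raises(self):
        track = _toy_track({"t": np.zeros((100, 2))})
        features = [Feature("bg", 10, 50, "+", "background_control")]
        with pytest.raises(ValueError):
            select_background(track, features)


def _null_pool(rng, n=400, tissue="t"):
    return BackgroundPool(["x"] * n, {tissue: rng.normal(size=n)}, ["bg"])


class TestSlidingWindow:
    def test_window_equal_to_pool_gives_p_one(self):
        vals = np.tile(np.array([[-1.0, 1.0]]), (60, 1))
        track = _toy_track({"t": vals})
        pool = BackgroundPool(["x"] * 60, {"t": vals.ravel()}, ["bg"])
        tests = sliding_window_test(track, pool, "t", window_size=60)
        assert len(tests) == 1
        assert tests[0].t_statistic == pytest.approx(0.0)
        assert tests[0].p_value == pytest.approx(1.0)

    def test_vectorized_matches_scalar_student_t(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(80, 2))
        track = _toy_track({"t": vals})
        pool = _null_pool(rng)
        tests = sliding_window_test(track, pool, "t", window_size=10)
        assert len(tests) == 71
        for w in (0, 17, 70):
            sample = vals[w : w + 10].ravel()
            t, df, p = student_t(sample, pool.values["t"])
            assert tests[w].t_statistic == pytest.approx(t, abs=1e-10)
            assert tests[w].p_value == pytest.approx(p, abs=1e-10)
            assert tests[w].df == df

    def test_strong_signal_window_significant(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(3.0, 1.0, size=(60, 2))  # effect size 3 sd
        track = _toy_track({"t": vals})
        tests = sliding_window_test(track, _null_pool(rng), "t", window_size=60)
        assert tests[0].p_value < 1e-3
        assert tests[0].mean_exceeds

    def test_monotone_power_in_effect_size(self):
        """Same noise draws: larger effect never yields fewer significant windows."""
        rng = np.random.default_rng(4)
        noise = rng.normal(size=(500, 2))
        inside = np.zeros((500, 1))
        inside[100:300] = 1.0
        pool = _null_pool(np.random.default_rng(5), n=1124)
        counts = []
        for effect in (0.5, 1.0, 2.0, 3.0):
            track = _toy_track({"t": noise + effect * inside})
            tests = sliding_window_test(track, pool, "t")
            counts.append(
                sum(t.p_value < 1e-3 and t.mean_exceeds for t in tests)
            )
        assert counts == sorted(counts)

    def test_track_shorter_than_window_rejected(self):
        track = _toy_track({"t": np.zeros((10, 2)) + np.arange(10)[:, None]})
        with pytest.raises(ValueError):
            sliding_window_test(track, _null_pool(np.random.default_rng(6)), "t")


class TestAssignProbePvalues:
    def _run(self, sig_window_idx, n_pos=200, window=60, convention="center"):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(n_pos, 2))
        track = _toy_track({"t": vals})
        pool = _null_pool(rng, n=1124)
        tests = sliding_window_test(track, pool, "t", window_size=window)
        for w in tests:
            w.p_value = 0.5
            w.mean_exceeds = True
        if sig_window_idx is not None:
            tests[sig_window_idx].p_value = 1e-6
        return assign_probe_pvalues(tests, track, "t", convention=convention,
                                    window_size=window)

    def test_single_significant_window_center_marks_one_probe(self):
        et = self._run(70)
        assert int(et.significant.sum()) == 1
        assert np.flatnonzero(et.significant)[0] == 100  # window 70 centers probe 100

    def test_single_significant_window_min_cover_marks_sixty(self):
        et = self._run(70, convention="min_cover")
        assert int(et.significant.sum()) == 60
        np.testing.assert_array_equal(
            np.flatnonzero(et.significant), np.arange(70, 130)
        )

    def test_constant_p_assigns_same_everywhere(self):
        for conv in ("center", "min_cover"):
            et = self._run(None, convention=conv)
            assert np.all(et.p_values == 0.5)
            assert not et.significant.any()

    def test_track_equal_to_window_single_window_shared(self):
        rng = np.random.default_rng(8)
        track = _toy_track({"t": rng.normal(size=(60, 2))})
        pool = _null_pool(rng)
        tests = sliding_window_test(track, pool, "t", window_size=60)
        et = assign_probe_pvalues(tests, track, "t")
        assert np.all(et.p_values == tests[0].p_value)


class TestTranscribedFraction:
    def _track(self, sig, positions=None, probe_length=60):
        from mitotile.expression import ExpressionTrack

        n = len(sig)
        return ExpressionTrack(
            tissue="t",
            positions=np.arange(n) * 2 if positions is None else positions,
            p_values=np.where(sig, 1e-6, 0.5),
            significant=np.asarray(sig, bool),
            probe_length=probe_length,
        )

    def test_no_significant_probes_zero(self):
        g = AnnotatedGenome("g", "ACGT" * 500, circular=True)
        frac = transcribed_fraction(self._track([False] * 1000), identity_map(g))
        assert frac == 0.0

    def test_all_significant_full_circular_tiling_one(self):
        g = AnnotatedGenome("g", "ACGT" * 500, circular=True)
        frac = transcribed_fraction(self._track([True] * 1000), identity_map(g))
        assert frac == 1.0

    def test_partial_coverage_counts_footprints(self):
        g = AnnotatedGenome("g", "ACGT" * 500, circular=True)
        sig = [False] * 1000
        sig[100] = True  # one probe at start 200 covers 60 bases
        frac = transcribed_fraction(self._track(sig), identity_map(g))
        assert frac == pytest.approx(60 / 2000)

    def test_duplicate_copies_inherit_calls(self):
        from tests.test_probes import _planted_repeat_genome
        from mitotile.probes import mask_duplications

        g = _planted_repeat_genome()
        nr = mask_duplications(g, min_len=1_000)
        # probes fully inside the kept copy of the repeat
        starts = np.arange(0, nr.nr_length - 60, 2)
        keep = np.array([nr.nr_to_genome(int(s)) for s in starts])
        inside = (keep >= 4_000) & (keep + 60 <= 5_500)
        track = self._track(inside.tolist(), positions=starts)
        frac = transcribed_fraction(track, nr)
        # both the kept copy and the discarded copy are covered
        assert frac == pytest.approx(2 * 1_500 / 30_000, rel=0.02)


class TestEndToEndCalling:
    def test_zero_noise_recovery_of_truth_intervals(self, plain_genome):
        """Noise-free calling recovers transcribed intervals to ~1 window."""
        from mitotile.simulate import simulate_experiment, simulate_truth

        truths = simulate_truth(plain_genome, [("z", 0.40, 3.0)], seed=11,
                                noise_sd=1.0, typical_interval_bp=6_000)
        truth = truths[0]
        truth.noise_sd = 0.0
        probes = tile_probes(identity_map(plain_genome), plain_genome,
                             circular=True)
        matrix = simulate_experiment(probes, [truth], seed=11)
        # zero-noise raw values are piecewise constant; z-scoring still works
        track = normalize_pipeline(matrix)
        pool = select_background(track, plain_genome.features)
        et = call_expression(track, pool)["z"]
        slack = 61 * 2 + 60  # one window of starts plus one footprint
        called = set(np.flatnonzero(et.significant))
        for s, e, _ in truth.intervals:
            idx = np.flatnonzero(
                (et.positions >= s + slack) & (et.positions + 60 <= e - slack)
            )
            assert set(idx) <= called, "interior of a true interval not called"
        # conversely, probes far from any interval are not called
        far = []
        for i, pos in enumerate(et.positions):
            if all(pos + 60 + slack <= s or pos >= e + slack
                   for s, e, _ in truth.intervals):
                far.append(i)
        assert not (set(far) & called)
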