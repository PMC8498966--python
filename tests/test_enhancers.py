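import numpy as np
import pytest
from scipy import stats

from macmic import enhancers, intervals
from macmic.model import GenomicInterval
from macmic.simulate import generate_ctcf_for_enhancers, generate_hockey_stick_enhancers

from conftest import make_track


class TestHighConfidencePeaks:
    def test_strictly_above_interpolated_quartile(self):
        rows = [("chr1", i * 1000, i * 1000 + 100, float(h)) for i, h in enumerate(range(1, 9))]
        track = make_track(rows, feature="CTCF")
        hc = enhancers.high_confidence_peaks(track)
        # oracle: Q3 of 1..8 under linear interpolation is 6.25
        assert sorted(hc.df["height"]) == [7.0, 8.0]

    def test_all_equal_heights_empty(self):
        track = make_track([("chr1", i * 1000, i * 1000 + 100, 5.0) for i in range(6)])
        assert len(enhancers.high_confidence_peaks(track)) == 0

    def test_single_peak_not_above_its_own_quartile(self):
        track = make_track([("chr1", 0, 100, 3.0)])
        assert len(enhancers.high_confidence_peaks(track)) == 0


def brute_force_cutoff(signals):
    """Exhaustive tangent search: first scaled forward slope >= 1."""
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    for i in range(n - 1):
        if (y[i + 1] - y[i]) / (x[i + 1] - x[i]) >= 1.0:
            return i
    return n - 1


class TestCallSuperenhancers:
    def test_nearby_peaks_are_stitched(self):
        track = make_track([("chr1", 0, 1000), ("chr1", 6000, 7000)], feature="H3K27ac")
        calls = enhancers.stitch_peaks(track)
        assert len(calls) == 1
        assert (calls[0].interval.start, calls[0].interval.end) == (0, 7000)
        assert calls[0].n_constituents == 2

    def test_distant_peaks_not_stitched(self):
        track = make_track([("chr1", 0, 1000), ("chr1", 20_000, 21_000)])
        assert len(enhancers.stitch_peaks(track)) == 2

    def test_stitching_idempotent(self):
        rng = np.random.default_rng(1)
        starts = np.cumsum(rng.integers(1000, 40_000, 50))
        track = make_track([("chr1", int(s), int(s) + 500) for s in starts])
        calls = enhancers.stitch_peaks(track)
        restitched = enhancers.stitch_peaks(
            make_track([(c.interval.chrom, c.interval.start, c.interval.end) for c in calls])
        )
        assert [(c.interval.start, c.interval.end) for c in calls] == [
            (c.interval.start, c.interval.end) for c in restitched
        ]

    def test_cutoff_matches_exhaustive_tangent_search(self):
        rng = np.random.default_rng(7)
        signals = np.concatenate([rng.uniform(0.8, 1.2, 990), rng.uniform(50, 100, 10)])
        rng.shuffle(signals)
        assert enhancers.superenhancer_cutoff_index(signals) == brute_force_cutoff(signals)

    def test_single_extreme_peak_is_super(self):
        rows = [("chr1", i * 50_000, i * 50_000 + 1000, 1.0, 1.0) for i in range(20)]
        rows.append(("chr1", 30 * 50_000, 30 * 50_000 + 1000, 1.0, 500.0))
        calls = enhancers.call_superenhancers(make_track(rows))
        supers = [c for c in calls if c.is_super]
        assert len(supers) == 1
        assert supers[0].total_signal == 500.0

    def test_recall_on_hockey_stick_fixture(self):
        track, truth = generate_hockey_stick_enhancers(990, 10, signal_ratio=50, seed=5)
        calls = enhancers.call_superenhancers(track)
        called = np.array([c.is_super for c in calls])
        recall = (called & truth).sum() / truth.sum()
        assert recall >= 0.9

    def test_under_three_enhancers_all_typical(self, caplog):
        track = make_track([("chr1", 0, 1000, 1.0, 50.0), ("chr1", 50_000, 51_000, 1.0, 1.0)])
        calls = enhancers.call_superenhancers(track)
        assert not any(c.is_super for c in calls)


class TestClassifyCseOse:
    def fixture_calls(self):
        h3k = make_track(
            [
                ("chr1", 0, 10_000, 1.0, 100.0),
                ("chr1", 50_000, 60_000, 1.0, 120.0),
                ("chr1", 100_000, 101_000, 1.0, 1.0),
                ("chr1", 150_000, 151_000, 1.0, 1.2),
                ("chr1", 200_000, 201_000, 1.0, 0.9),
            ],
            feature="H3K27ac",
        )
        return enhancers.call_superenhancers(h3k)

    def test_partition_and_labels(self):
        calls = self.fixture_calls()
        ctcf = make_track(
            [("chr1", 5_000, 5_200, h) for h in (1.0,)]
            + [("chr1", 300_000 + i * 1000, 300_000 + i * 1000 + 200, float(i)) for i in range(8)],
            feature="CTCF",
        )
        hc = enhancers.high_confidence_peaks(ctcf)
        # the peak inside the first SE has height 1.0: below the quartile
        classified = enhancers.classify_cse_ose(calls, hc)
        supers = [c for c in classified if c.is_super]
        assert {c.ctcf_class for c in supers} <= {"CSE", "OSE"}
        assert all(c.ctcf_class == "not-super" for c in classified if not c.is_super)
        first_se = [c for c in supers if c.interval.start == 0][0]
        assert first_se.ctcf_class == "OSE"  # only a sub-threshold CTCF peak

    def test_hc_peak_inside_makes_cse(self):
        calls = self.fixture_calls()
        ctcf = make_track(
            [("chr1", 55_000, 55_200, 50.0)]
            + [("chr1", 400_000 + i * 1000, 400_000 + i * 1000 + 200, 1.0) for i in range(8)],
            feature="CTCF",
        )
        hc = enhancers.high_confidence_peaks(ctcf)
        classified = enhancers.classify_cse_ose(calls, hc)
        se = [c for c in classified if c.interval.start == 50_000][0]
        assert se.ctcf_class == "CSE" and se.n_hc_ctcf == 1

    def test_cse_ose_partition_invariant(self):
        track, _ = generate_hockey_stick_enhancers(200, 8, seed=3)
        ctcf = generate_ctcf_for_enhancers(track, seed=4)
        hc = enhancers.high_confidence_peaks(ctcf)
        classified = enhancers.classify_cse_ose(enhancers.call_superenhancers(track), hc)
        supers = {id(c) for c in classified if c.is_super}
        cse = {id(c) for c in classified if c.ctcf_class == "CSE"}
        ose = {id(c) for c in classified if c.ctcf_class == "OSE"}
        assert cse | ose == supers
        assert cse & ose == set()


class TestAssignEnhancerGenes:
    def genes(self):
        from macmic.model import GeneModel

        return [
            GeneModel("hit", 9_999, "+", GenomicInterval("chr1", 9_999, 15_000, "+")),
            GeneModel("far", 500_000, "+", GenomicInterval("chr1", 500_000, 505_000, "+")),
        ]

    def test_one_bp_body_overlap_assigns(self):
        call = enhancers.EnhancerCall(
            GenomicInterval("chr1", 0, 10_000), 100.0, 1, True, "CSE", 1
        )
        assigned = enhancers.assign_enhancer_genes([call], self.genes(), "CSE")
        assert assigned == {"hit"}

    def test_cse_precedence_over_ose(self):
        cse = enhancers.EnhancerCall(GenomicInterval("chr1", 0, 10_000), 100.0, 1, True, "CSE", 1)
        ose = enhancers.EnhancerCall(GenomicInterval("chr1", 12_000, 14_000), 90.0, 1, True, "OSE", 0)
        cse_genes, ose_genes = enhancers.assign_cse_ose_genes([cse, ose], self.genes())
        assert cse_genes == {"hit"} and ose_genes == set()


class TestEnlargeTypicalEnhancers:
    def test_symmetric_growth_arithmetic(self):
        te = enhancers.EnhancerCall(GenomicInterval("chr1", 45_000, 45_200), 1.0, 1, False)
        se = enhancers.EnhancerCall(GenomicInterval("chr1", 0, 10_000), 100.0, 1, True)
        ctcf = make_track([("chr1", 0, 200)])
        enlarged, _ = enhancers.enlarge_typical_enhancers([te], [se], ctcf, seed=0)
        assert (enlarged[0].interval.start, enlarged[0].interval.end) == (40_100, 50_100)

    def test_all_widths_match_and_clipping_preserves_width(self):
        rng = np.random.default_rng(11)
        typical = [
            enhancers.EnhancerCall(
                GenomicInterval("chr1", int(s), int(s) + int(w)), 1.0, 1, False
            )
            for s, w in zip(rng.integers(0, 5_000, 30), rng.integers(200, 2_000, 30))
        ]
        supers = [
            enhancers.EnhancerCall(
                GenomicInterval("chr1", 100_000 * (i + 1), 100_000 * (i + 1) + int(w)),
                50.0, 1, True,
            )
            for i, w in enumerate(rng.integers(8_000, 40_000, 5))
        ]
        ctcf = make_track([("chr1", 0, 200)])
        enlarged, _ = enhancers.enlarge_typical_enhancers(typical, supers, ctcf, seed=2)
        rng2 = np.random.default_rng(2)
        matches = rng2.integers(0, len(supers), size=len(typical))
        for te, out, m in zip(typical, enlarged, matches):
            assert out.width == supers[m].width
            assert out.interval.start >= 0
            if out.interval.start > 0:  # unclipped: midpoint preserved
                mid_in = (te.interval.start + te.interval.end) // 2
                assert abs((out.interval.start + out.interval.end) / 2 - mid_in) <= 1

    def test_fixed_seed_reproducible(self):
        te = [enhancers.EnhancerCall(GenomicInterval("chr1", 1000, 1200), 1.0, 1, False)] * 5
        se = [
            enhancers.EnhancerCall(GenomicInterval("chr1", 10_000 * i, 10_000 * i + 5_000), 9.0, 1, True)
            for i in range(1, 4)
        ]
        ctcf = make_track([("chr1", 0, 200)])
        out1, s1 = enhancers.enlarge_typical_enhancers(te, se, ctcf, seed=7)
        out2, s2 = enhancers.enlarge_typical_enhancers(te, se, ctcf, seed=7)
        assert [(c.interval.start, c.interval.end) for c in out1] == [
            (c.interval.start, c.interval.end) for c in out2
        ]
        assert s1 == s2


class TestCtcfWidthTrend:
    def test_association_declines_across_width_groups(self):
        # CTCF planted preferentially in wide peaks: the fraction of peaks
        # coinciding with CTCF should fall from widest to narrowest group
        track, _ = generate_hockey_stick_enhancers(950, 50, seed=21)
        ctcf = generate_ctcf_for_enhancers(track, seed=22)
        groups = intervals.width_rank_groups(track, 200)
        fractions = []
        for g in groups:
            ivs = [
                GenomicInterval(r.chrom, int(r.start), int(r.end))
                for r in g.itertuples(index=False)
            ]
            fractions.append(enhancers.ctcf_association_rate(ivs, ctcf))
        rho = stats.spearmanr(range(len(fractions)), fractions).statistic
        assert rho < 0

    def test_enlarged_rate_between_typical_and_super(self):
        rates = []
        for seed in range(20):
            track, truth = generate_hockey_stick_enhancers(300, 12, seed=100 + seed)
            ctcf = generate_ctcf_for_enhancers(track, seed=200 + seed)
            calls = enhancers.call_superenhancers(track)
            supers = [c for c in calls if c.is_super]
            typical = [c for c in calls if not c.is_super]
            _, summary = enhancers.enlarge_typical_enhancers(typical, supers, ctcf, seed=seed)
            rates.append(summary)
        mean = {k: np.mean([r[k] for r in rates]) for k in rates[0]}
        assert mean["typical_ctcf_rate"] < mean["enlarged_ctcf_rate"] < mean["super_ctcf_rate"]
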