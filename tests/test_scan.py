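import numpy as np
import pytest

from ancestry_scan.genome_io import ConcatRef, Genome, Interval, jaccard
from ancestry_scan.scan import (
    AncestryTrack,
    LowDivConfig,
    LowDivMask,
    ScanConfig,
    build_synteny_map,
    classify_interval,
    classify_intervals,
    competitive_classify,
    final_blocks,
    identity_synteny_map,
    low_divergence_mask,
    percent_donor_intervals,
    run_introgression_scan,
    seed_blocks,
    window_smoothed_classes,
)
from ancestry_scan.synthetic_data import SimConfig, simulate_trio
from ancestry_scan.window_mapper import FilterConfig, WindowSpec
from conftest import make_hit


def track_from_labels(labels, step=2_500, window_len=10_000, seq_name="c1"):
    """Build an AncestryTrack directly from a label sequence."""
    windows = [
        Interval(seq_name, i * step, i * step + window_len) for i in range(len(labels))
    ]
    return AncestryTrack(
        genome_id="q",
        windows={seq_name: windows},
        labels={seq_name: list(labels)},
        scores={seq_name: [{} for _ in labels]},
    )


class TestLowDivergenceMask:
    def _recipient(self, length=205_000):
        return Genome(genome_id="R", sequences={"c1": "A" * length})

    def _hits(self, n_above, n_total=40, step=5_000):
        hits = []
        for i in range(n_total):
            matches = 9_850 if i < n_above else 9_700  # identity .985 / .970
            hits.append(make_hit(query_seq="c1", qstart=i * step, matches=matches))
        return hits

    def test_21_of_40_masked(self):
        mask = low_divergence_mask(self._hits(21), self._recipient())
        # 21/40 = 52.5% > 50% -> the 200 kb bin is masked
        assert mask.intervals == [Interval("c1", 0, 200_000)]

    def test_20_of_40_not_masked_strict(self):
        mask = low_divergence_mask(self._hits(20), self._recipient())
        assert mask.intervals == []

    def test_no_hits_empty_mask(self):
        mask = low_divergence_mask([], self._recipient())
        assert mask.intervals == []

    def test_counting_oracle(self):
        # derived by counting: windows above the identity bar / windows in bin
        hits = self._hits(25)
        above = sum(1 for h in hits if h.identity > 0.98)
        assert above == 25
        mask = low_divergence_mask(hits, self._recipient())
        assert bool(mask.intervals) == (above / 40 > 0.5)

    def test_adjacent_bins_merge(self):
        g = Genome(genome_id="R", sequences={"c1": "A" * 405_000})
        hits = [
            make_hit(query_seq="c1", qstart=i * 5_000, matches=9_990) for i in range(80)
        ]
        mask = low_divergence_mask(hits, g)
        assert mask.intervals == [Interval("c1", 0, 400_000)]

    def test_overlaps_query(self):
        mask = LowDivMask([Interval("c1", 100, 200), Interval("c1", 500, 600)])
        assert mask.overlaps("c1", 150, 160)
        assert mask.overlaps("c1", 0, 101)
        assert not mask.overlaps("c1", 200, 500)
        assert not mask.overlaps("c2", 0, 1_000)


def _concat():
    r = Genome(genome_id="R", sequences={"c1": "A" * 100_000})
    d = Genome(genome_id="D", sequences={"c1": "A" * 100_000})
    return ConcatRef(recipient=r, donor=d)


class TestCompetitiveClassify:
    def _windows(self, n=3):
        return [Interval("c1", i * 2_500, i * 2_500 + 10_000) for i in range(n)]

    def test_donor_only_hit(self):
        concat = _concat()
        hits = [make_hit(query_seq="c1", qstart=0, target_seq="D#c1", matches=9_950, window_index=0)]
        track = competitive_classify(hits, concat, self._windows(1))
        assert track.labels["c1"] == ["donor"]

    def test_equal_scores_ambiguous(self):
        concat = _concat()
        hits = [
            make_hit(query_seq="c1", qstart=0, target_seq="R#c1", matches=9_950, window_index=0),
            make_hit(query_seq="c1", qstart=0, target_seq="D#c1", matches=9_950, window_index=0),
        ]
        track = competitive_classify(hits, concat, self._windows(1))
        assert track.labels["c1"] == ["ambiguous"]

    def test_masked_overrides_hits(self):
        concat = _concat()
        hits = [make_hit(query_seq="c1", qstart=0, target_seq="D#c1", matches=9_950, window_index=0)]
        mask = LowDivMask([Interval("c1", 0, 50_000)])
        track = competitive_classify(hits, concat, self._windows(1), mask=mask)
        assert track.labels["c1"] == ["masked"]

    def test_no_hits_unmapped(self):
        track = competitive_classify([], _concat(), self._windows(2))
        assert track.labels["c1"] == ["unmapped", "unmapped"]

    def test_low_identity_best_hit_unmapped(self):
        hits = [make_hit(query_seq="c1", qstart=0, target_seq="D#c1", matches=9_700, window_index=0)]
        track = competitive_classify(hits, _concat(), self._windows(1),
                                     cfg=FilterConfig(min_identity=0.99))
        assert track.labels["c1"] == ["unmapped"]

    def test_label_partition_invariant(self, rng):
        concat = _concat()
        windows = self._windows(30)
        hits = []
        for i in range(30):
            for origin in ("R", "D"):
                if rng.random() < 0.7:
                    hits.append(
                        make_hit(query_seq="c1", qstart=i * 2_500, window_index=i,
                                 target_seq=f"{origin}#c1",
                                 matches=int(rng.integers(9_800, 10_001)))
                    )
        mask = LowDivMask([Interval("c1", 0, 20_000)])
        track = competitive_classify(hits, concat, windows, mask=mask)
        counts = track.label_counts()
        assert sum(counts.values()) == 30 == track.n_windows()

    def test_unknown_window_raises(self):
        hits = [make_hit(query_seq="c1", qstart=999, target_seq="D#c1")]
        with pytest.raises(ValueError):
            competitive_classify(hits, _concat(), self._windows(1))


class TestSeedBlocks:
    def test_exactly_ten(self):
        track = track_from_labels(["donor"] * 10)
        blocks = seed_blocks(track)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (0, 9 * 2_500 + 10_000)

    def test_nine_is_none(self):
        assert seed_blocks(track_from_labels(["donor"] * 9)) == []

    def test_run_length_enumeration(self):
        labels = ["donor"] * 12 + ["recipient"] + ["donor"] * 10
        blocks = seed_blocks(track_from_labels(labels))
        assert len(blocks) == 2

    def test_masked_breaks_run(self):
        labels = ["donor"] * 9 + ["masked"] + ["donor"] * 9
        assert seed_blocks(track_from_labels(labels)) == []


class TestPercentDonor:
    def test_all_donor(self):
        track = track_from_labels(["donor"] * 50)
        (iv,) = percent_donor_intervals(track)
        assert iv.pct_donor == 100.0

    def test_35_donor_15_recipient(self):
        track = track_from_labels(["donor"] * 35 + ["recipient"] * 15)
        (iv,) = percent_donor_intervals(track)
        assert iv.pct_donor == pytest.approx(100 * 35 / 50)

    def test_ambiguous_excluded_from_denominator(self):
        labels = ["donor"] * 10 + ["recipient"] * 10 + ["ambiguous"] * 30
        (iv,) = percent_donor_intervals(track_from_labels(labels))
        assert iv.pct_donor == pytest.approx(50.0)  # 10 / (10 + 10)

    def test_masked_windows_excluded_entirely(self):
        labels = ["masked"] * 10 + ["donor"] * 50
        (iv,) = percent_donor_intervals(track_from_labels(labels))
        assert iv.pct_donor == 100.0
        assert iv.first_window == 10

    def test_short_chromosome_skipped(self):
        assert percent_donor_intervals(track_from_labels(["donor"] * 49)) == []

    def test_pct_in_range(self, rng):
        labels = [np.random.default_rng(0).choice(
            ["donor", "recipient", "ambiguous", "unmapped"]) for _ in range(120)]
        for iv in percent_donor_intervals(track_from_labels(labels)):
            assert 0.0 <= iv.pct_donor <= 100.0


class TestClassifyIntervals:
    @pytest.mark.parametrize(
        "pct,expected",
        [(70.0, "introgressed"), (29.9, "recipient"), (50.0, "ambiguous"),
         (100.0, "introgressed"), (30.0, "ambiguous"), (69.9, "ambiguous"), (0.0, "recipient")],
    )
    def test_boundaries(self, pct, expected):
        assert classify_interval(pct) == expected

    def test_exhaustive_and_exclusive(self):
        for pct in np.linspace(0, 100, 1_001):
            assert classify_interval(float(pct)) in {"introgressed", "ambiguous", "recipient"}


class TestFinalBlocks:
    def _run(self, labels, cfg=ScanConfig()):
        track = track_from_labels(labels)
        smooth = percent_donor_intervals(track, cfg)
        classes = classify_intervals(smooth, cfg)
        return final_blocks(track, smooth, classes, cfg)

    def test_uniform_donor(self):
        blocks = self._run(["donor"] * 60)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.label == "introgressed"
        assert (b.start, b.end) == (0, 59 * 2_500 + 10_000)

    def test_no_donor_no_blocks(self):
        assert self._run(["recipient"] * 60) == []

    def test_planted_block_recovery_seed11(self):
        cfg = SimConfig(n_chroms=1, chrom_len=1_000_000, divergence=0.01,
                        introgressions=[("chr1", 350_000, 650_000)], seed=11)
        r, d, c, truth = simulate_trio(cfg)
        res = run_introgression_scan(c, r, d, apply_lowdiv_mask=False)
        intro = res.introgressed_blocks
        assert len(intro) == 1
        b = intro[0]
        t = truth.introgressions[0]
        inter = min(b.end, t.end) - max(b.start, t.start)
        assert inter / (b.end - b.start) >= 0.9
        assert inter / (t.end - t.start) >= 0.9

    def test_introgressed_block_contains_donor_window(self):
        labels = ["donor"] * 30 + ["recipient"] * 40
        track = track_from_labels(labels)
        smooth = percent_donor_intervals(track)
        classes = classify_intervals(smooth)
        for b in final_blocks(track, smooth, classes):
            if b.label == "introgressed":
                covered = [
                    lab for w, lab in zip(track.windows["c1"], track.labels["c1"])
                    if w.start >= b.start and w.end <= b.end
                ]
                assert "donor" in covered

    def test_hi_threshold_monotonicity(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            labels = list(r.choice(["donor", "recipient", "ambiguous"], size=200,
                                   p=[0.5, 0.4, 0.1]))
            prev = None
            for hi in (60.0, 70.0, 80.0, 90.0):
                cfg = ScanConfig(hi_threshold=hi)
                blocks = self._run(labels, cfg)
                total = sum(b.width for b in blocks if b.label == "introgressed")
                if prev is not None:
                    assert total <= prev
                prev = total


class TestSmoothedClasses:
    def test_nearest_centre_tie_goes_left(self):
        cfg = ScanConfig(min_run=2, smooth_n=4, smooth_overlap=3,
                         hi_threshold=70.0, lo_threshold=30.0)
        # 8 windows; intervals of 4 windows sliding by 1
        labels = ["donor"] * 4 + ["recipient"] * 4
        track = track_from_labels(labels)
        smooth = percent_donor_intervals(track, cfg)
        classes = classify_intervals(smooth, cfg)
        assigned = window_smoothed_classes(track, smooth, classes, cfg)["c1"]
        assert len(assigned) == 8
        assert all(a is not None for a in assigned)


class TestSyntenyMap:
    def test_identity_projection(self):
        g = Genome(genome_id="g", sequences={"c1": "A" * 50_000})
        smap = identity_synteny_map(g)
        iv = Interval("c1", 5_000, 6_000)
        assert smap.project_interval(iv) == [Interval("c1", 5_000, 6_000)]

    def test_constant_offset(self):
        hits = [
            make_hit(query_seq="c1", qstart=q, tstart=q + 1_000)
            for q in range(0, 20_000, 2_500)
        ]
        smap = build_synteny_map(hits)
        out = smap.project_interval(Interval("c1", 5_000, 6_000))
        assert out == [Interval("t1", 6_000, 7_000)]

    def test_before_first_anchor_unplaced(self):
        hits = [make_hit(query_seq="c1", qstart=q, tstart=q) for q in range(10_000, 30_000, 2_500)]
        smap = build_synteny_map(hits)
        assert smap.project_interval(Interval("c1", 0, 1_000)) == []

    def test_unknown_sequence_raises(self):
        smap = build_synteny_map([make_hit(query_seq="c1")])
        with pytest.raises(KeyError):
            smap.project_interval(Interval("cX", 0, 10))

    def test_duplicate_window_rejected(self):
        hits = [make_hit(query_seq="c1", qstart=0), make_hit(query_seq="c1", qstart=0)]
        with pytest.raises(ValueError):
            build_synteny_map(hits)

    def test_discontinuity_split(self):
        hits = [make_hit(query_seq="c1", qstart=q, tstart=q, target_seq="t1")
                for q in range(0, 10_000, 2_500)]
        hits += [make_hit(query_seq="c1", qstart=q, tstart=q - 10_000, target_seq="t2")
                 for q in range(10_000, 20_000, 2_500)]
        smap = build_synteny_map(hits)
        out = smap.project_interval(Interval("c1", 0, 20_000))
        assert len(out) == 2
        assert {o.seq_name for o in out} == {"t1", "t2"}


class TestScanConfig:
    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            ScanConfig(hi_threshold=30.0, lo_threshold=70.0)

    def test_bad_smoothing(self):
        with pytest.raises(ValueError):
            ScanConfig(smooth_n=50, smooth_overlap=50)
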