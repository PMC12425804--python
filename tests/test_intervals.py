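import numpy as np
import pandas as pd
import pytest

from brgdose.intervals import (
    IntervalSet,
    annotate_elements,
    consensus_peaks,
    count_overlaps,
    read_bed,
    read_chrom_sizes,
    shuffle_intervals,
)


def brute_force_overlaps(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """O(n*m) overlap oracle: >=1 bp intersection on the same chromosome."""
    out = np.zeros(len(query), dtype=int)
    for i, q in query.df.iterrows():
        for _, s in subject.df.iterrows():
            if q["chrom"] == s["chrom"] and q["start"] < s["end"] and s["start"] < q["end"]:
                out[i] += 1
    return out


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000) -> IntervalSet:
    recs = []
    for i in range(n):
        start = int(rng.integers(0, max_pos))
        recs.append((rng.choice(chroms), start, start + int(rng.integers(1, 500)), f"r{i}"))
    return IntervalSet.from_records(recs)


class TestIntervalSet:
    def test_half_open_invariants_enforced(self):
        with pytest.raises(ValueError, match="end > start"):
            IntervalSet.from_records([("chr1", 100, 100)])
        with pytest.raises(ValueError, match=">= 0"):
            IntervalSet.from_records([("chr1", -5, 10)])

    def test_bed_round_trip_byte_identical(self, tmp_path):
        ivs = IntervalSet.from_records(
            [("chr1", 100, 200, "a", 5.0), ("chr1", 300, 400, "b"), ("chr2", 0, 50, "c", 1.5)]
        )
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        ivs.to_bed(p1)
        read_bed(p1).to_bed(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_reader_tolerates_track_lines_and_comments(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text(
            "track name=peaks\n# comment\nchr1\t10\t20\nbrowser position chr1\nchr1\t30\t40\tpk\t7\t+\n"
        )
        ivs = read_bed(p)
        assert len(ivs) == 2
        assert ivs.df.loc[1, "score"] == 7

    def test_chrom_sizes_reader(self, tmp_path):
        p = tmp_path / "sizes.tsv"
        p.write_text("chr1\t1000\nchr2\t2000\n")
        assert read_chrom_sizes(p) == {"chr1": 1000, "chr2": 2000}


class TestConsensus:
    def test_identical_replicates_return_rep1(self):
        ivs = IntervalSet.from_records([("chr1", 0, 100, "a"), ("chr1", 200, 300, "b")])
        out = consensus_peaks(ivs, ivs)
        assert out.df[["chrom", "start", "end"]].equals(ivs.df[["chrom", "start", "end"]])

    def test_disjoint_replicates_empty(self):
        r1 = IntervalSet.from_records([("chr1", 0, 100)])
        r2 = IntervalSet.from_records([("chr2", 0, 100)])
        assert len(consensus_peaks(r1, r2)) == 0

    def test_single_bp_overlap_kept_half_open_abutment_dropped(self):
        r1 = IntervalSet.from_records([("chr1", 100, 200, "a")])
        assert len(consensus_peaks(r1, IntervalSet.from_records([("chr1", 199, 300)]))) == 1
        assert len(consensus_peaks(r1, IntervalSet.from_records([("chr1", 200, 300)]))) == 0

    def test_merge_dialect_unions_coordinates(self):
        r1 = IntervalSet.from_records([("chr1", 100, 200, "a")])
        r2 = IntervalSet.from_records([("chr1", 150, 320)])
        out = consensus_peaks(r1, r2, merge=True)
        assert (out.df.loc[0, "start"], out.df.loc[0, "end"]) == (100, 320)

    def test_agrees_with_brute_force_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            r1 = random_intervals(rng, int(rng.integers(1, 200)))
            r2 = random_intervals(rng, int(rng.integers(1, 200)))
            expected = (brute_force_overlaps(r1, r2) > 0).sum()
            assert len(consensus_peaks(r1, r2)) == expected


class TestAnnotation:
    TSS = IntervalSet.from_records([("chr1", 10_000, 10_001, "tss1")])
    CTCF = IntervalSet.from_records([("chr1", 50_000, 50_200, "ctcf1")])

    def annotate(self, peaks):
        return annotate_elements(peaks, self.TSS, self.CTCF)

    def test_peak_within_1kb_of_tss_is_promoter(self):
        cls = self.annotate(IntervalSet.from_records([("chr1", 9_500, 9_700, "p")]))
        assert cls["p"] == "promoter"

    def test_window_boundary_half_open(self):
        # window [9000, 11001): a peak ending at 9000 misses, ending at 9001 hits
        cls = self.annotate(
            IntervalSet.from_records(
                [("chr1", 8_800, 9_000, "out"), ("chr1", 8_800, 9_001, "in")]
            )
        )
        assert cls["out"] == "enhancer" and cls["in"] == "promoter"

    def test_promoter_priority_over_ctcf(self):
        tss = IntervalSet.from_records([("chr1", 50_100, 50_101, "t")])
        peaks = IntervalSet.from_records([("chr1", 50_000, 50_200, "p")])
        cls = annotate_elements(peaks, tss, self.CTCF)
        assert cls["p"] == "promoter"

    def test_ctcf_overlap_is_insulator_and_rest_enhancer(self):
        cls = self.annotate(
            IntervalSet.from_records(
                [("chr1", 50_100, 50_400, "i"), ("chr1", 80_000, 80_300, "e")]
            )
        )
        assert cls["i"] == "insulator" and cls["e"] == "enhancer"

    def test_annotation_total_with_empty_tss(self):
        peaks = IntervalSet.from_records([("chr1", 9_500, 9_700, "a"), ("chr1", 50_050, 50_150, "b")])
        cls = annotate_elements(peaks, IntervalSet.empty(), self.CTCF)
        assert set(cls) == {"enhancer", "insulator"}


class TestCountOverlaps:
    def test_identity_and_empty_subject(self):
        ivs = IntervalSet.from_records([("chr1", 0, 10, "a"), ("chr1", 20, 30, "b")])
        counts, total = count_overlaps(ivs, ivs)
        assert (counts == 1).all() and total == 2
        counts, total = count_overlaps(ivs, IntervalSet.empty())
        assert (counts == 0).all() and total == 0

    def test_nested_intervals_count_once_per_subject_hit(self):
        outer = IntervalSet.from_records([("chr1", 0, 1000, "outer")])
        inner = IntervalSet.from_records(
            [("chr1", 10, 20), ("chr1", 30, 40), ("chr1", 500, 600)]
        )
        counts, _ = count_overlaps(outer, inner)
        assert counts["outer"] == 3

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            q = random_intervals(rng, int(rng.integers(1, 200)))
            s = random_intervals(rng, int(rng.integers(1, 200)))
            counts, total = count_overlaps(q, s)
            oracle = brute_force_overlaps(q, s)
            assert (counts.to_numpy() == oracle).all()
            assert total == (oracle > 0).sum()


class TestShuffle:
    GENOME = {"chr1": 100_000, "chr2": 50_000}

    def test_lengths_preserved_and_deterministic(self):
        rng = np.random.default_rng(3)
        ivs = random_intervals(rng, 50, chroms=("chr1", "chr2"), max_pos=40_000)
        s1 = shuffle_intervals(ivs, self.GENOME, seed=9)
        s2 = shuffle_intervals(ivs, self.GENOME, seed=9)
        assert s1.df.equals(s2.df)
        assert sorted(s1.lengths()) == sorted(ivs.lengths())
        s3 = shuffle_intervals(ivs, self.GENOME, seed=10)
        assert not s3.df["start"].equals(s1.df["start"])

    def test_within_chrom_preserves_chromosome_counts(self):
        rng = np.random.default_rng(4)
        ivs = random_intervals(rng, 80, chroms=("chr1", "chr2"), max_pos=40_000)
        s = shuffle_intervals(ivs, self.GENOME, seed=1, within_chrom=True)
        assert s.df["chrom"].value_counts().to_dict() == ivs.df["chrom"].value_counts().to_dict()

    def test_placements_stay_on_genome(self):
        rng = np.random.default_rng(5)
        ivs = random_intervals(rng, 100, chroms=("chr2",), max_pos=40_000)
        s = shuffle_intervals(ivs, self.GENOME, seed=2)
        ends = s.df.apply(lambda r: self.GENOME[r["chrom"]], axis=1)
        assert (s.df["start"] >= 0).all() and (s.df["end"] <= ends).all()

    def test_oversized_interval_errors(self):
        ivs = IntervalSet.from_records([("chr2", 0, 60_000, "big")])
        with pytest.raises(ValueError, match="fit"):
            shuffle_intervals(ivs, self.GENOME, seed=0)
        with pytest.raises(ValueError, match="longer than every"):
            shuffle_intervals(
                IntervalSet.from_records([("chr1", 0, 200_000)]),
                self.GENOME, seed=0, within_chrom=False,
            )
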