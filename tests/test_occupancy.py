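"""3'-end recording conventions, mispriming filter, normalization,
replicate handling, and count tables."""

import numpy as np
import pandas as pd
import pytest

from netseq.annotation import Gene, GeneAnnotationSet
from netseq.occupancy import (OccupancyTrack, build_count_table,
                              filter_mispriming, gene_rpkm, make_reads,
                              merge_replicates, normalize_per_million,
                              reads_from_bam, record_three_prime_ends,
                              replicate_correlation)

CHROMS = {"chr1": 1000}


class TestRecordThreePrimeEnds:
    def test_minus_alignment_records_five_prime_end_on_plus_strand(self):
        """A read aligned on - over [100, 175) has its sequencing 5' end
        at 174; first-strand chemistry puts the transcript on +."""
        reads = make_reads([("chr1", 100, 175, "-", "AAAAAA")])
        track = record_three_prime_ends(reads, CHROMS)
        assert track.get("chr1", "+")[174] == 1
        assert track.get("chr1", "-").sum() == 0

    def test_plus_alignment_maps_to_minus_transcript_at_start(self):
        reads = make_reads([("chr1", 100, 175, "+", "AAAAAA")])
        track = record_three_prime_ends(reads, CHROMS)
        assert track.get("chr1", "-")[100] == 1

    def test_second_strand_orientation_keeps_alignment_strand(self):
        reads = make_reads([("chr1", 100, 175, "-", "AAAAAA")])
        track = record_three_prime_ends(reads, CHROMS,
                                        orientation="fr-secondstrand")
        assert track.get("chr1", "-")[174] == 1

    def test_empty_input_gives_empty_track(self):
        track = record_three_prime_ends(make_reads([]), CHROMS)
        assert track.total() == 0
        assert track.library_size == 0

    def test_conservation_of_read_count(self):
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 900, size=1000)
        reads = make_reads([("chr1", int(s), int(s) + 50,
                             rng.choice(["+", "-"]), "AAAAAA")
                            for s in starts])
        track = record_three_prime_ends(reads, CHROMS)
        assert track.total() == 1000

    def test_unknown_chromosome_skipped_with_warning(self):
        reads = make_reads([("chrX", 10, 60, "+", "AAAAAA"),
                            ("chr1", 10, 60, "+", "AAAAAA")])
        with pytest.warns(UserWarning, match="unknown chromosome"):
            track = record_three_prime_ends(reads, CHROMS)
        assert track.total() == 1
        assert track.meta["skipped_unknown_chrom"] == 1

    def test_strand_swap_symmetry(self):
        rng = np.random.default_rng(2)
        recs = [("chr1", int(s), int(s) + 40,
                 str(rng.choice(["+", "-"])), "AAAAAA")
                for s in rng.integers(0, 900, size=200)]
        flipped = [(c, s, e, "-" if st == "+" else "+", b)
                   for c, s, e, st, b in recs]
        t1 = record_three_prime_ends(make_reads(recs), CHROMS)
        t2 = record_three_prime_ends(make_reads(flipped), CHROMS)
        # flipping alignment strand moves the recorded end (start <-> end-1)
        # AND swaps the transcript strand; check total conservation and
        # that per-strand totals swap
        assert t1.total() == t2.total()
        assert t1.get("chr1", "+").sum() == t2.get("chr1", "-").sum()


class TestMisprimingFilter:
    @pytest.fixture
    def genome(self):
        return {"chr1": "ACGT" * 250}

    def test_exact_adjacent_match_removed(self, genome):
        # minus alignment over [100, 120): 3' end at 119, transcript "+",
        # adjacent hexamer = genome[120:126]
        hexamer = genome["chr1"][120:126]
        reads = make_reads([("chr1", 100, 120, "-", hexamer)])
        retained, removed = filter_mispriming(reads, genome)
        assert removed == 1 and retained.empty

    def test_single_mismatch_retained(self, genome):
        hexamer = genome["chr1"][120:126]
        bad = ("A" if hexamer[-1] != "A" else "C")
        reads = make_reads([("chr1", 100, 120, "-", hexamer[:-1] + bad)])
        retained, removed = filter_mispriming(reads, genome)
        assert removed == 0 and len(retained) == 1

    def test_minus_transcript_uses_reverse_complement(self, genome):
        # plus alignment at [100, 120): 3' end 100, transcript "-",
        # adjacent = revcomp(genome[94:100])
        from netseq.genome import revcomp
        hexamer = revcomp(genome["chr1"][94:100])
        reads = make_reads([("chr1", 100, 120, "+", hexamer)])
        _, removed = filter_mispriming(reads, genome)
        assert removed == 1

    def test_chromosome_edge_read_retained_and_flagged(self, genome):
        reads = make_reads([("chr1", 980, 1000, "-", "ACGTAC")])
        retained, removed = filter_mispriming(reads, genome)
        assert removed == 0
        assert retained.attrs["edge_flagged"] == 1


class TestNormalization:
    def _track(self, count=4, library=2_000_000):
        t = OccupancyTrack(CHROMS)
        t.get("chr1", "+")[10] = count
        t.library_size = library
        return t

    def test_per_million_formula(self):
        norm = normalize_per_million(self._track())
        assert norm.get("chr1", "+")[10] == pytest.approx(2.0)
        assert norm.normalized

    def test_normalized_total_is_one_million(self):
        t = OccupancyTrack(CHROMS)
        rng = np.random.default_rng(3)
        t.get("chr1", "+")[:] = rng.integers(0, 5, size=1000)
        t.library_size = t.total()
        assert normalize_per_million(t).total() == pytest.approx(1e6)

    def test_double_normalization_errors(self):
        norm = normalize_per_million(self._track())
        with pytest.raises(ValueError, match="already normalized"):
            normalize_per_million(norm)

    def test_empty_library_errors(self):
        with pytest.raises(ValueError, match="library_size 0"):
            normalize_per_million(OccupancyTrack(CHROMS))


class TestRpkm:
    def test_formula_case(self):
        ann = GeneAnnotationSet([Gene("g", "chr1", 0, 1000, "+")], CHROMS)
        t = OccupancyTrack(CHROMS)
        t.get("chr1", "+")[:1000] = 0.1  # 100 reads over 1 kb
        t.library_size = 1_000_000
        assert gene_rpkm(t, ann)["g"] == pytest.approx(100.0)

    def test_zero_reads_zero_rpkm(self):
        ann = GeneAnnotationSet([Gene("g", "chr1", 0, 500, "-")], CHROMS)
        t = OccupancyTrack(CHROMS)
        t.library_size = 10
        assert gene_rpkm(t, ann)["g"] == 0.0

    def test_against_interval_sum_oracle(self, toy_world):
        _, ann, rep1, _, _ = toy_world
        rpkm = gene_rpkm(rep1, ann)
        rng = np.random.default_rng(4)
        for g in rng.choice(ann.genes, size=20, replace=False):
            arr = rep1.get(g.chrom, g.strand)
            brute = sum(float(arr[p]) for p in range(g.start, g.end))
            expected = brute / (g.length / 1000) / (rep1.library_size / 1e6)
            assert rpkm[g.gene_id] == pytest.approx(expected)


class TestReplicateCorrelation:
    def test_identical_vectors_give_one(self):
        a = pd.Series([1.0, 2.0, 5.0], index=list("abc"))
        assert replicate_correlation(a, a) == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        b = pd.Series([3.0, 1.0, 2.0], index=list("abc"))
        # closed form: r = cov/(sd_a sd_b) = -0.5 -> R^2 = 0.25
        with pytest.warns(UserWarning):
            r2 = replicate_correlation(a, b)
        assert r2 == pytest.approx(0.25)

    def test_below_threshold_warns(self):
        rng = np.random.default_rng(5)
        x = pd.Series(rng.random(100))
        y = pd.Series(0.85 * x + 0.5 * rng.random(100))
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert r2 < 0.97
        with pytest.warns(UserWarning, match="below threshold"):
            replicate_correlation(x, y, threshold=0.97)

    def test_too_few_genes_errors(self):
        a = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            replicate_correlation(a, a)


class TestMergeReplicates:
    def _tracks(self, n=2):
        tracks = []
        for i in range(n):
            t = OccupancyTrack(CHROMS)
            t.get("chr1", "+")[100 + i] = 10
            t.get("chr1", "+")[500] = 5
            t.library_size = 15
            tracks.append(t)
        return tracks

    def test_identical_tracks_preserve_normalized_profile(self):
        t1, _ = self._tracks()
        t2 = t1.copy()
        merged = merge_replicates(t1, t2)
        single = normalize_per_million(t1)
        assert np.allclose(merged.get("chr1", "+"), single.get("chr1", "+"))

    def test_merge_conserves_total(self):
        t1, t2 = self._tracks()
        merged = merge_replicates(t1, t2)
        assert merged.total() == pytest.approx(1e6)
        assert merged.library_size == 30

    def test_three_way_merge_is_associative(self):
        t1, t2 = self._tracks()
        t3 = t1.copy()
        direct = merge_replicates(t1, t2, t3)
        # pairwise: merge raw sums first, then bring in the third
        pair = OccupancyTrack(CHROMS)
        for t in (t1, t2):
            for key in pair.data:
                pair.data[key] += t.data[key]
        pair.library_size = t1.library_size + t2.library_size
        stepwise = merge_replicates(pair, t3)
        assert np.allclose(direct.get("chr1", "+"),
                           stepwise.get("chr1", "+"))

    def test_mixing_normalized_and_raw_errors(self):
        t1, t2 = self._tracks()
        with pytest.raises(ValueError, match="raw"):
            merge_replicates(normalize_per_million(t1), t2)


class TestCountTable:
    def test_sense_antisense_partition_by_strand(self):
        genes = [Gene("gA", "chr1", 100, 400, "+"),
                 Gene("antigA", "chr1", 100, 400, "-")]
        ann = GeneAnnotationSet(genes, CHROMS)
        t = OccupancyTrack(CHROMS)
        t.get("chr1", "+")[200] = 7
        t.get("chr1", "-")[300] = 3
        t.library_size = 10
        table = build_count_table({"s1": t}, ann)
        assert table.loc["gA", "s1"] == 7
        assert table.loc["antigA", "s1"] == 3

    def test_totals_complement_intergenic_reads(self, toy_world):
        """Gene-body totals equal library size minus reads outside genes
        when every read falls in a gene (antisense off)."""
        from netseq.simulate import (SimulationConfig, generate_toy_genome,
                                     simulate_occupancy)
        cfg = SimulationConfig(n_genes=10, antisense_fraction=0.0, seed=8)
        _, ann = generate_toy_genome(cfg)
        rep1, _, _ = simulate_occupancy(ann, cfg)
        table = build_count_table({"s1": rep1}, ann)
        assert table["s1"].sum() == rep1.library_size

    def test_empty_sample_is_all_zero(self):
        ann = GeneAnnotationSet([Gene("g", "chr1", 0, 500, "+")], CHROMS)
        t = OccupancyTrack(CHROMS)
        table = build_count_table({"empty": t}, ann)
        assert (table["empty"] == 0).all()


class TestBamRoundTrip:
    def test_sam_reads_match_direct_records(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": "chr1", "LN": 1000}]}
        path = tmp_path / "toy.sam"
        with pysam.AlignmentFile(path, "wh", header=header) as out:
            for i, (start, rev) in enumerate([(100, True), (300, False)]):
                a = pysam.AlignedSegment()
                a.query_name = f"r{i}#ACGTAC"
                a.query_sequence = "A" * 50
                a.reference_id = 0
                a.reference_start = start
                a.cigarstring = "50M"
                a.flag = 16 if rev else 0
                a.mapping_quality = 60
                out.write(a)
        reads = reads_from_bam(path)
        assert list(reads["start"]) == [100, 300]
        assert list(reads["strand"]) == ["-", "+"]
        assert set(reads["barcode"]) == {"ACGTAC"}
        track = record_three_prime_ends(reads, CHROMS)
        assert track.get("chr1", "+")[149] == 1
        assert track.get("chr1", "-")[300] == 1
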