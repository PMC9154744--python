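"""Feature assembly around pause loci and real-vs-control testing."""

import numpy as np
import pandas as pd
import pytest

from netseq.annotation import Gene, GeneAnnotationSet
from netseq.features import (FeatureSpec, assemble_features,
                             feature_distribution_tests, labeled_loci,
                             shuffled_control_loci, write_flank_fasta)
from netseq.genome import revcomp
from netseq.occupancy import OccupancyTrack

CHROMS = {"chr1": 4000}


def loci_frame(rows, label=None):
    df = pd.DataFrame(rows, columns=["chrom", "position", "strand",
                                     "gene_id"])
    if label is not None:
        df["label"] = label
    return df


@pytest.fixture
def world():
    rng = np.random.default_rng(61)
    seq = "".join(rng.choice(list("ACGT"), size=4000))
    genome = {"chr1": seq}
    gene = Gene("g", "chr1", 500, 3500, "+")
    ann = GeneAnnotationSet([gene], CHROMS)
    return genome, gene, ann


class TestControlLoci:
    def _pauses(self, gene, n=40, seed=0):
        rng = np.random.default_rng(seed)
        offsets = rng.choice(gene.length, size=n, replace=False)
        return loci_frame([(gene.chrom, gene.start + int(o), gene.strand,
                            gene.gene_id) for o in offsets])

    def test_per_gene_count_match_and_disjoint(self, world):
        _, gene, ann = world
        pauses = self._pauses(gene)
        for seed in range(5):
            ctrl = shuffled_control_loci(pauses, ann, seed)
            assert len(ctrl) == len(pauses)
            assert not set(map(tuple, ctrl[["chrom", "position"]]
                               .itertuples(index=False))) \
                & set(map(tuple, pauses[["chrom", "position"]]
                          .itertuples(index=False)))

    def test_determinism(self, world):
        _, gene, ann = world
        pauses = self._pauses(gene)
        assert shuffled_control_loci(pauses, ann, 9).equals(
            shuffled_control_loci(pauses, ann, 9))

    def test_saturated_gene_errors(self):
        gene = Gene("tiny", "chr1", 0, 700, "+")
        ann = GeneAnnotationSet([gene], CHROMS)
        pauses = loci_frame([("chr1", i, "+", "tiny") for i in range(700)])
        with pytest.raises(ValueError, match="saturated"):
            shuffled_control_loci(pauses, ann, 0)

    def test_controls_sample_gene_body_background(self, world):
        """Aggregated over many seeds, control trinucleotide frequencies
        approach the gene-body background distribution."""
        genome, gene, ann = world
        pauses = self._pauses(gene, n=100)
        seq = genome["chr1"]
        body = [seq[i - 1:i + 2] for i in
                range(gene.start + 1, gene.end - 1)]
        background = pd.Series(body).value_counts(normalize=True)
        counts: dict[str, int] = {}
        total = 0
        for seed in range(50):
            ctrl = shuffled_control_loci(pauses, ann, seed)
            for pos in ctrl["position"]:
                tri = seq[pos - 1:pos + 2]
                counts[tri] = counts.get(tri, 0) + 1
                total += 1
        observed = pd.Series(counts) / total
        tv = 0.5 * (background.subtract(observed, fill_value=0.0)
                    .abs().sum())
        # expected sampling TV for 64 categories at n=5000 is ~0.045
        assert tv < 0.07


class TestAssembleFeatures:
    def test_center_trinucleotide_extraction(self, world):
        genome, gene, ann = world
        pos = 1000
        expected = genome["chr1"][pos - 1:pos + 2]
        table = assemble_features(
            loci_frame([("chr1", pos, "+", "g")], label="real"),
            genome, ann)
        assert table.loc[0, "trinucleotide"] == expected
        assert table.loc[0, "base_+0"] == expected[1]

    def test_minus_strand_is_reverse_complemented(self, world):
        genome, _, _ = world
        gene = Gene("m", "chr1", 500, 3500, "-")
        ann = GeneAnnotationSet([gene], CHROMS)
        pos = 1200
        table = assemble_features(
            loci_frame([("chr1", pos, "-", "m")], label="real"),
            genome, ann)
        expected = revcomp(genome["chr1"][pos - 1:pos + 2])
        assert table.loc[0, "trinucleotide"] == expected

    def test_mirrored_genome_leaves_sequence_features_unchanged(self,
                                                                world):
        genome, gene, ann = world
        pos = 1500
        fwd = assemble_features(
            loci_frame([("chr1", pos, "+", "g")], label="real"),
            genome, ann)
        # mirror: reverse-complement the chromosome and flip the strand
        L = len(genome["chr1"])
        mirror_genome = {"chr1": revcomp(genome["chr1"])}
        mpos = L - 1 - pos
        mgene = Gene("g", "chr1", L - gene.end, L - gene.start, "-")
        mann = GeneAnnotationSet([mgene], CHROMS)
        rev = assemble_features(
            loci_frame([("chr1", mpos, "-", "g")], label="real"),
            mirror_genome, mann)
        seq_cols = [c for c in fwd.columns if c.startswith("base_")]
        assert fwd.loc[0, seq_cols].tolist() == rev.loc[0, seq_cols].tolist()
        assert fwd.loc[0, "trinucleotide"] == rev.loc[0, "trinucleotide"]
        assert fwd.loc[0, "melting_tm"] == pytest.approx(
            rev.loc[0, "melting_tm"])

    def test_constant_track_window_mean(self, world):
        genome, _, ann = world
        track = OccupancyTrack(CHROMS)
        track.get("chr1", "+")[:] = 5.0
        spec = FeatureSpec("mnase", track=track, window=25)
        table = assemble_features(
            loci_frame([("chr1", 900, "+", "g")], label="real"),
            genome, ann, track_specs=[spec])
        assert table.loc[0, "mnase"] == pytest.approx(5.0)

    def test_uniform_shape_table_lookup(self, world):
        genome, _, ann = world
        pentamers = ["".join(p) for p in
                     __import__("itertools").product("ACGT", repeat=5)]
        shape = pd.DataFrame({"twist": 32.1}, index=pd.Index(
            pentamers, name="pentamer"))
        table = assemble_features(
            loci_frame([("chr1", 777, "+", "g")], label="real"),
            genome, ann, shape_table=shape)
        assert table.loc[0, "shape_twist"] == pytest.approx(32.1)

    def test_chromosome_edge_locus_flagged_missing(self):
        genome = {"chr1": "ACGT" * 1000}
        gene = Gene("e", "chr1", 0, 700, "+")
        ann = GeneAnnotationSet([gene], CHROMS)
        table = assemble_features(
            loci_frame([("chr1", 4, "+", "e")], label="real"), genome, ann)
        assert bool(table.loc[0, "edge_flag"])
        assert np.isnan(table.loc[0, "melting_tm"])

    def test_positional_features(self, world):
        genome, gene, ann = world
        dyads = {"chr1": np.array([900, 2000])}
        table = assemble_features(
            loci_frame([("chr1", 1000, "+", "g")], label="real"),
            genome, ann, nucleosome_dyads=dyads)
        assert table.loc[0, "relative_position"] == pytest.approx(
            (1000 - 500) / 3000)
        assert table.loc[0, "dist_tss"] == 500
        assert table.loc[0, "dist_polya"] == 3499 - 1000
        assert table.loc[0, "dist_dyad"] == 100


class TestDistributionTests:
    def _table(self, shift=0.0, n=500, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for label, delta in (("real", shift), ("control", 0.0)):
            for _ in range(n):
                rows.append({
                    "label": label, "gene_id": "g",
                    "feat_a": rng.normal(delta, 1.0),
                    "feat_b": rng.normal(0.0, 1.0),
                    "feat_const": 1.0,
                    "trinucleotide": "TAT",
                })
        return pd.DataFrame(rows)

    def test_null_features_rarely_significant(self):
        clean = 0
        for seed in range(20):
            res = feature_distribution_tests(self._table(0.0, seed=seed))
            tested = res[res["status"] == "tested"]
            clean += (tested["p_bonferroni"] >= 0.05).all()
        # two features at alpha 0.05: expect ~90% clean seeds
        assert clean >= 15

    def test_planted_two_sigma_shift_detected(self):
        res = feature_distribution_tests(self._table(2.0, seed=2))
        row = res.set_index("feature").loc["feat_a"]
        assert row["p_bonferroni"] < 0.001

    def test_bonferroni_is_p_times_m_capped(self):
        res = feature_distribution_tests(self._table(0.5, seed=3))
        tested = res[res["status"] == "tested"]
        m = len(tested)
        assert np.allclose(tested["p_bonferroni"],
                           np.minimum(tested["p"] * m, 1.0))

    def test_categorical_and_constant_features_skipped(self):
        res = feature_distribution_tests(self._table(0.0, seed=4))
        status = res.set_index("feature")["status"]
        assert status["trinucleotide"] == "categorical"
        assert status["feat_const"] == "zero-variance"


class TestFlankFasta:
    def test_export_roundtrip(self, world, tmp_path):
        genome, gene, ann = world
        loci = loci_frame([("chr1", 1000, "+", "g"),
                           ("chr1", 2000, "+", "g")])
        path = tmp_path / "flanks.fa"
        write_flank_fasta(loci, genome, path)
        from Bio import SeqIO
        records = list(SeqIO.parse(str(path), "fasta"))
        assert len(records) == 2
        assert str(records[0].seq) == genome["chr1"][990:1011]


def test_labeled_loci_balanced(world):
    genome, gene, ann = world
    rng = np.random.default_rng(71)
    offsets = rng.choice(gene.length, size=20, replace=False)
    pauses = loci_frame([(gene.chrom, gene.start + int(o), gene.strand,
                          gene.gene_id) for o in offsets])
    table = labeled_loci(pauses, ann, seed=1)
    assert (table["label"] == "real").sum() == 20
    assert (table["label"] == "control").sum() == 20
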