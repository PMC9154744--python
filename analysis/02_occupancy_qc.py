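"""Occupancy-level QC on the simulated wild type: mispriming removal on
a simulated read set, per-gene RPKM replicate correlation, replicate
merging, and the count table a differential-expression tool would
consume (sense plus antisense units)."""

import json
from pathlib import Path

from netseq.annotation import GeneAnnotationSet
from netseq.antisense import build_antisense_annotation
from netseq.genome import read_fasta
from netseq.occupancy import (OccupancyTrack, build_count_table,
                              filter_mispriming, gene_rpkm,
                              merge_replicates, replicate_correlation)
from netseq.simulate import SimulationConfig, simulate_misprimed_reads

DATA = Path("scratch/pipeline_data")
RESULTS = Path("results")


def load_track(prefix, chrom_lengths):
    return OccupancyTrack.read_bedgraph(prefix, chrom_lengths)


def main() -> None:
    genome = read_fasta(DATA / "genome.fa")
    ann = GeneAnnotationSet.read_gff3(DATA / "annotation.gff3")
    with open(DATA / "config.json") as fh:
        seed = json.load(fh)["seed"]

    reads = simulate_misprimed_reads(genome, ann, 0.2, seed,
                                     n_reads=20_000)
    retained, removed = filter_mispriming(reads, genome)
    print(f"mispriming filter: removed {removed}/{len(reads)} reads "
          f"({removed / len(reads):.1%}; 20% planted plus chance "
          f"collisions)")

    rep1 = load_track(DATA / "wt.rep1", ann.chrom_lengths)
    rep2 = load_track(DATA / "wt.rep2", ann.chrom_lengths)
    rpkm1, rpkm2 = gene_rpkm(rep1, ann), gene_rpkm(rep2, ann)
    r2 = replicate_correlation(rpkm1, rpkm2, threshold=0.75)
    print(f"replicate RPKM correlation R^2 = {r2:.3f}")

    merged = merge_replicates(rep1, rep2)
    merged.write_bedgraph(DATA / "wt.merged")

    anti_ann, removed_units = build_antisense_annotation(ann)
    combined = GeneAnnotationSet(list(ann) + list(anti_ann),
                                 ann.chrom_lengths)
    table = build_count_table({"wt_rep1": rep1, "wt_rep2": rep2}, combined)
    table.to_csv(RESULTS / "02_count_table.tsv", sep="\t")
    print(f"count table: {len(table)} units "
          f"({len(anti_ann)} antisense; {len(removed_units)} dropped "
          f"for same-strand overlap)")

    with open(RESULTS / "02_occupancy_qc.json", "w") as fh:
        json.dump({"misprimed_removed": removed,
                   "misprime_rate": removed / len(reads),
                   "replicate_r2": r2,
                   "merged_library": merged.library_size}, fh, indent=2)


if __name__ == "__main__":
    main()
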