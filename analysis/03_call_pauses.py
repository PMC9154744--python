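"""Call single-nucleotide pauses per replicate in every simulated
strain: expression filter (> 2 reads/bp in both replicates), local
negative-binomial background over 200 nt, 3 sd threshold, >= 2 reads."""

import json
from pathlib import Path

from netseq.annotation import GeneAnnotationSet
from netseq.occupancy import OccupancyTrack
from netseq.pause_calling import (call_pauses, select_well_expressed,
                                  write_bed)
from netseq.pause_metrics import considered_length

DATA = Path("scratch/pipeline_data")
RESULTS = Path("results")
STRAINS = ("wt", "mutA", "mutB")


def main() -> None:
    summary = {}
    ann = GeneAnnotationSet.read_gff3(DATA / "annotation.gff3")
    for strain in STRAINS:
        rep1 = OccupancyTrack.read_bedgraph(DATA / f"{strain}.rep1",
                                            ann.chrom_lengths)
        rep2 = OccupancyTrack.read_bedgraph(DATA / f"{strain}.rep2",
                                            ann.chrom_lengths)
        filt = select_well_expressed(rep1, rep2, ann)
        filt.to_csv(DATA / f"{strain}.expression_filter.tsv", sep="\t",
                    index=False)
        calls1 = call_pauses(rep1, ann, filt)
        calls2 = call_pauses(rep2, ann, filt)
        write_bed(calls1, DATA / f"{strain}.rep1.pauses.bed")
        write_bed(calls2, DATA / f"{strain}.rep2.pauses.bed")
        length = considered_length(filt, ann)
        summary[strain] = {
            "well_expressed_genes": int(filt["passes"].sum()),
            "considered_length_bp": length,
            "calls_rep1": len(calls1), "calls_rep2": len(calls2),
            "initial_density_per_kb": 1000 * len(calls1) / length,
        }
        print(f"{strain}: {len(calls1)}/{len(calls2)} calls over "
              f"{length / 1000:.0f} kb "
              f"({1000 * len(calls1) / length:.1f} per kb, i.e. one "
              f"call every {length / max(len(calls1), 1):.0f} bp)")
    with open(RESULTS / "03_pause_calls.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
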