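"""Summarize reproducible pause sets: density per strain, positional
distribution against a scrambled control, and the tri-state
shared-pause matrix across the simulated strains."""

import json
from pathlib import Path

import pandas as pd

from netseq.annotation import GeneAnnotationSet
from netseq.pause_metrics import (considered_length, pause_density,
                                  positional_distribution,
                                  scramble_pauses, shared_pause_matrix)

DATA = Path("scratch/pipeline_data")
RESULTS = Path("results")
STRAINS = ("wt", "mutA", "mutB")


def main() -> None:
    summary = {}
    pause_sets, filters = {}, {}
    ann = GeneAnnotationSet.read_gff3(DATA / "annotation.gff3")
    for strain in STRAINS:
        pauses = pd.read_csv(DATA / f"{strain}.reproducible_pauses.tsv",
                             sep="\t")
        filt = pd.read_csv(DATA / f"{strain}.expression_filter.tsv",
                           sep="\t")
        pause_sets[strain], filters[strain] = pauses, filt
        length = considered_length(filt, ann)
        density = pause_density(pauses, length)
        dist = positional_distribution(pauses, ann)
        scrambled = scramble_pauses(pauses, ann, seed=1)
        null_dist = positional_distribution(scrambled, ann)
        summary[strain] = {
            "density_per_kb": density,
            "positional": dist.set_index("bin")["fraction"].round(4)
                              .to_dict(),
            "scrambled": null_dist.set_index("bin")["fraction"].round(4)
                                  .to_dict(),
        }
        print(f"{strain}: {density:.2f} reproducible pauses/kb; "
              f"5'/mid/3' = "
              + "/".join(f"{v:.2f}" for v in dist["fraction"]))

    # all strains share one genome, so loci are directly comparable
    mat = shared_pause_matrix(pause_sets, filters, min_strains=2)
    mat.to_csv(RESULTS / "05_shared_pause_matrix.tsv", sep="\t")
    print(f"shared-pause matrix: {mat.shape[0]} loci found in >= 2 "
          f"strains")
    summary["shared_matrix_loci"] = int(mat.shape[0])
    with open(RESULTS / "05_pause_metrics.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
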