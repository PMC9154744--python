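"""Generate the synthetic study: one toy genome with annotated
transcription units shared by all strains, and two replicate
NET-seq-like occupancy tracks per strain (wild type plus two
mutant-like strains that differ only in their occupancy seed, hence in
which pause sites are planted).

Bulky per-position tracks go under scratch/pipeline_data/ (inputs for
the later stages); small summaries land in results/.
"""

import json
from dataclasses import replace
from pathlib import Path

from netseq.genome import write_fasta
from netseq.simulate import (SimulationConfig, generate_toy_genome,
                             simulate_occupancy)

DATA = Path("scratch/pipeline_data")
RESULTS = Path("results")
GENOME_SEED = 1
STRAIN_SEEDS = {"wt": 1, "mutA": 2, "mutB": 3}


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    base = SimulationConfig(seed=GENOME_SEED)
    genome, ann = generate_toy_genome(base)
    write_fasta(genome, DATA / "genome.fa")
    ann.write_gff3(DATA / "annotation.gff3")
    base.to_json(DATA / "config.json")

    summary = {}
    for strain, seed in STRAIN_SEEDS.items():
        cfg = replace(base, seed=seed)
        rep1, rep2, truth = simulate_occupancy(ann, cfg)
        rep1.write_bedgraph(DATA / f"{strain}.rep1")
        rep2.write_bedgraph(DATA / f"{strain}.rep2")
        truth.to_csv(DATA / f"{strain}.truth.tsv", sep="\t", index=False)
        summary[strain] = {
            "seed": seed, "genes": len(ann),
            "planted_pauses": int(len(truth)),
            "reproducible_pauses": int(truth["reproducible"].sum()),
            "library_rep1": rep1.library_size,
            "library_rep2": rep2.library_size,
        }
        print(f"{strain}: {len(truth)} planted pauses "
              f"({truth['reproducible'].mean():.0%} reproducible), "
              f"libraries {rep1.library_size:.0f}/"
              f"{rep2.library_size:.0f}")
    with open(RESULTS / "01_simulation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
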