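"""Replicate reproducibility by IDR: match per-replicate calls at exact
coordinates, fit the copula mixture from the standard initialization
(mu=3, sigma=1, rho=0.9, p=0.5), and keep pairs with global IDR < 1%."""

import json
from dataclasses import asdict
from pathlib import Path

from netseq.idr import assign_idr, match_pauses, reproducible_pauses
from netseq.pause_calling import read_bed

DATA = Path("scratch/pipeline_data")
RESULTS = Path("results")
STRAINS = ("wt", "mutA", "mutB")


def main() -> None:
    summary = {}
    for strain in STRAINS:
        calls1 = read_bed(DATA / f"{strain}.rep1.pauses.bed")
        calls2 = read_bed(DATA / f"{strain}.rep2.pauses.bed")
        pairs = match_pauses(calls1, calls2)
        pairs, params = assign_idr(pairs)
        kept = reproducible_pauses(pairs, threshold=0.01)
        kept.to_csv(DATA / f"{strain}.reproducible_pauses.tsv", sep="\t",
                    index=False)
        initial = 0.5 * (len(calls1) + len(calls2))
        summary[strain] = {
            "matched_pairs": len(pairs),
            "reproducible": len(kept),
            "fraction_of_initial_calls": len(kept) / initial,
            "fitted_params": asdict(params),
        }
        print(f"{strain}: {len(kept)} reproducible pauses "
              f"({len(kept) / initial:.0%} of initial calls; the assay "
              f"expectation is roughly one-third)")
    with open(RESULTS / "04_idr_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
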