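"""Genome sequences as plain ``{chrom: str}`` dictionaries with FASTA I/O."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GenomeSequence = dict  # chrom -> uppercase DNA string


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> GenomeSequence:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def chrom_lengths(genome: GenomeSequence) -> dict[str, int]:
    return {chrom: len(seq) for chrom, seq in genome.items()}
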