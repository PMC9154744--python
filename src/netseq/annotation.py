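"""Transcription-unit annotations.

Internally every interval is 0-based half-open on the forward genomic
strand; GFF3 (1-based inclusive) is converted on read/write.  A
transcription unit carries its strand, so the transcription start site
(TSS) and poly(A) site are derived properties: for a ``+`` unit the TSS
is ``start`` and the poly(A) site is ``end - 1``; for a ``-`` unit the
reverse.  A unit may carry at most one intron, stored as a half-open
genomic interval, from which the 5' and 3' splice-site anchors are
derived strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import pandas as pd

STRANDS = ("+", "-")


def opposite_strand(strand: str) -> str:
    return "-" if strand == "+" else "+"


@dataclass(frozen=True)
class Gene:
    """A transcription unit (sense gene or derived antisense unit)."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    intron: Optional[tuple[int, int]] = None  # half-open genomic interval

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.end > self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.intron is not None:
            i0, i1 = self.intron
            if not (self.start < i0 < i1 < self.end):
                raise ValueError(f"{self.gene_id}: intron outside gene body")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def polya(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def five_ss(self) -> Optional[int]:
        """First intronic base in transcript orientation (splice donor)."""
        if self.intron is None:
            return None
        return self.intron[0] if self.strand == "+" else self.intron[1] - 1

    @property
    def three_ss(self) -> Optional[int]:
        """Last intronic base in transcript orientation (splice acceptor)."""
        if self.intron is None:
            return None
        return self.intron[1] - 1 if self.strand == "+" else self.intron[0]

    def relative_position(self, genomic_pos: int) -> float:
        """Position relative to the TSS as a fraction of gene length in [0, 1)."""
        if not self.start <= genomic_pos < self.end:
            raise ValueError(
                f"position {genomic_pos} outside {self.gene_id} "
                f"[{self.start},{self.end})"
            )
        if self.strand == "+":
            offset = genomic_pos - self.start
        else:
            offset = self.end - 1 - genomic_pos
        return offset / self.length

    def antisense_unit(self) -> "Gene":
        """Mirror unit on the opposite strand with identical coordinates."""
        return replace(self, gene_id=f"anti{self.gene_id}",
                       strand=opposite_strand(self.strand), intron=None)


class GeneAnnotationSet:
    """Ordered collection of transcription units plus chromosome sizes."""

    def __init__(self, genes: Iterable[Gene], chrom_lengths: dict[str, int]):
        self.genes: list[Gene] = list(genes)
        self.chrom_lengths = dict(chrom_lengths)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene identifiers in annotation")
        self._by_id = {g.gene_id: g for g in self.genes}
        for g in self.genes:
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > self.chrom_lengths[g.chrom]:
                raise ValueError(f"{g.gene_id} extends past end of {g.chrom}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def introns(self) -> list[Gene]:
        return [g for g in self.genes if g.intron is not None]

    def total_length(self) -> int:
        return sum(g.length for g in self.genes)

    def nonoverlapping(self) -> "GeneAnnotationSet":
        """Subset of units that overlap no other unit on either strand."""
        keep = []
        for g in self.genes:
            clash = any(
                h is not g and h.chrom == g.chrom
                and h.start < g.end and g.start < h.end
                for h in self.genes
            )
            if not clash:
                keep.append(g)
        return GeneAnnotationSet(keep, self.chrom_lengths)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append({
                "gene_id": g.gene_id, "chrom": g.chrom, "start": g.start,
                "end": g.end, "strand": g.strand, "length": g.length,
                "tss": g.tss, "polya": g.polya,
                "intron_start": g.intron[0] if g.intron else pd.NA,
                "intron_end": g.intron[1] if g.intron else pd.NA,
            })
        return pd.DataFrame(rows)

    # ---------------------------------------------------------------- GFF3

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in sorted(self.chrom_lengths):
                fh.write(f"##sequence-region {chrom} 1 "
                         f"{self.chrom_lengths[chrom]}\n")
            for g in self.genes:
                fh.write("\t".join([
                    g.chrom, "netseq", "gene", str(g.start + 1), str(g.end),
                    ".", g.strand, ".", f"ID={g.gene_id}",
                ]) + "\n")
                if g.intron is not None:
                    fh.write("\t".join([
                        g.chrom, "netseq", "intron",
                        str(g.intron[0] + 1), str(g.intron[1]),
                        ".", g.strand, ".",
                        f"ID={g.gene_id}.i1;Parent={g.gene_id}",
                    ]) + "\n")

    @classmethod
    def read_gff3(cls, path) -> "GeneAnnotationSet":
        chrom_lengths: dict[str, int] = {}
        genes: dict[str, dict] = {}
        order: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##sequence-region"):
                    _, chrom, _one, length = line.split()
                    chrom_lengths[chrom] = int(length)
                    continue
                if not line or line.startswith("#"):
                    continue
                chrom, _src, ftype, start, end, _score, strand, _frame, attrs \
                    = line.split("\t")
                attr = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
                if ftype == "gene":
                    gid = attr["ID"]
                    genes[gid] = {"chrom": chrom, "start": int(start) - 1,
                                  "end": int(end), "strand": strand,
                                  "intron": None}
                    order.append(gid)
                elif ftype == "intron":
                    parent = attr["Parent"]
                    genes[parent]["intron"] = (int(start) - 1, int(end))
        built = [Gene(gene_id=gid, **genes[gid]) for gid in order]
        if not chrom_lengths:
            for g in built:
                chrom_lengths[g.chrom] = max(
                    chrom_lengths.get(g.chrom, 0), g.end)
        return cls(built, chrom_lengths)
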