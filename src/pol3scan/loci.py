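"""Candidate ncRNA loci and their BED6 representation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .seqs import revcomp


@dataclass(frozen=True)
class NcRNALocus:
    """A candidate ncRNA gene: 0-based half-open genomic interval + strand.

    ``rna_class`` is the biological identity of the candidate (RPR for the
    RNase P RNA, MRP for the RNase MRP RNA, or other); it does not influence
    promoter classification, only which signature set applies.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rna_class: str = "RPR"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"locus {self.locus_id}: invalid interval")
        if self.strand not in ("+", "-"):
            raise ValueError(f"locus {self.locus_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sense_sequence(self, genome: Mapping[str, str]) -> str:
        seq = genome[self.chrom][self.start : self.end]
        return revcomp(seq) if self.strand == "-" else seq


def read_bed6(path) -> list[NcRNALocus]:
    """BED6 (0-based half-open); the name column carries the locus id,
    optionally suffixed ``|<rna_class>``."""
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            locus_id, _, rna_class = name.partition("|")
            loci.append(
                NcRNALocus(
                    locus_id=locus_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    rna_class=rna_class or "RPR",
                )
            )
    return loci


def write_bed6(loci: Iterable[NcRNALocus], path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for locus in loci:
            name = f"{locus.locus_id}|{locus.rna_class}"
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t{name}\t0\t{locus.strand}\n"
            )
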