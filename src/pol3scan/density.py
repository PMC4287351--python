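"""Read-density comparison between the ncRNA-containing region and the
preceding intron of the recipient gene.

Density is read count divided by interval length (reads per bp); fold
enrichment is the ratio of two densities.  The module accepts either raw
read intervals (BED6, counted by >=1 bp overlap) or pre-tabulated counts
(TSV with interval_id, count, length), because published comparisons are
often reported directly as counts over interval lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class ReadInterval:
    chrom: str
    start: int
    end: int
    strand: Optional[str] = None


@dataclass(frozen=True)
class DensityRecord:
    interval_id: str
    read_count: int
    length: int
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.interval_id}: interval length must be > 0")
        if self.read_count < 0:
            raise ValueError(f"{self.interval_id}: read count must be >= 0")

    @property
    def density(self) -> float:
        """Reads per bp."""
        return self.read_count / self.length


def read_bed_reads(path) -> list[ReadInterval]:
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            strand = fields[5] if len(fields) >= 6 else None
            reads.append(
                ReadInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return reads


def count_overlaps(
    reads: Sequence[ReadInterval],
    chrom: str,
    start: int,
    end: int,
    strand: Optional[str] = None,
) -> int:
    """Number of reads overlapping [start, end) on ``chrom`` by >=1 bp.

    Strand-agnostic unless ``strand`` is given (then only reads on that
    strand count; unstranded reads never match a stranded query).
    """
    same_chrom = [r for r in reads if r.chrom == chrom]
    if reads and not same_chrom:
        raise KeyError(
            f"no reads on sequence id {chrom!r} (reads cover "
            f"{sorted({r.chrom for r in reads})})"
        )
    tree = IntervalTree()
    for i, r in enumerate(same_chrom):
        if strand is not None and r.strand != strand:
            continue
        tree.addi(r.start, r.end, i)
    return len(tree.overlap(start, end))


def density_from_reads(
    interval_id: str,
    reads: Sequence[ReadInterval],
    chrom: str,
    start: int,
    end: int,
    strand: Optional[str] = None,
) -> DensityRecord:
    return DensityRecord(
        interval_id=interval_id,
        read_count=count_overlaps(reads, chrom, start, end, strand),
        length=end - start,
        chrom=chrom,
        start=start,
        end=end,
    )


def fold_enrichment(a: DensityRecord, b: DensityRecord) -> float:
    """Density ratio a/b (how much denser the ncRNA region is than the
    reference intron)."""
    if b.density <= 0:
        raise ZeroDivisionError(
            f"reference interval {b.interval_id} has zero read density; "
            "fold enrichment is undefined"
        )
    return a.density / b.density


def read_counts_tsv(path) -> list[DensityRecord]:
    """Pre-tabulated counts: TSV with columns interval_id, count, length."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"interval_id", "count", "length"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        DensityRecord(
            interval_id=str(row["interval_id"]),
            read_count=int(row["count"]),
            length=int(row["length"]),
        )
        for row in frame.to_dict("records")
    ]


def density_report(records: Sequence[DensityRecord], reference_id: str) -> pd.DataFrame:
    """Tabulate densities and fold enrichment of every interval over the
    named reference interval."""
    by_id = {r.interval_id: r for r in records}
    if reference_id not in by_id:
        raise KeyError(f"reference interval {reference_id!r} not in records")
    ref = by_id[reference_id]
    return pd.DataFrame(
        [
            {
                "interval_id": r.interval_id,
                "read_count": r.read_count,
                "length": r.length,
                "density": r.density,
                "fold_enrichment_vs_reference": fold_enrichment(r, ref),
            }
            for r in records
        ]
    )
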