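"""Genomic-context resolution: is a candidate locus intergenic, intronic in
a recipient (host) gene, or overlapping an exon?

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted at the parsing boundary.  Multi-transcript genes are resolved
against their longest transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import gffutils

from .loci import NcRNALocus

#: Flanking-gene markers used when an intergenic locus has no neighbor on
#: one side of the sequence.
EDGE_5PRIME = "<genome_edge_5prime>"
EDGE_3PRIME = "<genome_edge_3prime>"


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted by start, 0-based half-open

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: tuple[Transcript, ...]

    def longest_transcript(self) -> Transcript:
        # ties broken by transcript id for determinism
        return max(
            self.transcripts,
            key=lambda t: (t.span[1] - t.span[0], t.transcript_id),
        )


class Annotation:
    """Gene models indexed per sequence, ready for context lookups."""

    def __init__(self, genes: Sequence[Gene], known_chroms: set[str] | None = None):
        self.genes = {g.gene_id: g for g in genes}
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end, g.gene_id))
        self.known_chroms = set(known_chroms or ()) | set(self._by_chrom)

    @classmethod
    def from_gff3(cls, path) -> "Annotation":
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        known = set()
        for directive in db.directives:
            if directive.startswith("sequence-region"):
                known.add(directive.split()[1])
        genes = []
        for gene in db.features_of_type("gene"):
            transcripts = []
            for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
                exons = sorted(
                    (e.start - 1, e.end) for e in db.children(mrna, featuretype="exon")
                )
                if not exons:
                    continue
                transcripts.append(
                    Transcript(
                        transcript_id=mrna.id,
                        gene_id=gene.id,
                        chrom=gene.seqid,
                        strand=gene.strand,
                        exons=tuple(exons),
                    )
                )
            if not transcripts:
                # gene without mRNA children: exons attached directly
                exons = sorted(
                    (e.start - 1, e.end) for e in db.children(gene, featuretype="exon")
                )
                if exons:
                    transcripts.append(
                        Transcript(
                            transcript_id=f"{gene.id}.t1",
                            gene_id=gene.id,
                            chrom=gene.seqid,
                            strand=gene.strand,
                            exons=tuple(exons),
                        )
                    )
            genes.append(
                Gene(
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    start=gene.start - 1,
                    end=gene.end,
                    strand=gene.strand,
                    transcripts=tuple(transcripts),
                )
            )
        return cls(genes, known_chroms=known)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])


@dataclass(frozen=True)
class ContextCall:
    """Placement of one candidate locus relative to the annotation."""

    locus_id: str
    placement: str  # "intronic" | "intergenic" | "overlapping_exon"
    recipient_gene_id: Optional[str] = None
    flanking_gene_ids: Optional[tuple[str, str]] = None
    intron_ordinal: Optional[int] = None  # 1-based, 5'->3' on recipient strand
    last_intron: bool = False
    orientation: str = "not_applicable"  # "same" | "opposite" | "not_applicable"
    containment: str = "full"  # "full" | "partial"

    def __post_init__(self) -> None:
        if self.placement == "intronic":
            if self.recipient_gene_id is None or self.containment != "full":
                raise ValueError(
                    f"{self.locus_id}: intronic calls need a recipient gene and "
                    "full containment"
                )
        if self.placement == "intergenic" and self.flanking_gene_ids is None:
            raise ValueError(f"{self.locus_id}: intergenic calls need flanking genes")


@dataclass(frozen=True)
class CohabitationGroup:
    """Loci sharing one recipient gene (tandem = adjacent copies in the same
    intron in the same orientation, with nothing annotated between them)."""

    gene_id: str
    locus_ids: tuple[str, ...]
    same_intron: bool
    tandem: bool

    def __post_init__(self) -> None:
        if not self.locus_ids:
            raise ValueError("cohabitation group must have at least one member")
        if self.tandem and not self.same_intron:
            raise ValueError("tandem copies must share an intron")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def resolve_context(locus: NcRNALocus, annotation: Annotation) -> ContextCall:
    """Classify the locus as intronic / intergenic / overlapping_exon.

    A locus is intronic iff it lies fully inside one intron of the chosen
    (longest) transcript of one gene and touches no exon; any >=1 bp exon
    overlap makes it overlapping_exon (containment ``full`` when a single
    exon contains the whole locus).  Otherwise it is intergenic, reported
    with both flanking genes (edge markers at sequence ends).
    """
    if locus.chrom not in annotation.known_chroms:
        raise KeyError(
            f"locus {locus.locus_id}: sequence id {locus.chrom!r} absent from "
            "the annotation"
        )
    interval = (locus.start, locus.end)
    genes = annotation.genes_on(locus.chrom)

    exon_hits: list[tuple[Gene, tuple[int, int]]] = []
    intron_hit: Optional[tuple[Gene, Transcript, int]] = None
    for gene in genes:
        if _overlap(interval, (gene.start, gene.end)) == 0:
            continue
        tx = gene.longest_transcript()
        for exon in tx.exons:
            if _overlap(interval, exon) > 0:
                exon_hits.append((gene, exon))
        if intron_hit is None:
            for i, intron in enumerate(tx.introns):
                if intron[0] <= locus.start and locus.end <= intron[1]:
                    intron_hit = (gene, tx, i)
                    break

    if exon_hits:
        gene, _ = exon_hits[0]
        full = any(e[0] <= locus.start and locus.end <= e[1] for _, e in exon_hits)
        return ContextCall(
            locus_id=locus.locus_id,
            placement="overlapping_exon",
            recipient_gene_id=gene.gene_id,
            orientation="same" if locus.strand == gene.strand else "opposite",
            containment="full" if full else "partial",
        )

    if intron_hit is not None:
        gene, tx, genomic_index = intron_hit
        n_introns = len(tx.introns)
        ordinal = (
            genomic_index + 1 if gene.strand == "+" else n_introns - genomic_index
        )
        return ContextCall(
            locus_id=locus.locus_id,
            placement="intronic",
            recipient_gene_id=gene.gene_id,
            intron_ordinal=ordinal,
            last_intron=(ordinal == n_introns),
            orientation="same" if locus.strand == gene.strand else "opposite",
            containment="full",
        )

    # Residual gene overlap without exon overlap or full intron containment
    # (possible only with overlapping gene models): report as a partial
    # exon-structure overlap rather than inventing a class.
    for gene in genes:
        if _overlap(interval, (gene.start, gene.end)) > 0:
            return ContextCall(
                locus_id=locus.locus_id,
                placement="overlapping_exon",
                recipient_gene_id=gene.gene_id,
                orientation="same" if locus.strand == gene.strand else "opposite",
                containment="partial",
            )

    left = None
    for gene in genes:
        if gene.end <= locus.start and (left is None or gene.end > left.end):
            left = gene
    right = None
    for gene in genes:
        if gene.start >= locus.end and (right is None or gene.start < right.start):
            right = gene
    return ContextCall(
        locus_id=locus.locus_id,
        placement="intergenic",
        flanking_gene_ids=(
            left.gene_id if left else EDGE_5PRIME,
            right.gene_id if right else EDGE_3PRIME,
        ),
        orientation="not_applicable",
        containment="full",
    )


def find_cohabitants(
    loci: Sequence[NcRNALocus],
    annotation: Annotation,
    contexts: Sequence[ContextCall] | None = None,
) -> list[CohabitationGroup]:
    """Group intronic loci by recipient gene; flag same-intron and tandem
    (same intron, same orientation, members adjacent with no other candidate
    locus between them) arrangements."""
    if contexts is None:
        contexts = [resolve_context(l, annotation) for l in loci]
    by_id = {l.locus_id: l for l in loci}
    groups: dict[str, list[ContextCall]] = {}
    for call in contexts:
        if call.placement == "intronic":
            groups.setdefault(call.recipient_gene_id, []).append(call)
    out = []
    for gene_id in sorted(groups):
        calls = sorted(groups[gene_id], key=lambda c: by_id[c.locus_id].start)
        members = [by_id[c.locus_id] for c in calls]
        same_intron = len({c.intron_ordinal for c in calls}) == 1
        same_orientation = len({m.strand for m in members}) == 1
        # within one intron nothing is annotated between members, so
        # adjacency only fails if a foreign candidate locus intervenes
        adjacent = True
        if same_intron and len(members) > 1:
            lo = min(m.start for m in members)
            hi = max(m.end for m in members)
            member_ids = {m.locus_id for m in members}
            for other in loci:
                if (
                    other.locus_id not in member_ids
                    and other.chrom == members[0].chrom
                    and other.start < hi
                    and other.end > lo
                ):
                    adjacent = False
        tandem = bool(
            len(members) > 1 and same_intron and same_orientation and adjacent
        )
        out.append(
            CohabitationGroup(
                gene_id=gene_id,
                locus_ids=tuple(m.locus_id for m in members),
                same_intron=same_intron,
                tandem=tandem,
            )
        )
    return out
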