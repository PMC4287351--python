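import pytest

from oracles import oracle_placement
from pol3scan.context import (
    Annotation,
    EDGE_3PRIME,
    Gene,
    Transcript,
    find_cohabitants,
    resolve_context,
)
from pol3scan.loci import NcRNALocus


def make_gene(gene_id, chrom, exons, strand):
    exons = tuple(tuple(e) for e in sorted(exons))
    tx = Transcript(f"{gene_id}.t1", gene_id, chrom, strand, exons)
    return Gene(gene_id, chrom, exons[0][0], exons[-1][1], strand, (tx,))


@pytest.fixture
def two_gene_annotation():
    # geneA: exons 100-200, 800-900, 1500-1600 (introns 200-800, 900-1500)
    # geneB: exons 3000-3100, 3500-3600 on the minus strand
    g1 = make_gene("geneA", "chr1", [(100, 200), (800, 900), (1500, 1600)], "+")
    g2 = make_gene("geneB", "chr1", [(3000, 3100), (3500, 3600)], "-")
    return Annotation([g1, g2])


class TestResolveContext:
    def test_locus_in_last_intron_same_strand(self, two_gene_annotation):
        locus = NcRNALocus("l1", "chr1", 1000, 1300, "+")
        call = resolve_context(locus, two_gene_annotation)
        assert call.placement == "intronic"
        assert call.recipient_gene_id == "geneA"
        assert call.intron_ordinal == 2 and call.last_intron
        assert call.orientation == "same" and call.containment == "full"

    def test_opposite_strand_locus_reports_opposite_orientation(
        self, two_gene_annotation
    ):
        locus = NcRNALocus("l2", "chr1", 300, 600, "-")
        call = resolve_context(locus, two_gene_annotation)
        assert call.placement == "intronic" and call.orientation == "opposite"
        assert call.intron_ordinal == 1 and not call.last_intron

    def test_intergenic_locus_reports_both_neighbors(self, two_gene_annotation):
        call = resolve_context(
            NcRNALocus("l3", "chr1", 2000, 2300, "+"), two_gene_annotation
        )
        assert call.placement == "intergenic"
        assert call.flanking_gene_ids == ("geneA", "geneB")
        assert call.orientation == "not_applicable"

    def test_locus_after_last_gene_gets_edge_marker(self, two_gene_annotation):
        call = resolve_context(
            NcRNALocus("l4", "chr1", 5000, 5200, "+"), two_gene_annotation
        )
        assert call.flanking_gene_ids == ("geneB", EDGE_3PRIME)

    def test_exon_straddling_locus_is_partial_overlap(self, two_gene_annotation):
        call = resolve_context(
            NcRNALocus("l5", "chr1", 150, 400, "+"), two_gene_annotation
        )
        assert call.placement == "overlapping_exon"
        assert call.containment == "partial"

    def test_locus_fully_inside_exon_is_full_overlap(self, two_gene_annotation):
        call = resolve_context(
            NcRNALocus("l6", "chr1", 3010, 3090, "+"), two_gene_annotation
        )
        assert call.placement == "overlapping_exon" and call.containment == "full"

    def test_unknown_sequence_id_raises(self, two_gene_annotation):
        with pytest.raises(KeyError):
            resolve_context(NcRNALocus("l7", "chrX", 0, 100, "+"), two_gene_annotation)

    def test_intron_ordinal_reverses_with_recipient_strand(self):
        exons = [(100, 200), (500, 600), (900, 1000), (1300, 1400)]
        locus = NcRNALocus("l8", "chr1", 650, 800, "+")  # genomic intron 2 of 3
        fwd = resolve_context(locus, Annotation([make_gene("g", "chr1", exons, "+")]))
        rev = resolve_context(locus, Annotation([make_gene("g", "chr1", exons, "-")]))
        n_introns = len(exons) - 1
        assert fwd.intron_ordinal == 2
        assert rev.intron_ordinal == n_introns - fwd.intron_ordinal + 1

    def test_matches_per_base_oracle_on_random_annotations(self, rng):
        for trial in range(30):
            genes, cursor = [], 0
            for gi in range(int(rng.integers(1, 6))):
                cursor += int(rng.integers(50, 200))
                exons = []
                for _ in range(int(rng.integers(2, 5))):
                    start = cursor
                    cursor += int(rng.integers(20, 80))
                    exons.append((start, cursor))
                    cursor += int(rng.integers(30, 150))
                cursor = exons[-1][1]
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(make_gene(f"g{trial}_{gi}", "chr1", exons, strand))
            ann = Annotation(genes)
            transcripts = [
                (g.longest_transcript().exons, g.strand) for g in genes
            ]
            for _ in range(10):
                start = int(rng.integers(0, cursor + 100))
                end = start + int(rng.integers(10, 120))
                locus = NcRNALocus("q", "chr1", start, end, "+")
                call = resolve_context(locus, ann)
                assert call.placement == oracle_placement(start, end, transcripts)


class TestCohabitation:
    def test_tandem_copies_in_same_intron(self, two_gene_annotation):
        loci = [
            NcRNALocus("a", "chr1", 250, 350, "+"),
            NcRNALocus("b", "chr1", 400, 500, "+"),
        ]
        (group,) = find_cohabitants(loci, two_gene_annotation)
        assert group.gene_id == "geneA"
        assert group.locus_ids == ("a", "b")
        assert group.same_intron and group.tandem

    def test_copies_in_different_introns_are_not_tandem(self, two_gene_annotation):
        loci = [
            NcRNALocus("a", "chr1", 250, 350, "+"),
            NcRNALocus("b", "chr1", 1000, 1100, "+"),
        ]
        (group,) = find_cohabitants(loci, two_gene_annotation)
        assert group.same_intron is False and group.tandem is False

    def test_opposite_orientation_copies_are_not_tandem(self, two_gene_annotation):
        loci = [
            NcRNALocus("a", "chr1", 250, 350, "+"),
            NcRNALocus("b", "chr1", 400, 500, "-"),
        ]
        (group,) = find_cohabitants(loci, two_gene_annotation)
        assert group.same_intron is True and group.tandem is False

    def test_loci_in_different_genes_form_singletons(self, two_gene_annotation):
        loci = [
            NcRNALocus("a", "chr1", 250, 350, "+"),
            NcRNALocus("b", "chr1", 3200, 3300, "-"),
        ]
        groups = find_cohabitants(loci, two_gene_annotation)
        assert sorted(g.gene_id for g in groups) == ["geneA", "geneB"]
        assert all(len(g.locus_ids) == 1 and not g.tandem for g in groups)

    def test_synthetic_embedded_loci_resolve_to_truth(self, clean_species):
        from pol3scan.context import Annotation as Ann

        genes = [
            make_gene(g.gene_id, clean_species.chrom, g.exons, g.strand)
            for g in clean_species.genes
        ]
        ann = Annotation(genes)
        by_id = {l.locus_id: l for l in clean_species.loci}
        for t in clean_species.truth:
            if t.planted_class != "embedded_polII":
                continue
            call = resolve_context(by_id[t.locus_id], ann)
            assert call.placement == "intronic"
            assert call.recipient_gene_id == t.recipient_gene_id
            assert call.intron_ordinal == t.intron_ordinal
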