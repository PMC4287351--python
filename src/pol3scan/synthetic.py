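"""Seeded synthetic species generator.

Emulates the two gene architectures the classifier must separate:

* *embedded* ncRNA loci — signal-free bodies planted wholly inside an
  intron of a pol II host gene, in the host's orientation;
* *independent* ncRNA loci — intergenic bodies with a planted PSE
  (start 45-80 nt upstream by default), a TATA box whose 3' end sits
  21-27 nt upstream of the locus, and a 3' poly-T run of 4-5 nt within
  the proximal terminator window;

plus U6/7SK-like training promoters that carry the same species PSE/TATA
consensus.  ``promoter_noise`` is the per-site substitution rate applied to
every planted consensus copy (training promoters and genomic signals
alike), modelling per-copy divergence from one species-wide consensus.

Background sequence is i.i.d. at the configured GC content.  Everything is
driven by one ``numpy`` generator seeded from the config, so a fixed
config+seed reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .defaults import (
    DEFAULT_PROXIMAL_WINDOW,
    DEFAULT_PSE_CONSENSUS,
    DEFAULT_PSE_SEARCH_WINDOW,
    DEFAULT_SIGNATURES,
    DEFAULT_TATA_CONSENSUS,
    DEFAULT_TATA_OFFSET_WINDOW,
)
from .loci import NcRNALocus, write_bed6
from .seqs import mutate, random_dna, realize_iupac, revcomp


class SizingError(ValueError):
    """A configured feature cannot physically fit (names the gene/feature)."""


class PlacementError(RuntimeError):
    """Non-overlapping placement failed after bounded retries."""


@dataclass(frozen=True)
class SyntheticSpeciesConfig:
    species_id: str = "synthspecies"
    genome_length: int = 60_000
    gc_content: float = 0.40
    n_host_genes: int = 6
    exons_per_gene: int = 4
    exon_length: int = 150
    intron_length: int = 700
    n_embedded_loci: int = 3
    n_independent_loci: int = 2
    locus_length: int = 300
    tata_offset_range: tuple[int, int] = DEFAULT_TATA_OFFSET_WINDOW
    polyT_run_range: tuple[int, int] = (4, 5)
    pse_search_window: tuple[int, int] = DEFAULT_PSE_SEARCH_WINDOW
    proximal_window: int = DEFAULT_PROXIMAL_WINDOW
    promoter_noise: float = 0.0
    n_training_promoters: int = 20
    pse_consensus: str = DEFAULT_PSE_CONSENSUS
    tata_consensus: str = DEFAULT_TATA_CONSENSUS
    signature_motifs: dict = field(default_factory=lambda: dict(DEFAULT_SIGNATURES))
    max_placement_retries: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "genome_length": self.genome_length,
            "n_host_genes": self.n_host_genes,
            "n_embedded_loci": self.n_embedded_loci,
            "n_independent_loci": self.n_independent_loci,
            "n_training_promoters": self.n_training_promoters,
            "locus_length": self.locus_length,
            "exon_length": self.exon_length,
            "intron_length": self.intron_length,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0 (got {value})")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.promoter_noise < 1.0:
            raise ValueError("promoter_noise must be in [0, 1)")
        if self.exons_per_gene < 2:
            raise ValueError("exons_per_gene must be >= 2 (genes need introns)")
        for name in ("tata_offset_range", "polyT_run_range", "pse_search_window"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be a nonempty nonnegative range")
        if self.polyT_run_range[1] > self.proximal_window:
            raise ValueError("polyT runs must fit inside the proximal window")
        need = (
            self.tata_offset_range[1]
            + len(self.tata_consensus)
            + len(self.pse_consensus)
        )
        if self.pse_search_window[1] < need:
            raise ValueError(
                "pse_search_window too narrow: PSE must fit upstream of the "
                f"TATA region (need upstream distance up to {need})"
            )

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpeciesConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        for key in ("tata_offset_range", "polyT_run_range", "pse_search_window"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted locus.

    Embedded records carry no planted signal positions; independent records
    carry all three (PSE upstream distance, TATA gap, terminator start).
    """

    locus_id: str
    planted_class: str  # "embedded_polII" | "independent_polIII"
    strand: str
    pse_offset: Optional[int] = None  # locus start - PSE start, sense strand
    tata_offset: Optional[int] = None  # gap between TATA 3' end and locus
    terminator_start: Optional[int] = None  # bp downstream of 3' end
    terminator_length: Optional[int] = None
    pse_seq: Optional[str] = None  # planted (possibly mutated) copies
    tata_seq: Optional[str] = None
    recipient_gene_id: Optional[str] = None
    intron_ordinal: Optional[int] = None

    def __post_init__(self) -> None:
        planted = (self.pse_offset, self.tata_offset, self.terminator_start)
        if self.planted_class == "embedded_polII":
            if any(v is not None for v in planted):
                raise ValueError(f"{self.locus_id}: embedded loci carry no signals")
            if self.recipient_gene_id is None or self.intron_ordinal is None:
                raise ValueError(f"{self.locus_id}: embedded loci need a recipient")
        elif self.planted_class == "independent_polIII":
            if any(v is None for v in planted):
                raise ValueError(
                    f"{self.locus_id}: independent loci need all three signals"
                )
        else:
            raise ValueError(f"unknown planted_class {self.planted_class!r}")


@dataclass(frozen=True)
class SyntheticGene:
    gene_id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic order, 0-based half-open

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass
class SyntheticSpecies:
    config: SyntheticSpeciesConfig
    chrom: str
    genome: dict[str, str]
    genes: list[SyntheticGene]
    loci: list[NcRNALocus]
    truth: list[TruthRecord]
    training_promoters: list[str]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            row = asdict(t)
            rows.append({k: ("" if v is None else v) for k, v in row.items()})
        columns = [
            "locus_id",
            "planted_class",
            "strand",
            "pse_offset",
            "tata_offset",
            "terminator_start",
            "terminator_length",
            "pse_seq",
            "tata_seq",
            "recipient_gene_id",
            "intron_ordinal",
        ]
        return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# generation


def _gene_length(cfg: SyntheticSpeciesConfig) -> int:
    return cfg.exons_per_gene * cfg.exon_length + (
        cfg.exons_per_gene - 1
    ) * cfg.intron_length


#: clearance kept between a planted cassette and genes / contig edges so the
#: scanner always has full upstream/downstream context available
_CLEARANCE = 150
_EMBED_MARGIN = 10


def generate_species(config: SyntheticSpeciesConfig) -> SyntheticSpecies:
    """Build one synthetic species (genome, genes, loci, truth, training
    promoters) in memory; see :func:`write_species` for the file bundle."""
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"

    gene_len = _gene_length(config)
    n = config.n_host_genes
    gap = (config.genome_length - n * gene_len) // (n + 1) if n else 0
    min_gap = config.locus_length + config.pse_search_window[1] + 2 * _CLEARANCE
    if n and gap < min_gap:
        raise SizingError(
            f"genome_length {config.genome_length} leaves intergenic gaps of "
            f"{gap} bp between {n} host genes of {gene_len} bp; need >= {min_gap}"
        )

    genome = list(random_dna(rng, config.genome_length, config.gc_content))

    genes: list[SyntheticGene] = []
    for i in range(n):
        start = gap + i * (gene_len + gap)
        exons = tuple(
            (
                start + j * (config.exon_length + config.intron_length),
                start + j * (config.exon_length + config.intron_length)
                + config.exon_length,
            )
            for j in range(config.exons_per_gene)
        )
        strand = str(rng.choice(["+", "-"]))
        genes.append(
            SyntheticGene(
                gene_id=f"{config.species_id}_gene{i + 1}",
                start=start,
                end=start + gene_len,
                strand=strand,
                exons=exons,
            )
        )

    occupied: list[tuple[int, int]] = []  # planted cassettes/bodies

    def overlaps_occupied(lo: int, hi: int) -> bool:
        return any(lo < e and s < hi for s, e in occupied)

    loci: list[NcRNALocus] = []
    truth: list[TruthRecord] = []

    # embedded loci ---------------------------------------------------------
    if config.n_embedded_loci:
        if not genes:
            raise SizingError("embedded loci requested but n_host_genes is 0")
        if config.intron_length < config.locus_length + 2 * _EMBED_MARGIN:
            raise SizingError(
                f"introns of {genes[0].gene_id} (and all host genes) are "
                f"{config.intron_length} bp: too short for a "
                f"{config.locus_length} bp embedded locus"
            )
    for k in range(config.n_embedded_loci):
        placed = False
        for _ in range(config.max_placement_retries):
            gene = genes[rng.integers(0, len(genes))]
            introns = gene.introns
            j = int(rng.integers(0, len(introns)))
            ilo, ihi = introns[j]
            lo = ilo + _EMBED_MARGIN
            hi = ihi - _EMBED_MARGIN - config.locus_length
            if hi < lo:
                continue
            start = int(rng.integers(lo, hi + 1))
            if overlaps_occupied(start - _EMBED_MARGIN, start + config.locus_length + _EMBED_MARGIN):
                continue
            body = _locus_body(rng, config)
            strand = gene.strand  # embedded copies ride the host orientation
            genome[start : start + config.locus_length] = list(
                revcomp(body) if strand == "-" else body
            )
            occupied.append((start, start + config.locus_length))
            locus_id = f"{config.species_id}_emb{k + 1}"
            loci.append(
                NcRNALocus(locus_id, chrom, start, start + config.locus_length, strand)
            )
            n_introns = len(introns)
            ordinal = j + 1 if gene.strand == "+" else n_introns - j
            truth.append(
                TruthRecord(
                    locus_id=locus_id,
                    planted_class="embedded_polII",
                    strand=strand,
                    recipient_gene_id=gene.gene_id,
                    intron_ordinal=ordinal,
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place embedded locus {k + 1} after "
                f"{config.max_placement_retries} retries"
            )

    # independent loci ------------------------------------------------------
    gaps: list[tuple[int, int]] = []
    edges = [0] + [c for g in genes for c in (g.start, g.end)] + [config.genome_length]
    for a, b in zip(edges[::2], edges[1::2]):
        lo, hi = a + _CLEARANCE, b - _CLEARANCE
        if hi > lo:
            gaps.append((lo, hi))
    for k in range(config.n_independent_loci):
        if not gaps:
            raise SizingError("no intergenic gap can host an independent locus")
        placed = False
        for _ in range(config.max_placement_retries):
            glo, ghi = gaps[rng.integers(0, len(gaps))]
            g_off = int(
                rng.integers(
                    config.tata_offset_range[0], config.tata_offset_range[1] + 1
                )
            )
            d_floor = max(
                config.pse_search_window[0],
                g_off + len(config.tata_consensus) + len(config.pse_consensus),
            )
            d = int(rng.integers(d_floor, config.pse_search_window[1] + 1))
            run = int(rng.integers(config.polyT_run_range[0],
                                   config.polyT_run_range[1] + 1))
            down_len = config.proximal_window + 10
            total = d + config.locus_length + down_len
            if ghi - glo < total:
                continue
            p = int(rng.integers(glo, ghi - total + 1))
            if overlaps_occupied(p, p + total):
                continue
            up = _upstream_with_signals(rng, config, d, g_off)
            body = _locus_body(rng, config)
            down, term_start = _downstream_with_terminator(rng, config, down_len, run)
            cassette = up + body + down
            strand = str(rng.choice(["+", "-"]))
            if strand == "+":
                genome[p : p + total] = list(cassette)
                start = p + d
            else:
                genome[p : p + total] = list(revcomp(cassette))
                start = p + down_len
            occupied.append((p, p + total))
            locus_id = f"{config.species_id}_ind{k + 1}"
            loci.append(
                NcRNALocus(locus_id, chrom, start, start + config.locus_length, strand)
            )
            truth.append(
                TruthRecord(
                    locus_id=locus_id,
                    planted_class="independent_polIII",
                    strand=strand,
                    pse_offset=d,
                    tata_offset=g_off,
                    terminator_start=term_start,
                    terminator_length=run,
                    pse_seq=up[:len(config.pse_consensus)],
                    tata_seq=up[d - g_off - len(config.tata_consensus) : d - g_off],
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place independent locus {k + 1} after "
                f"{config.max_placement_retries} retries"
            )

    training = [_training_promoter(rng, config) for _ in range(config.n_training_promoters)]

    return SyntheticSpecies(
        config=config,
        chrom=chrom,
        genome={chrom: "".join(genome)},
        genes=genes,
        loci=loci,
        truth=truth,
        training_promoters=training,
    )


def _locus_body(rng: np.random.Generator, cfg: SyntheticSpeciesConfig) -> str:
    """Random locus body with the configured signature motifs planted at
    spread-out positions (so candidates validate as bona fide ncRNAs)."""
    body = list(random_dna(rng, cfg.locus_length, cfg.gc_content))
    motifs = list(cfg.signature_motifs.values())
    if motifs:
        slots = np.linspace(
            20, cfg.locus_length - 20 - max(len(m) for m in motifs), num=len(motifs)
        )
        for pos, motif in zip(slots, motifs):
            pos = int(pos)
            realized = realize_iupac(rng, motif)
            if pos + len(realized) <= cfg.locus_length:
                body[pos : pos + len(realized)] = list(realized)
    return "".join(body)


def _upstream_with_signals(
    rng: np.random.Generator, cfg: SyntheticSpeciesConfig, d: int, gap: int
) -> str:
    """Upstream cassette of length d: PSE copy at its 5' end (so the PSE
    start sits exactly d bases upstream of the locus) and a TATA copy whose
    3' end sits ``gap`` bases upstream of the locus."""
    up = list(random_dna(rng, d, cfg.gc_content))
    pse = mutate(rng, cfg.pse_consensus, cfg.promoter_noise)
    tata = mutate(rng, cfg.tata_consensus, cfg.promoter_noise)
    up[0 : len(pse)] = list(pse)
    tstart = d - gap - len(tata)
    up[tstart : tstart + len(tata)] = list(tata)
    return "".join(up)


def _downstream_with_terminator(
    rng: np.random.Generator, cfg: SyntheticSpeciesConfig, down_len: int, run: int
) -> tuple[str, int]:
    """Downstream cassette: background free of >=min_run T-runs, with one
    planted poly-T run (non-T flanks) inside the proximal window."""
    min_run = cfg.polyT_run_range[0]
    out: list[str] = []
    while len(out) < down_len:
        base = random_dna(rng, 1, cfg.gc_content)
        if base == "T" and len(out) >= min_run - 1 and all(
            b == "T" for b in out[-(min_run - 1):]
        ):
            base = str(rng.choice(["A", "C", "G"]))
        out.append(base)
    term_start = int(rng.integers(0, cfg.proximal_window - run + 1))
    out[term_start : term_start + run] = ["T"] * run
    if term_start > 0 and out[term_start - 1] == "T":
        out[term_start - 1] = str(rng.choice(["A", "C", "G"]))
    end = term_start + run
    if end < down_len and out[end] == "T":
        out[end] = str(rng.choice(["A", "C", "G"]))
    return "".join(out), term_start


def _training_promoter(rng: np.random.Generator, cfg: SyntheticSpeciesConfig) -> str:
    """One U6/7SK-like upstream region: random flanks around a (noisy) PSE
    copy, a variable spacer, and a (noisy) TATA copy — unaligned on purpose,
    the model builder anchors them."""
    left = random_dna(rng, int(rng.integers(10, 26)), cfg.gc_content)
    spacer = random_dna(rng, int(rng.integers(8, 17)), cfg.gc_content)
    right = random_dna(rng, int(rng.integers(15, 31)), cfg.gc_content)
    pse = mutate(rng, cfg.pse_consensus, cfg.promoter_noise)
    tata = mutate(rng, cfg.tata_consensus, cfg.promoter_noise)
    return left + pse + spacer + tata + right


# ---------------------------------------------------------------------------
# file bundle


def write_species(species: SyntheticSpecies, out_dir) -> dict[str, Path]:
    """Write genome FASTA, GFF3, candidate BED6, training-promoter FASTA and
    the truth TSV; the seed is recorded in every header."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = species.config
    seed_note = f"seed={cfg.seed} species={cfg.species_id}"

    paths = {
        "genome": out / "genome.fasta",
        "annotation": out / "annotation.gff3",
        "candidates": out / "candidates.bed",
        "promoters": out / "promoters.fasta",
        "truth": out / "truth.tsv",
    }

    with open(paths["genome"], "w") as fh:
        for name, seq in species.genome.items():
            fh.write(f">{name} {seed_note}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    with open(paths["annotation"], "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"# {seed_note}\n")
        for name, seq in species.genome.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for gene in species.genes:
            c = species.chrom
            fh.write(
                f"{c}\tpol3scan_sim\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            tid = f"{gene.gene_id}.t1"
            fh.write(
                f"{c}\tpol3scan_sim\tmRNA\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={tid};Parent={gene.gene_id}\n"
            )
            for e_i, (es, ee) in enumerate(gene.exons, start=1):
                fh.write(
                    f"{c}\tpol3scan_sim\texon\t{es + 1}\t{ee}\t.\t{gene.strand}\t.\t"
                    f"ID={tid}.exon{e_i};Parent={tid}\n"
                )

    write_bed6(species.loci, paths["candidates"], header_comment=seed_note)

    with open(paths["promoters"], "w") as fh:
        for i, seq in enumerate(species.training_promoters, start=1):
            fh.write(f">{cfg.species_id}_prom{i} {seed_note}\n{seq}\n")

    with open(paths["truth"], "w") as fh:
        fh.write(f"# {seed_note}\n")
        species.truth_frame().to_csv(fh, sep="\t", index=False)

    return paths


# ---------------------------------------------------------------------------
# read-count simulation


def simulate_read_counts(
    interval_ids: Sequence[str],
    lengths: Sequence[int],
    mean_densities: Sequence[float],
    seed: int,
) -> pd.DataFrame:
    """Poisson counts per interval with expectation density x length.

    The count distribution is a stand-in: the underlying published counts
    come from tiling/RNA-seq pipelines whose noise model is unspecified, so
    independent Poisson sampling is used as the simplest count model.
    """
    if not (len(interval_ids) == len(lengths) == len(mean_densities)):
        raise ValueError("interval_ids, lengths and mean_densities must align")
    densities = np.asarray(mean_densities, dtype=float)
    if (densities < 0).any():
        raise ValueError("mean densities must be >= 0")
    lengths_arr = np.asarray(lengths, dtype=int)
    if (lengths_arr <= 0).any():
        raise ValueError("interval lengths must be > 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(densities * lengths_arr)
    return pd.DataFrame(
        {
            "interval_id": list(interval_ids),
            "count": counts.astype(int),
            "length": lengths_arr,
        }
    )


def audit_planted_signals(species: SyntheticSpecies) -> None:
    """Literal re-scan of the emitted genome: every independent locus must
    show its planted PSE/TATA copies at the recorded offsets and its poly-T
    run at the recorded start.  Raises AssertionError on any mismatch."""
    from .scan import locus_flanks  # local import to avoid a cycle

    cfg = species.config
    by_id = {l.locus_id: l for l in species.loci}
    for t in species.truth:
        if t.planted_class != "independent_polIII":
            continue
        locus = by_id[t.locus_id]
        up, _body, down = locus_flanks(
            species.genome, locus, cfg.pse_search_window[1], cfg.proximal_window + 10
        )
        d, gap = t.pse_offset, t.tata_offset
        got_pse = up[len(up) - d : len(up) - d + len(cfg.pse_consensus)]
        if got_pse != t.pse_seq:
            raise AssertionError(f"{t.locus_id}: PSE not at recorded offset {d}")
        tlen = len(cfg.tata_consensus)
        got_tata = up[len(up) - gap - tlen : len(up) - gap]
        if got_tata != t.tata_seq:
            raise AssertionError(f"{t.locus_id}: TATA not at recorded gap {gap}")
        run = down[t.terminator_start : t.terminator_start + t.terminator_length]
        if run != "T" * t.terminator_length:
            raise AssertionError(
                f"{t.locus_id}: poly-T run not at recorded start {t.terminator_start}"
            )
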