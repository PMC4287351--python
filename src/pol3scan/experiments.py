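"""Study-scale experiments over synthetic species panels.

These functions drive the library end to end at the problem sizes used by
the analysis scripts: multi-species round-trip recovery of the planted
two-group divide, recall of independent pol III loci as promoter noise
rises, and strand-symmetry audits.  Everything is seeded; seeds derived
for sub-experiments stay below 2**31.
"""

from __future__ import annotations

import tempfile
from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import EMBEDDED, INDEPENDENT, make_record, summarize_species
from .context import Annotation, Gene, Transcript, resolve_context
from .pipeline import RunConfig, run_pipeline
from .pwm import build_promoter_model
from .scan import scan_locus
from .seqs import revcomp
from .synthetic import (
    SyntheticSpecies,
    SyntheticSpeciesConfig,
    generate_species,
    write_species,
)

_SEED_MOD = 2**31 - 1


def _sub_seed(seed: int, salt: int) -> int:
    return (seed * 1_000_003 + salt) % _SEED_MOD


def annotation_from_species(species: SyntheticSpecies) -> Annotation:
    """Build the in-memory annotation directly from the generator's gene
    models (equivalent to writing and re-parsing the GFF3)."""
    genes = []
    for g in species.genes:
        tx = Transcript(f"{g.gene_id}.t1", g.gene_id, species.chrom, g.strand, g.exons)
        genes.append(Gene(g.gene_id, species.chrom, g.start, g.end, g.strand, (tx,)))
    return Annotation(genes, known_chroms={species.chrom})


def classify_species_in_memory(species: SyntheticSpecies):
    """Model building + scanning + context + classification without file IO."""
    model = build_promoter_model(
        species.training_promoters,
        pse_consensus=species.config.pse_consensus,
        tata_consensus=species.config.tata_consensus,
        pse_search_window=species.config.pse_search_window,
        tata_offset_window=species.config.tata_offset_range,
    )
    annotation = annotation_from_species(species)
    records = []
    for locus in species.loci:
        status = scan_locus(
            species.genome,
            locus,
            model,
            proximal_window=species.config.proximal_window,
        )
        context = resolve_context(locus, annotation)
        records.append(make_record(species.config.species_id, status, context))
    return records, model


def panel_configs(
    seed: int,
    n_embedded_species: int = 3,
    n_independent_species: int = 3,
    loci_per_species: int = 6,
    promoter_noise: float = 0.0,
) -> list[SyntheticSpeciesConfig]:
    """A panel of single-architecture species: each species carries either
    only embedded or only independent loci, mirroring the observed divide."""
    configs = []
    for i in range(n_embedded_species):
        configs.append(
            SyntheticSpeciesConfig(
                species_id=f"emb_species_{i + 1}",
                seed=_sub_seed(seed, i),
                n_embedded_loci=loci_per_species,
                n_independent_loci=0,
                promoter_noise=promoter_noise,
            )
        )
    for i in range(n_independent_species):
        configs.append(
            SyntheticSpeciesConfig(
                species_id=f"ind_species_{i + 1}",
                seed=_sub_seed(seed, 100 + i),
                n_embedded_loci=0,
                n_independent_loci=loci_per_species,
                promoter_noise=promoter_noise,
            )
        )
    return configs


def _expected_group(truth_classes: Sequence[str]) -> str:
    n_emb = sum(c == EMBEDDED for c in truth_classes)
    n_ind = sum(c == INDEPENDENT for c in truth_classes)
    if n_emb and not n_ind:
        return "embedded group"
    if n_ind and not n_emb:
        return "polIII group"
    return "mixed/unresolved"


def roundtrip_panel(seed: int, file_based: bool = True, **panel_kwargs) -> dict:
    """Run the full classifier over a noise-free panel and score the
    recovery of the planted locus classes and species divide.

    ``file_based=True`` round-trips every species through the on-disk
    bundle (FASTA/GFF3/BED/TSV) and the pipeline runner, exercising the
    same path a shell user takes.
    """
    configs = panel_configs(seed, **panel_kwargs)
    all_records = []
    truth_by_locus: dict[str, str] = {}
    expected_groups: dict[str, str] = {}
    for cfg in configs:
        species = generate_species(cfg)
        for t in species.truth:
            truth_by_locus[t.locus_id] = t.planted_class
        expected_groups[cfg.species_id] = _expected_group(
            [t.planted_class for t in species.truth]
        )
        if file_based:
            with tempfile.TemporaryDirectory() as tmp:
                paths = write_species(species, Path(tmp) / "data")
                result = run_pipeline(
                    RunConfig(
                        genome=paths["genome"],
                        annotation=paths["annotation"],
                        candidates=paths["candidates"],
                        promoters=paths["promoters"],
                        out_dir=Path(tmp) / "out",
                        species_id=cfg.species_id,
                        seed=cfg.seed,
                    )
                )
            all_records.extend(result.records)
        else:
            records, _model = classify_species_in_memory(species)
            all_records.extend(records)

    predicted = {r.locus_id: r.final_class for r in all_records}
    per_class = {}
    for cls in (EMBEDDED, INDEPENDENT):
        tp = sum(
            1
            for lid, true_cls in truth_by_locus.items()
            if true_cls == cls and predicted[lid] == cls
        )
        n_pred = sum(1 for v in predicted.values() if v == cls)
        n_true = sum(1 for v in truth_by_locus.values() if v == cls)
        per_class[cls] = {
            "precision": tp / n_pred if n_pred else 1.0,
            "recall": tp / n_true if n_true else 1.0,
        }
    summary = summarize_species(all_records).set_index("species_id")
    species_hits = sum(
        summary.loc[sp, "group"] == grp for sp, grp in expected_groups.items()
    )
    return {
        "n_loci": len(truth_by_locus),
        "n_species": len(configs),
        "locus_accuracy": np.mean(
            [predicted[lid] == cls for lid, cls in truth_by_locus.items()]
        ),
        "precision": min(v["precision"] for v in per_class.values()),
        "recall": min(v["recall"] for v in per_class.values()),
        "per_class": per_class,
        "species_divide_accuracy": species_hits / len(configs),
    }


def noise_recall_curve(
    seed: int,
    noise_levels: Sequence[float] = (0.0, 0.1, 0.2, 0.3),
    n_replicates: int = 25,
    loci_per_replicate: int = 8,
) -> pd.DataFrame:
    """Recall of independent pol III loci at increasing promoter noise.

    Each replicate is one independent-only species whose training promoters
    and planted signals diverge from the species consensus at the given
    per-site rate; replicates share derived seeds across noise levels.
    """
    rows = []
    for noise in noise_levels:
        tp = n = 0
        for rep in range(n_replicates):
            cfg = SyntheticSpeciesConfig(
                species_id=f"noise_rep{rep}",
                seed=_sub_seed(seed, 10_000 + rep),
                n_embedded_loci=0,
                n_independent_loci=loci_per_replicate,
                n_host_genes=4,
                promoter_noise=noise,
            )
            species = generate_species(cfg)
            records, _ = classify_species_in_memory(species)
            n += len(records)
            tp += sum(r.final_class == INDEPENDENT for r in records)
        rows.append({"promoter_noise": noise, "recall": tp / n, "n_loci": n})
    return pd.DataFrame(rows)


def strand_symmetry_agreement(seed: int, n_species: int = 3) -> dict:
    """Fraction of synthetic loci whose evidence scan is identical between
    the native construction and the reverse-complemented genome with
    mirrored locus coordinates and flipped strand."""
    agree = total = 0
    for i in range(n_species):
        cfg = SyntheticSpeciesConfig(
            species_id=f"sym_{i}",
            seed=_sub_seed(seed, 20_000 + i),
            n_embedded_loci=3,
            n_independent_loci=3,
        )
        species = generate_species(cfg)
        model = build_promoter_model(species.training_promoters)
        chrom_seq = species.genome[species.chrom]
        flipped = {species.chrom: revcomp(chrom_seq)}
        for locus in species.loci:
            mirrored = replace(
                locus,
                start=len(chrom_seq) - locus.end,
                end=len(chrom_seq) - locus.start,
                strand="-" if locus.strand == "+" else "+",
            )
            total += 1
            agree += scan_locus(species.genome, locus, model) == scan_locus(
                flipped, mirrored, model
            )
    return {"agreement": agree / total, "n_loci": total}


def positional_rule_checks() -> dict:
    """Boundary behavior of the positioned-TATA gap window and the poly-T
    minimum run, checked on deterministic planted constructions."""
    from .pwm import PromoterModel, build_pwm, calibrate_threshold
    from .scan import scan_polyT, scan_tata_positioned

    tata_pwm = build_pwm(["TATAAA"] * 4)
    pse_pwm = build_pwm(["CTCACCCTAACTCA"] * 4)
    model = PromoterModel(
        pse=pse_pwm,
        tata=tata_pwm,
        pse_threshold=calibrate_threshold(pse_pwm, ["CTCACCCTAACTCA"]),
        tata_threshold=calibrate_threshold(tata_pwm, ["TATAAA"]),
    )
    checks = {}
    for gap, expected in [(21, True), (27, True), (20, False), (28, False)]:
        seq = ["C"] * 120
        start = 120 - gap - 6
        seq[start : start + 6] = "TATAAA"
        _hit, positioned = scan_tata_positioned("".join(seq), model)
        checks[f"tata_gap_{gap}"] = positioned is expected
    for run, expected in [(3, False), (4, True), (5, True)]:
        call = scan_polyT("G" * 5 + "T" * run + "G" * 20)
        checks[f"polyT_run_{run}"] = (call is not None) is expected
    return {
        "accuracy": sum(checks.values()) / len(checks),
        "n_checks": len(checks),
        "checks": checks,
    }
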