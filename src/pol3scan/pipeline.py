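"""End-to-end orchestration: model building, scanning, context resolution,
classification, optional density and signature reports, plus a manifest
recording parameters, seed and input checksums for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO

from . import classify as classify_mod
from .context import Annotation, ContextCall, find_cohabitants, resolve_context
from .defaults import (
    DEFAULT_ABOX,
    DEFAULT_BBOX,
    DEFAULT_MIN_POLYT_RUN,
    DEFAULT_PROXIMAL_WINDOW,
    DEFAULT_PSE_CONSENSUS,
    DEFAULT_PSE_SEARCH_WINDOW,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_TATA_CONSENSUS,
    DEFAULT_TATA_OFFSET_WINDOW,
    DEFAULT_THRESHOLD_MARGIN,
)
from .loci import read_bed6
from .pwm import PromoterModel, build_promoter_model, save_model
from .scan import PolIIIStatus, scan_locus, tata_gap
from .density import density_report, read_counts_tsv
from .signatures import SignatureSet, verify_candidate

log = logging.getLogger("pol3scan")


@dataclass
class RunConfig:
    genome: Path
    annotation: Path
    candidates: Path
    promoters: Path
    out_dir: Path
    species_id: str = "species"
    counts: Optional[Path] = None
    reference_interval: Optional[str] = None
    signatures_yaml: Optional[Path] = None
    pse_consensus: str = DEFAULT_PSE_CONSENSUS
    tata_consensus: str = DEFAULT_TATA_CONSENSUS
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    margin: float = DEFAULT_THRESHOLD_MARGIN
    tata_offset_window: tuple[int, int] = DEFAULT_TATA_OFFSET_WINDOW
    pse_search_window: tuple[int, int] = DEFAULT_PSE_SEARCH_WINDOW
    min_polyT_run: int = DEFAULT_MIN_POLYT_RUN
    proximal_window: int = DEFAULT_PROXIMAL_WINDOW
    abox: str = DEFAULT_ABOX
    bbox: str = DEFAULT_BBOX
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genome", "annotation", "candidates", "promoters"):
            path = Path(getattr(self, name))
            setattr(self, name, path)
            if not path.exists():
                raise FileNotFoundError(f"{name} input missing: {path}")
        for name in ("counts", "signatures_yaml"):
            value = getattr(self, name)
            if value is not None:
                path = Path(value)
                setattr(self, name, path)
                if not path.exists():
                    raise FileNotFoundError(f"{name} input missing: {path}")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.update(overrides)
        for key in ("tata_offset_window", "pse_search_window"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class RunResult:
    model: PromoterModel
    statuses: dict[str, PolIIIStatus]
    contexts: dict[str, ContextCall]
    records: list
    evidence: pd.DataFrame
    context_table: pd.DataFrame
    classification: pd.DataFrame
    species_summary: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def load_genome(path) -> dict[str, str]:
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def load_promoters(path) -> list[str]:
    seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def evidence_table(
    statuses: dict[str, PolIIIStatus], model: PromoterModel
) -> pd.DataFrame:
    upstream_len = max(model.min_upstream_length, model.pse_search_window[1])
    rows = []
    for locus_id, st in statuses.items():
        rows.append(
            {
                "locus_id": locus_id,
                "pse_score": "" if st.pse_hit is None else round(st.pse_hit.score, 4),
                # distance from PSE start to locus start, on the sense strand
                "pse_start": ""
                if st.pse_hit is None
                else upstream_len - st.pse_hit.start,
                "tata_score": ""
                if st.tata_hit is None
                else round(st.tata_hit.score, 4),
                "tata_gap": ""
                if st.tata_hit is None
                else tata_gap(st.tata_hit, upstream_len),
                "tata_positioned": st.tata_positioned,
                "polyT_start": "" if st.terminator is None else st.terminator.run_start,
                "polyT_len": "" if st.terminator is None else st.terminator.run_length,
                "proximal": False if st.terminator is None else st.terminator.proximal,
                "internal_promoter": st.internal_promoter,
                "verdict": st.verdict,
            }
        )
    return pd.DataFrame(rows)


def context_table(contexts: dict[str, ContextCall]) -> pd.DataFrame:
    rows = []
    for locus_id, c in contexts.items():
        rows.append(
            {
                "locus_id": locus_id,
                "placement": c.placement,
                "recipient_gene_id": c.recipient_gene_id or "",
                "flank_5prime": c.flanking_gene_ids[0] if c.flanking_gene_ids else "",
                "flank_3prime": c.flanking_gene_ids[1] if c.flanking_gene_ids else "",
                "intron_ordinal": "" if c.intron_ordinal is None else c.intron_ordinal,
                "last_intron": c.last_intron,
                "orientation": c.orientation,
                "containment": c.containment,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunResult:
    """Scan -> context -> classify for one species; writes the report bundle
    (evidence/context/classification/species-summary TSVs + manifest) into
    ``config.out_dir`` and returns the in-memory results."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    log.info("loading inputs")
    genome = load_genome(config.genome)
    annotation = Annotation.from_gff3(config.annotation)
    loci = read_bed6(config.candidates)
    promoters = load_promoters(config.promoters)

    log.info("building promoter model from %d training sequences", len(promoters))
    model = build_promoter_model(
        promoters,
        pse_consensus=config.pse_consensus,
        tata_consensus=config.tata_consensus,
        pseudocount=config.pseudocount,
        margin=config.margin,
        tata_offset_window=config.tata_offset_window,
        pse_search_window=config.pse_search_window,
    )

    log.info("scanning %d candidate loci", len(loci))
    statuses = {
        l.locus_id: scan_locus(
            genome,
            l,
            model,
            min_polyT_run=config.min_polyT_run,
            proximal_window=config.proximal_window,
            abox=config.abox,
            bbox=config.bbox,
        )
        for l in loci
    }
    contexts = {l.locus_id: resolve_context(l, annotation) for l in loci}
    records = [
        classify_mod.make_record(config.species_id, statuses[l.locus_id], contexts[l.locus_id])
        for l in loci
    ]

    evidence = evidence_table(statuses, model)
    ctx_table = context_table(contexts)
    classification = classify_mod.records_to_frame(records)
    summary = classify_mod.summarize_species(records) if records else pd.DataFrame()

    paths = {
        "model": out / "promoter_model.json",
        "evidence": out / "evidence.tsv",
        "context": out / "context.tsv",
        "cohabitation": out / "cohabitation.tsv",
        "classification": out / "classification.tsv",
        "species_summary": out / "species_summary.tsv",
        "manifest": out / "manifest.json",
    }
    save_model(model, paths["model"])
    evidence.to_csv(paths["evidence"], sep="\t", index=False)
    ctx_table.to_csv(paths["context"], sep="\t", index=False)
    groups = find_cohabitants(loci, annotation, [contexts[l.locus_id] for l in loci])
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "locus_ids": ",".join(g.locus_ids),
                "n_members": len(g.locus_ids),
                "same_intron": g.same_intron,
                "tandem": g.tandem,
            }
            for g in groups
        ]
    ).to_csv(paths["cohabitation"], sep="\t", index=False)
    classification.to_csv(paths["classification"], sep="\t", index=False)
    summary.to_csv(paths["species_summary"], sep="\t", index=False)

    if config.signatures_yaml is not None:
        sigs = SignatureSet.from_yaml(config.signatures_yaml)
        rows = []
        for l in loci:
            report = verify_candidate(l.sense_sequence(genome), sigs)
            rows.append(
                {
                    "locus_id": l.locus_id,
                    "passed": report.passed,
                    "missing": ",".join(report.missing),
                    **{
                        f"hits_{name}": ",".join(map(str, starts))
                        for name, starts in report.hits.items()
                    },
                }
            )
        paths["signatures"] = out / "signature_report.tsv"
        pd.DataFrame(rows).to_csv(paths["signatures"], sep="\t", index=False)

    if config.counts is not None:
        if config.reference_interval is None:
            raise ValueError("counts input requires reference_interval")
        report = density_report(read_counts_tsv(config.counts), config.reference_interval)
        paths["density"] = out / "density_report.tsv"
        report.to_csv(paths["density"], sep="\t", index=False)

    try:
        ver = pkg_version("pol3scan")
    except PackageNotFoundError:  # running from a source tree
        ver = "unknown"
    manifest = {
        "package": "pol3scan",
        "version": ver,
        "seed": config.seed,
        "species_id": config.species_id,
        "parameters": {
            "pse_consensus": config.pse_consensus,
            "tata_consensus": config.tata_consensus,
            "pseudocount": config.pseudocount,
            "margin": config.margin,
            "tata_offset_window": list(config.tata_offset_window),
            "pse_search_window": list(config.pse_search_window),
            "min_polyT_run": config.min_polyT_run,
            "proximal_window": config.proximal_window,
            "abox": config.abox,
            "bbox": config.bbox,
        },
        "inputs": {
            name: {"path": str(getattr(config, name)), "sha256": _sha256(getattr(config, name))}
            for name in ("genome", "annotation", "candidates", "promoters")
        },
        "outputs": {name: str(p) for name, p in paths.items()},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return RunResult(
        model=model,
        statuses=statuses,
        contexts=contexts,
        records=records,
        evidence=evidence,
        context_table=ctx_table,
        classification=classification,
        species_summary=summary,
        paths=paths,
    )
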