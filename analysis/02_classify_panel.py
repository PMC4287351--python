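#!/usr/bin/env python
"""Run the full classifier over the synthetic panel and score the recovery
of the planted two-group divide.

Each species round-trips through its on-disk bundle (FASTA/GFF3/BED) and
the pipeline runner: promoter-model calibration from its own training
promoters, evidence scanning, genomic-context resolution, and per-locus /
per-species classification.  Writes the locus table, species summary and
recovery metrics under results/.
"""

import argparse
import json
from pathlib import Path

from pol3scan.experiments import roundtrip_panel

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=20_240_101)
    args = parser.parse_args()

    out = roundtrip_panel(args.seed, file_based=True)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with open(results / "02_roundtrip_metrics.json", "w") as fh:
        json.dump(out, fh, indent=1)
        fh.write("\n")

    print(
        f"{out['n_species']} species, {out['n_loci']} loci: "
        f"locus accuracy {out['locus_accuracy']:.3f}, "
        f"precision {out['precision']:.3f}, recall {out['recall']:.3f}, "
        f"species divide accuracy {out['species_divide_accuracy']:.3f}"
    )
    if out["precision"] == out["recall"] == 1.0:
        print(
            "Every planted class was recovered exactly: signal-free intronic "
            "loci -> embedded group, full-promoter intergenic loci -> pol III "
            "group."
        )


if __name__ == "__main__":
    main()
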