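#!/usr/bin/env python
"""Read-density enrichment of the ncRNA-containing region over the
preceding intron of its recipient gene.

Two parts: (i) the published polyA+ worked examples, recomputed from the
printed per-interval read counts (both land inside the 3- to 5-fold
claim); (ii) a seeded simulation check that Poisson counts planted at a
known density ratio recover that ratio.  Writes results/03_density.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from pol3scan.density import DensityRecord, fold_enrichment
from pol3scan.synthetic import simulate_read_counts

ROOT = Path(__file__).resolve().parents[1]

POLYA = {
    "D_virilis": ((2435, 353), (978, 683)),
    "D_pseudoobscura": ((2478, 322), (1980, 804)),
}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=20_240_101)
    parser.add_argument("--replicates", type=int, default=200)
    args = parser.parse_args()

    rows = []
    for label, (rpr, intron) in POLYA.items():
        a = DensityRecord("rpr", *rpr)
        b = DensityRecord("prev_intron", *intron)
        ratio = fold_enrichment(a, b)
        rows.append(
            {
                "comparison": label,
                "source": "published polyA+ counts",
                "rpr_density": round(a.density, 4),
                "intron_density": round(b.density, 4),
                "fold_enrichment": round(ratio, 3),
                "within_3_to_5_fold": 3.0 <= ratio <= 5.0,
            }
        )
        print(f"{label}: {ratio:.3f}-fold enrichment (3-5 fold claim: ok)")

    # simulation: plant a 4.8-fold ratio at realistic interval sizes
    ratios = []
    for rep in range(args.replicates):
        counts = simulate_read_counts(
            ["rpr", "prev_intron"], [353, 683], [4.8 * 1.5, 1.5],
            seed=(args.seed + rep) % (2**31 - 1),
        )
        d = counts["count"] / counts["length"]
        ratios.append(d.iloc[0] / d.iloc[1])
    mean_ratio = sum(ratios) / len(ratios)
    rows.append(
        {
            "comparison": "simulated_4.8x",
            "source": f"{args.replicates} Poisson replicates",
            "rpr_density": "",
            "intron_density": "",
            "fold_enrichment": round(mean_ratio, 3),
            "within_3_to_5_fold": 3.0 <= mean_ratio <= 5.0,
        }
    )
    print(
        f"simulated planted 4.8x ratio recovered as {mean_ratio:.3f} "
        f"over {args.replicates} replicates"
    )

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(results / "03_density.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
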