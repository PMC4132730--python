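#!/usr/bin/env python
"""Perkins map distances per genotype and comparisons against wild type.

Reads the class-count tables written by 01_simulate_populations.py,
estimates the Perkins distance (cM +/- SD) of both intervals for every
genotype, and tests each mutant-like genotype against wild type with the
between-genotype Z test, reporting the percent change.  The class II
derepression presets should show clearly increased distances (moderate for
the cofactor-like genotype, strong for the helicase-like one) on both
intervals.  Writes results/map_distances.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from tetrakit import distance_z_test, map_distance, percent_change
from tetrakit.io import read_class_counts

GENOTYPES = ("wild_type", "mhf_like", "fancm_like", "poisson_null")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    counts = {
        name: read_class_counts(args.outdir / f"counts_{name}.csv")
        for name in GENOTYPES
    }
    rows = []
    for name in GENOTYPES:
        for interval in ("I2a", "I2b"):
            d = map_distance(counts[name], interval)
            row = {
                "genotype": name,
                "interval": interval,
                "cM": round(d.cM, 3),
                "sd": round(d.sd, 3),
                "n": d.n,
            }
            if name != "wild_type":
                ref = map_distance(counts["wild_type"], interval)
                z, p = distance_z_test(d, ref)
                row |= {
                    "pct_change_vs_wild_type": round(percent_change(d, ref), 1),
                    "z_vs_wild_type": round(z, 3),
                    "p_vs_wild_type": float(f"{p:.3g}"),
                }
            rows.append(row)
            print(
                f"{name:13s} {interval}: {d.cM:6.2f} cM +/- {d.sd:.2f}"
                + (
                    f"  ({row['pct_change_vs_wild_type']:+.1f}% vs wild type, "
                    f"P = {row['p_vs_wild_type']:.3g})"
                    if name != "wild_type"
                    else ""
                )
            )
    out = args.outdir / "map_distances.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
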