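#!/usr/bin/env python
"""Simulate tetrad populations for the illustrative genotype presets.

Generates 20,000 pollen tetrads per genotype under the two-pathway
crossover model — a wild type dominated by interfering class I crossovers,
two anti-crossover-mutant-like genotypes with the Poisson class II pathway
derepressed to different degrees, and an interference-free Poisson control —
classifies them into joint (I2a, I2b) PD/TT/NPD classes, and writes one
class-count table per genotype under results/.
"""

import argparse
from pathlib import Path

from tetrakit import preset, simulate_tetrad_population, tally
from tetrakit.io import write_class_counts

GENOTYPES = ("wild_type", "mhf_like", "fancm_like", "poisson_null")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--n", type=int, default=20_000)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for i, name in enumerate(GENOTYPES):
        cfg = preset(name, n_meioses=args.n, seed=args.seed + i)
        counts = tally(simulate_tetrad_population(cfg))
        out = args.outdir / f"counts_{name}.csv"
        write_class_counts(counts, out)
        print(
            f"{name}: {counts.n} tetrads scored "
            f"(class I {cfg.lambda1}, class II {cfg.lambda2}, "
            f"shape {cfg.nu}) -> {out}"
        )


if __name__ == "__main__":
    main()
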