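#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes, under results/simulated/:
  * a 5-Mb pileup genome (theta=0.002, eps=0.002, depth 10) with five
    planted homozygous tracts, plus the planted-truth BED;
  * a three-population genotype panel (A, B and an admixed target C at
    alpha=0.5) as VCF with a sample->population map;
  * a two-locus Wright-Fisher LD panel at Ne=500, c=0.005.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np

from herdscan import formats, genoqc, simdata

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    spec = simdata.plant_tracts(5_000_000, 5, 25, 50, rng)
    table, truth = simdata.simulate_pileup_genome(
        5_000_000, theta=0.002, epsilon=0.002, mean_depth=10, roh_spec=spec, seed=SEED
    )
    formats.write_pileup(table, OUT / "genome.pileup.tsv")
    formats.write_bed(truth.planted_roh, OUT / "planted_roh.bed")
    (OUT / "genome.truth.json").write_text(
        json.dumps(dataclasses.asdict(truth), default=str, indent=2) + "\n"
    )
    print(f"pileup genome: {len(table)} covered sites, {len(spec)} planted tracts")

    ga, gb, gc, ptruth = simdata.simulate_admixed_panel(
        50_000, f_a=0.05, f_b=0.05, f_c=0.001, alpha=0.5, n_per_pop=30, seed=SEED
    )
    merged, groups = genoqc.combine_panels({"A": ga, "B": gb, "C": gc})
    formats.write_vcf(merged, OUT / "panel.vcf")
    with open(OUT / "populations.tsv", "w") as fh:
        fh.write("sample\tpopulation\n")
        for s, p in groups.items():
            fh.write(f"{s}\t{p}\n")
    print(f"admixed panel: {merged.n_variants} SNPs x {merged.n_samples} samples (alpha=0.5)")

    g, ltruth = simdata.simulate_twolocus_wf(500, 0.005, 2000, 50, seed=SEED)
    formats.write_vcf(g, OUT / "ld_panel.vcf")
    print(f"LD panel: {g.n_variants // 2} two-locus systems at c={ltruth.extras['c']}")


if __name__ == "__main__":
    main()
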