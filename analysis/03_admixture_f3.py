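#!/usr/bin/env python
"""QC, LD pruning and the three-population f3 test on the panel from 01.

Reads results/simulated/panel.vcf; writes qc_report.tsv and f3.tsv under
results/admixture/. The target C was generated as a 50:50 mixture of A and
B, so f3(C; A, B) should be strongly negative (Z << -3).
"""

import dataclasses
from pathlib import Path

import pandas as pd

from herdscan import f3stats, formats, genoqc

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "admixture"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    g = formats.read_vcf(ROOT / "simulated" / "panel.vcf")
    pm = pd.read_csv(ROOT / "simulated" / "populations.tsv", sep="\t")
    groups = dict(zip(pm["sample"], pm["population"]))

    qc, rep = genoqc.qc_filter(g)
    (OUT / "qc_report.tsv").write_text("\n".join(rep.steps) + "\n")
    print(f"QC: {g.n_variants} -> {qc.n_variants} variants, "
          f"{g.n_samples} -> {qc.n_samples} samples")

    pruned = genoqc.ld_prune(qc, r2_max=0.10)
    print(f"LD pruning (r2 < 0.10): {qc.n_variants} -> {pruned.n_variants} variants")

    freqs = f3stats.allele_freqs(qc, groups)
    rows = []
    for target, ra, rb in [("C", "A", "B"), ("A", "B", "C"), ("B", "A", "C")]:
        r = f3stats.f3(target, ra, rb, freqs, block_snps=1000)
        rows.append(dataclasses.asdict(r))
        verdict = "admixed" if r.significant else "no admixture signal"
        print(f"f3({target}; {ra}, {rb}) = {r.f3:+.5f} +- {r.se:.5f}  "
              f"Z = {r.z:+.1f}  -> {verdict}")
    formats.write_tsv(pd.DataFrame(rows), OUT / "f3.tsv")


if __name__ == "__main__":
    main()
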