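#!/usr/bin/env python
"""Windowed heterozygosity, theta/epsilon ML and ROH calling on the
simulated genome from 01, scored against the planted truth.

Reads results/simulated/genome.pileup.tsv; writes windows.tsv, theta.json,
roh.bed and roh_summary.tsv under results/diversity/.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from herdscan import formats, roh, seqdiversity

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "diversity"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = formats.read_pileup(ROOT / "simulated" / "genome.pileup.tsv")
    truth = json.loads((ROOT / "simulated" / "genome.truth.json").read_text())
    f = seqdiversity.filter_sites(table)
    print(f"{len(f)}/{len(table)} sites pass the 4-30x depth filter")

    wins = seqdiversity.window_heterozygosity(f)
    formats.write_tsv(wins, OUT / "windows.tsv")
    ok = wins[~wins.flagged]
    print(f"mean 10-kb window het rate: {ok.het_rate.mean():.3e} "
          f"(generated theta {truth['theta_true']})")

    est = seqdiversity.estimate_theta_epsilon(f)
    (OUT / "theta.json").write_text(json.dumps(dataclasses.asdict(est), indent=2) + "\n")
    print(f"ML estimates: theta={est.theta:.3e} eps={est.epsilon:.3e} "
          f"(truth {truth['theta_true']}, {truth['epsilon_true']})")

    bins = roh.bin_counts(f)
    avg = roh.genome_average(bins)
    calls = roh.call_roh(bins, avg)
    formats.write_bed(calls, OUT / "roh.bed")
    assayed = int((~bins.no_data).sum()) * 10_000
    summ = roh.summarize_roh(calls, f, assayed)
    formats.write_tsv(pd.DataFrame([dataclasses.asdict(summ)]), OUT / "roh_summary.tsv")
    print(f"called {summ.n_roh} ROH covering {summ.cum_length/1e6:.2f} Mb "
          f"(F_ROH={summ.f_roh:.3f}); planted {len(truth['planted_roh'])} tracts")
    print(f"pi_in={summ.pi_in:.2e}  pi_out={summ.pi_out:.2e}")


if __name__ == "__main__":
    main()
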