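"""Bin-based detection of runs of homozygosity (ROH) from pileup data.

The genome is tiled into consecutive 10-kb bins; each bin's statistic is the
number of heterozygous calls among its well-covered sites ("SNP count"). A
run of homozygosity is a stretch of bins whose SNP counts are far below the
genome-wide average:

* a bin is *low* when its SNP count is below ``seed_factor`` (default 0.25)
  times the genomic average count per bin;
* a candidate run starts and ends at low bins; between low bins it may pass
  over bins of ordinary diversity provided each stays at or below
  ``bin_ceiling_factor`` (2.0) times the average — this relaxation absorbs
  isolated local-assembly or alignment artifacts inside a genuinely
  homozygous stretch;
* every time the run reaches a further low bin, its running mean SNP count
  must not exceed ``run_mean_factor`` (2/3) of the genomic average; when no
  further low bin is reachable the candidate is trimmed back to the last low
  bin reached (so a run never ends on an above-threshold bin);
* a run is emitted only if it spans at least ``min_bins`` (20) bins and
  ``min_length`` base pairs.

Low-coverage ("no-data") bins inside a candidate neither extend nor break it
when at most 2 consecutive; 3 or more consecutive no-data bins break the run.
Scanning resumes after an emitted run, so emitted intervals are disjoint.

``summarize_roh`` reports the count, cumulative length and genome fraction
(F_ROH) of the calls, plus nucleotide diversity inside (pi_in) and outside
(pi_out) their union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqdiversity import PileupTable, het_call_sensitivity, het_mask


@dataclass(frozen=True)
class ROHParams:
    bin_size: int = 10_000
    seed_factor: float = 0.25
    bin_ceiling_factor: float = 2.0
    run_mean_factor: float = 2.0 / 3.0
    min_bins: int = 20
    min_length: int | None = None  # defaults to min_bins * bin_size
    max_nodata_gap: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.seed_factor < self.run_mean_factor < self.bin_ceiling_factor):
            raise ValueError("require 0 < seed_factor < run_mean_factor < bin_ceiling_factor")
        if self.min_bins < 1:
            raise ValueError("min_bins must be >= 1")

    @property
    def effective_min_length(self) -> int:
        return self.min_bins * self.bin_size if self.min_length is None else self.min_length


@dataclass
class ROHInterval:
    chrom: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    n_bins: int
    mean_snp_per_bin: float


@dataclass
class ROHSummary:
    n_roh: int
    cum_length: int
    f_roh: float
    pi_in: float
    pi_out: float
    pi_in_raw: float = 0.0
    pi_out_raw: float = 0.0


def bin_counts(
    table: PileupTable,
    bin_size: int = 10_000,
    min_covered_fraction: float = 0.2,
    min_alt_reads: int = 2,
    min_alt_fraction: float = 0.2,
) -> pd.DataFrame:
    """Tile each chromosome into consecutive bins of ``bin_size`` bp.

    Bins run from coordinate 0 to the last covered site; every bin in that
    range is emitted, including empty ones. Columns: chrom, bin_index,
    start, end, snp_count, covered_sites, no_data (True when covered_sites
    is below ``min_covered_fraction`` x bin_size).
    """
    if not table.is_sorted():
        raise ValueError("pileup sites must be sorted by (chrom, pos)")
    het = het_mask(table, min_alt_reads, min_alt_fraction)
    frames = []
    for chrom in dict.fromkeys(table.chrom):
        sel = table.chrom == chrom
        pos = table.pos[sel]
        h = het[sel]
        n_bins = int((pos.max() - 1) // bin_size) + 1 if len(pos) else 0
        bidx = (pos - 1) // bin_size
        covered = np.bincount(bidx, minlength=n_bins)
        snp = np.bincount(bidx, weights=h.astype(float), minlength=n_bins).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_index": np.arange(n_bins),
                    "start": np.arange(n_bins) * bin_size,
                    "end": (np.arange(n_bins) + 1) * bin_size,
                    "snp_count": snp,
                    "covered_sites": covered,
                    "no_data": covered < min_covered_fraction * bin_size,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "bin_index", "start", "end", "snp_count", "covered_sites", "no_data"]
        )
    return pd.concat(frames, ignore_index=True)


def genome_average(bins: pd.DataFrame) -> float:
    """Mean SNP count per bin over informative (non-no-data) bins."""
    ok = bins.loc[~bins["no_data"], "snp_count"]
    if len(ok) == 0:
        raise ValueError("no informative bins")
    return float(ok.mean())


def call_roh(bins: pd.DataFrame, genome_avg: float, params: ROHParams = ROHParams()) -> list[ROHInterval]:
    """Scan bins chromosome by chromosome and emit disjoint ROH intervals."""
    if genome_avg <= 0:
        raise ValueError("genome_avg must be positive")
    seed_thr = params.seed_factor * genome_avg
    ceil_thr = params.bin_ceiling_factor * genome_avg
    mean_thr = params.run_mean_factor * genome_avg
    out: list[ROHInterval] = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        sub = sub.sort_values("bin_index")
        snp = sub["snp_count"].to_numpy()
        nodata = sub["no_data"].to_numpy()
        start_bp = sub["start"].to_numpy()
        end_bp = sub["end"].to_numpy()
        n = len(snp)
        i = 0
        while i < n:
            if nodata[i] or snp[i] >= seed_thr:
                i += 1
                continue
            # grow: j = last low bin reached; probe forward for the next one
            j = i
            total = float(snp[i])
            n_data = 1
            k = i + 1
            probe_total = total
            probe_data = n_data
            gap = 0
            while k < n:
                if nodata[k]:
                    gap += 1
                    if gap > params.max_nodata_gap:
                        break
                    k += 1
                    continue
                if snp[k] > ceil_thr:
                    break
                gap = 0
                probe_total += snp[k]
                probe_data += 1
                if snp[k] < seed_thr:
                    # checkpoint: accept the stretch up to k if mean still low
                    if probe_total / probe_data <= mean_thr:
                        j, total, n_data = k, probe_total, probe_data
                        k += 1
                        continue
                    break
                k += 1
            n_bins = j - i + 1
            length = int(end_bp[j] - start_bp[i])
            if n_bins >= params.min_bins and length >= params.effective_min_length:
                out.append(
                    ROHInterval(
                        chrom=str(chrom),
                        start=int(start_bp[i]),
                        end=int(end_bp[j]),
                        n_bins=n_bins,
                        mean_snp_per_bin=total / n_data,
                    )
                )
                i = j + 1
            else:
                i += 1
    return out


def summarize_roh(
    intervals: list[ROHInterval],
    table: PileupTable,
    assayed_length: int,
    min_alt_reads: int = 2,
    min_alt_fraction: float = 0.2,
    dropout_correction: bool = True,
) -> ROHSummary:
    """Diversity inside/outside the ROH union, F_ROH against assayed length.

    ``intervals`` must be pairwise disjoint; sites are assigned by their
    0-based position. pi_in_raw / pi_out_raw are heterozygous-site fractions
    over covered sites; pi_in / pi_out additionally divide out the het-call
    sensitivity of each covered site (allele dropout at modest depth — see
    ``seqdiversity.het_call_sensitivity``), making them consistent
    estimators of per-site heterozygosity. All rates are 0 when no site
    falls on that side.
    """
    if assayed_length <= 0:
        raise ValueError("assayed_length must be positive")
    ivs = sorted(intervals, key=lambda r: (r.chrom, r.start))
    for a, b in zip(ivs, ivs[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError("ROH intervals must be disjoint")
    het = het_mask(table, min_alt_reads, min_alt_fraction)
    inside = np.zeros(len(table), dtype=bool)
    for chrom in {r.chrom for r in ivs}:
        sel = table.chrom == chrom
        pos0 = table.pos[sel] - 1
        starts = np.array([r.start for r in ivs if r.chrom == chrom])
        ends = np.array([r.end for r in ivs if r.chrom == chrom])
        hit = np.searchsorted(starts, pos0, side="right") - 1
        ok = (hit >= 0) & (pos0 < ends[np.clip(hit, 0, None)])
        inside[np.flatnonzero(sel)[ok]] = True
    n_in = int(inside.sum())
    n_out = int(len(table) - n_in)
    pi_in_raw = float(het[inside].sum() / n_in) if n_in else 0.0
    pi_out_raw = float(het[~inside].sum() / n_out) if n_out else 0.0
    if dropout_correction:
        sens = het_call_sensitivity(table.depth, min_alt_reads, min_alt_fraction)
        eff_in = float(sens[inside].sum())
        eff_out = float(sens[~inside].sum())
        pi_in = float(het[inside].sum() / eff_in) if eff_in > 0 else 0.0
        pi_out = float(het[~inside].sum() / eff_out) if eff_out > 0 else 0.0
    else:
        pi_in, pi_out = pi_in_raw, pi_out_raw
    cum = int(sum(r.end - r.start for r in ivs))
    return ROHSummary(
        n_roh=len(ivs),
        cum_length=cum,
        f_roh=cum / assayed_length,
        pi_in=pi_in,
        pi_out=pi_out,
        pi_in_raw=pi_in_raw,
        pi_out_raw=pi_out_raw,
    )
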