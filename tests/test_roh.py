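"""ROH binning, calling (vs brute-force oracle) and diversity summaries."""

import numpy as np
import pandas as pd
import pytest

from herdscan.roh import (
    ROHInterval,
    ROHParams,
    bin_counts,
    call_roh,
    genome_average,
    summarize_roh,
)
from herdscan.seqdiversity import filter_sites, het_mask
from herdscan.simdata import simulate_pileup_genome

from conftest import make_table
from roh_oracle import oracle_call_roh

BIN = 10_000


def bins_frame(snp, nodata=None, chrom="chr1"):
    n = len(snp)
    nodata = np.zeros(n, bool) if nodata is None else np.asarray(nodata, bool)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "bin_index": np.arange(n),
            "start": np.arange(n) * BIN,
            "end": (np.arange(n) + 1) * BIN,
            "snp_count": np.asarray(snp),
            "covered_sites": np.where(nodata, 0, 9000),
            "no_data": nodata,
        }
    )


def random_bin_genome(rng, n_bins):
    """Bin table with background diversity, planted low runs of assorted
    lengths (some below the length rule), occasional spikes and no-data
    stretches — the adversarial terrain for the caller."""
    avg = 16.0
    snp = rng.poisson(avg, n_bins)
    nodata = np.zeros(n_bins, bool)
    i = 0
    while i < n_bins - 5:
        roll = rng.random()
        if roll < 0.05:  # low tract
            L = int(rng.integers(5, 45))
            snp[i : i + L] = rng.poisson(0.5, min(L, n_bins - i))
            i += L + int(rng.integers(1, 10))
        elif roll < 0.08:  # no-data stretch
            L = int(rng.integers(1, 5))
            nodata[i : i + L] = True
            i += L
        elif roll < 0.11:  # spike
            snp[i] = int(avg * rng.uniform(2.2, 4.0))
            i += 1
        else:
            i += 1
    return snp, nodata


class TestBinCounts:
    def test_tiling_contract(self, small_pileup):
        table, _ = small_pileup
        bins = bin_counts(filter_sites(table))
        assert (bins.start % BIN == 0).all()
        assert (bins.end - bins.start == BIN).all()
        assert bins.bin_index.is_monotonic_increasing

    def test_empty_region_flagged(self):
        # sites only in the 3rd bin: bins 0-1 exist, carry no data
        tbl = make_table([(10, 0, 0, 0)] * 50, start_pos=25_000)
        bins = bin_counts(tbl)
        assert len(bins) == 3
        assert bins.no_data[:2].all()
        assert (bins.snp_count[:2] == 0).all()

    def test_counts_track_generator(self, small_pileup):
        table, _ = small_pileup
        f = filter_sites(table)
        bins = bin_counts(f)
        ok = bins[~bins.no_data]
        expected = het_mask(f).mean() * ok.covered_sites.mean()
        assert ok.snp_count.mean() == pytest.approx(expected, rel=0.15)


class TestCallROH:
    def test_uniform_bins_yield_nothing(self):
        bins = bins_frame(np.full(300, 16))
        assert call_roh(bins, 16.0) == []

    def test_rejects_nonpositive_average(self):
        with pytest.raises(ValueError):
            call_roh(bins_frame([1, 2]), 0.0)

    def test_planted_tract_recovered_with_tight_boundaries(self):
        rng = np.random.default_rng(8)
        snp = rng.poisson(20.0, 300)
        snp[100:130] = 0  # 30-bin homozygous tract
        bins = bins_frame(snp)
        calls = call_roh(bins, genome_average(bins))
        assert len(calls) == 1
        (iv,) = calls
        assert abs(iv.start - 100 * BIN) <= BIN
        assert abs(iv.end - 130 * BIN) <= BIN
        assert iv.n_bins >= 28

    def test_short_tract_rejected(self):
        rng = np.random.default_rng(9)
        snp = rng.poisson(20.0, 300)
        snp[100:110] = 0  # 10 bins < min_bins
        bins = bins_frame(snp)
        assert call_roh(bins, genome_average(bins)) == []

    def test_matches_bruteforce_on_random_genomes(self):
        params = ROHParams()
        rng = np.random.default_rng(123)
        for _ in range(10):
            snp, nodata = random_bin_genome(rng, int(rng.integers(150, 600)))
            bins = bins_frame(snp, nodata)
            avg = genome_average(bins)
            got = [(c.start, c.end, c.n_bins) for c in call_roh(bins, avg, params)]
            want = oracle_call_roh(
                snp, nodata, bins.start.to_numpy(), bins.end.to_numpy(), avg, params
            )
            assert got == want

    def test_seed_factor_monotonicity(self):
        """A stricter seed threshold can only lose ROH calls."""
        rng = np.random.default_rng(77)
        snp, nodata = random_bin_genome(rng, 500)
        bins = bins_frame(snp, nodata)
        avg = genome_average(bins)
        counts = []
        for sf in (0.05, 0.15, 0.25):
            p = ROHParams(seed_factor=sf)
            counts.append(len(call_roh(bins, avg, p)))
        assert counts == sorted(counts)

    def test_min_bins_monotonicity(self):
        rng = np.random.default_rng(78)
        snp, nodata = random_bin_genome(rng, 500)
        bins = bins_frame(snp, nodata)
        avg = genome_average(bins)
        lengths = []
        for mb in (10, 20, 40):
            p = ROHParams(min_bins=mb)
            lengths.append(sum(c.end - c.start for c in call_roh(bins, avg, p)))
        assert lengths == sorted(lengths, reverse=True)

    def test_nodata_gap_rules(self):
        snp = np.concatenate([np.full(25, 0), np.full(100, 16)])
        # 2 no-data bins inside the tract: run survives across them
        nodata = np.zeros(125, bool)
        nodata[10:12] = True
        bins = bins_frame(snp, nodata)
        calls = call_roh(bins, 16.0)
        assert len(calls) == 1 and calls[0].end == 25 * BIN
        # 3 consecutive no-data bins break it into halves too short to emit
        nodata3 = np.zeros(125, bool)
        nodata3[10:13] = True
        assert call_roh(bins_frame(snp, nodata3), 16.0) == []


class TestSummarize:
    def test_no_intervals_means_genome_rate(self, small_pileup):
        table, _ = small_pileup
        f = filter_sites(table)
        summ = summarize_roh([], f, assayed_length=1_000_000)
        assert summ.f_roh == 0 and summ.n_roh == 0
        assert summ.pi_out_raw == pytest.approx(het_mask(f).mean())

    def test_planted_tract_partitions_diversity(self, small_pileup):
        table, truth = small_pileup
        f = filter_sites(table)
        intervals = [
            ROHInterval(c, s, e, (e - s) // BIN, 0.0) for c, s, e in truth.planted_roh
        ]
        summ = summarize_roh(intervals, f, assayed_length=1_000_000)
        assert summ.pi_in < 0.1 * truth.theta_true
        assert summ.pi_out == pytest.approx(truth.theta_true, rel=0.15)
        assert summ.f_roh == pytest.approx(0.3)

    def test_pi_in_local_to_intervals(self, small_pileup):
        """Perturbing sites outside the ROH union cannot change pi_in."""
        table, truth = small_pileup
        f = filter_sites(table)
        intervals = [
            ROHInterval(c, s, e, (e - s) // BIN, 0.0) for c, s, e in truth.planted_roh
        ]
        base = summarize_roh(intervals, f, 1_000_000)
        outside = (f.pos - 1 < 300_000) | (f.pos - 1 >= 600_000)
        mod = f.counts.copy()
        mod[np.flatnonzero(outside)[:500]] = (5, 5, 0, 0)
        from herdscan.seqdiversity import PileupTable

        f2 = PileupTable(f.chrom, f.pos, mod)
        assert summarize_roh(intervals, f2, 1_000_000).pi_in == base.pi_in

    def test_disjointness_enforced(self, small_pileup):
        table, _ = small_pileup
        overlapping = [
            ROHInterval("chr1", 0, 50_000, 5, 0.0),
            ROHInterval("chr1", 40_000, 90_000, 5, 0.0),
        ]
        with pytest.raises(ValueError, match="disjoint"):
            summarize_roh(overlapping, filter_sites(table), 1_000_000)

    def test_zero_assayed_length_rejected(self, small_pileup):
        table, _ = small_pileup
        with pytest.raises(ValueError):
            summarize_roh([], filter_sites(table), 0)
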