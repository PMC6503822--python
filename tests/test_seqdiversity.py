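"""Site filtering, het calling, windowed diversity and theta/epsilon ML."""

import math

import numpy as np
import pytest

from herdscan.seqdiversity import (
    PileupSite,
    PileupTable,
    SiteFilterConfig,
    call_het,
    estimate_theta_epsilon,
    filter_sites,
    het_call_sensitivity,
    het_mask,
    pileup_loglik,
    window_heterozygosity,
)
from herdscan.simdata import simulate_pileup_genome

from conftest import make_table


class TestFilterSites:
    def test_depth_bounds_inclusive(self):
        tbl = make_table([(3, 0, 0, 0), (4, 0, 0, 0), (30, 0, 0, 0), (28, 2, 1, 0)])
        kept = filter_sites(tbl, SiteFilterConfig())
        assert list(kept.depth) == [4, 30]
        assert list(kept.pos) == [2, 3]

    def test_empty_input(self):
        assert len(filter_sites(PileupTable.from_sites([]))) == 0

    def test_idempotent(self, small_pileup):
        table, _ = small_pileup
        once = filter_sites(table)
        twice = filter_sites(once)
        assert np.array_equal(once.counts, twice.counts)

    def test_rejects_unsorted(self):
        tbl = make_table([(10, 0, 0, 0), (10, 0, 0, 0)])
        tbl.pos = tbl.pos[::-1].copy()
        with pytest.raises(ValueError, match="sorted"):
            filter_sites(tbl)


class TestCallHet:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((8, 2, 0, 0), True),   # 2 reads, fraction 0.2: both thresholds met
            ((10, 0, 0, 0), False),  # no minor allele
            ((9, 1, 0, 0), False),  # 1 read < 2
            ((5, 5, 0, 0), True),
            ((24, 6, 0, 0), True),  # fraction exactly 0.2 at depth 30
            ((25, 5, 0, 0), False),  # fraction 1/6 < 0.2 under the joint rule
        ],
    )
    def test_threshold_rule(self, counts, expected):
        site = PileupSite("chr1", 1, sum(counts), counts)
        assert call_het(site) is expected

    def test_any_mode_accepts_either_threshold(self):
        # 5 of 30 reads: enough reads, too small a fraction
        site = PileupSite("chr1", 1, 30, (25, 5, 0, 0))
        assert call_het(site, require="any") is True
        assert call_het(site, require="all") is False

    def test_mask_matches_scalar(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 12, size=(200, 4))
        tbl = make_table(counts)
        mask = het_mask(tbl)
        for i, site in enumerate(tbl.sites()):
            assert mask[i] == call_het(site)


class TestHetCallSensitivity:
    def test_known_depths(self):
        # min(X, d-X) >= 2 with X ~ Bin(d, 1/2): d=4 -> P(X=2) = 6/16
        s = het_call_sensitivity(np.array([4, 10]))
        assert s[0] == pytest.approx(6 / 16)
        assert s[1] == pytest.approx(1.0 - 22 / 1024)

    def test_bounded_and_increasing_at_scale(self):
        s = het_call_sensitivity(np.arange(4, 31))
        assert np.all((s >= 0) & (s <= 1))
        assert s[-1] > 0.99


class TestWindows:
    def test_rate_arithmetic(self):
        # one window holding 9,000 covered sites of which 18 are het
        counts = [(5, 5, 0, 0)] * 18 + [(10, 0, 0, 0)] * 8982
        wins = window_heterozygosity(make_table(counts), window=10_000)
        assert len(wins) == 1
        assert wins.loc[0, "n_covered"] == 9000
        assert wins.loc[0, "het_rate"] == pytest.approx(2.0e-3)
        assert not wins.loc[0, "flagged"]

    def test_all_hom_genome_has_zero_rates(self):
        table, _ = simulate_pileup_genome(200_000, theta=0.0, epsilon=0.0, mean_depth=10, seed=5)
        wins = window_heterozygosity(filter_sites(table))
        assert (wins.het_rate == 0).all()

    def test_windows_tile_from_zero(self):
        tbl = make_table([(10, 0, 0, 0)], start_pos=10_000)  # 1-based 10000 -> window 0
        wins = window_heterozygosity(tbl, window=10_000)
        assert wins.loc[0, "start"] == 0 and wins.loc[0, "end"] == 10_000

    def test_sparse_window_flagged(self):
        tbl = make_table([(10, 0, 0, 0)] * 100)
        wins = window_heterozygosity(tbl, window=10_000, min_covered_fraction=0.2)
        assert wins.loc[0, "flagged"].item() is True

    def test_aggregate_equals_totals(self, small_pileup):
        """Conservation: pooled window counts reproduce the genome-wide rate."""
        table, _ = small_pileup
        f = filter_sites(table)
        wins = window_heterozygosity(f)
        assert wins.n_het.sum() == het_mask(f).sum()
        assert wins.n_covered.sum() == len(f)

    def test_mean_rate_tracks_theta(self):
        theta = 0.002
        table, _ = simulate_pileup_genome(2_000_000, theta, 0.0, 10, seed=11)
        f = filter_sites(table)
        wins = window_heterozygosity(f)
        ok = wins[~wins.flagged]
        # called-het rate = theta x mean call sensitivity (allele dropout)
        expect = theta * het_call_sensitivity(f.depth).mean()
        sd = math.sqrt(expect * (1 - expect) / wins.n_covered.sum())
        assert abs(ok.n_het.sum() / ok.n_covered.sum() - expect) < 3 * sd


def brute_force_loglik(table, theta, eps):
    """Direct per-site summation of the two-component mixture likelihood."""
    h = theta / (1 + theta)
    total = 0.0
    for site in table.sites():
        d = site.depth
        counts = sorted(site.base_counts, reverse=True)
        coef = math.factorial(d)
        for c in counts:
            coef //= math.factorial(c)
        p_hom = (1 - eps) ** counts[0] * (eps / 3) ** (d - counts[0])
        pa = (1 - eps) / 2 + eps / 6
        p_het = pa ** (counts[0] + counts[1]) * (eps / 3) ** (counts[2] + counts[3])
        total += math.log(coef * ((1 - h) * p_hom + h * p_het))
    return total


class TestThetaEpsilon:
    def test_loglik_matches_direct_summation(self):
        rng = np.random.default_rng(2)
        counts = rng.multinomial(12, [0.7, 0.2, 0.06, 0.04], size=50)
        tbl = make_table(counts)
        for theta, eps in [(1e-3, 1e-3), (5e-3, 1e-2), (0.05, 2e-3)]:
            assert pileup_loglik(tbl, theta, eps) == pytest.approx(
                brute_force_loglik(tbl, theta, eps), abs=1e-9
            )

    def test_monoallelic_input_drives_both_to_zero(self):
        tbl = make_table([(10, 0, 0, 0)] * 2000)
        est = estimate_theta_epsilon(tbl)
        assert est.theta < 1e-6 and est.epsilon < 1e-6
        assert "at_bound" in est.flags

    def test_low_confidence_flag(self):
        tbl = make_table([(10, 0, 0, 0)] * 50)
        assert "low_confidence" in estimate_theta_epsilon(tbl).flags

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            estimate_theta_epsilon(PileupTable.from_sites([]))

    def test_matches_het_fraction_without_errors(self):
        """At eps=0 the ML theta equals the plain observed het fraction,
        up to the small allele-dropout correction (< 2% at depth ~10)."""
        table, _ = simulate_pileup_genome(1_000_000, 0.005, 0.0, 10, seed=21)
        f = filter_sites(table)
        est = estimate_theta_epsilon(f)
        plain = (np.partition(f.counts, 2, axis=1)[:, 2] > 0).mean()
        assert est.theta == pytest.approx(plain, rel=0.02)

    def test_theta_monotone_in_het_fraction(self):
        """Adding het-like sites to a pileup never lowers the estimate."""
        base = [(10, 0, 0, 0)] * 3000
        prev = -1.0
        for n_het in (3, 9, 30):
            tbl = make_table([(5, 5, 0, 0)] * n_het + base)
            est = estimate_theta_epsilon(tbl)
            assert est.theta >= prev
            prev = est.theta
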