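"""Per-site diversity from read pileups.

The observations are per-site base counts (A, C, G, T) from a single diploid
genome. Three things are computed here:

* a depth filter selecting well-covered sites (default 4x-30x, inclusive);
* windowed heterozygosity: the fraction of covered sites that look
  heterozygous in non-overlapping 10-kb windows;
* joint maximum-likelihood estimation of the per-site heterozygosity theta
  and the per-read sequencing-error rate epsilon, from the base counts of
  all filtered sites under a two-component (hom/het) mixture model.

Under the infinite-allele approximation a site is heterozygous with
probability h = theta/(1+theta) (~ theta for small theta), so the fitted
theta is directly comparable to the windowed heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

BASES = "ACGT"


class PileupSite(NamedTuple):
    """One genomic position: 1-based ``pos`` and read counts per base."""

    chrom: str
    pos: int
    depth: int
    base_counts: tuple[int, int, int, int]


@dataclass
class PileupTable:
    """Columnar pileup: parallel arrays over sites, sorted by (chrom, pos).

    ``pos`` is 1-based (pileup convention); interval arithmetic elsewhere in
    the package converts to 0-based half-open coordinates.
    """

    chrom: np.ndarray  # dtype object/str, shape (n,)
    pos: np.ndarray  # int64, 1-based, shape (n,)
    counts: np.ndarray  # int64, shape (n, 4), columns A C G T

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        if self.chrom.dtype == object:
            self.chrom = self.chrom.astype(str)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.dtype.kind != "i":
            self.counts = self.counts.astype(np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (n_sites, 4)")
        if len(self.chrom) != len(self.pos) or len(self.pos) != len(self.counts):
            raise ValueError("chrom, pos and counts must have equal length")
        if len(self.pos) and self.pos.min() < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError("negative base count")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def is_sorted(self) -> bool:
        if len(self) < 2:
            return True
        same = self.chrom[1:] == self.chrom[:-1]
        if np.any(same & (np.diff(self.pos) <= 0)):
            return False
        # chromosome blocks must be contiguous
        block_names = [self.chrom[0], *self.chrom[1:][~same]]
        return len(block_names) == len(set(block_names))

    def take(self, idx: np.ndarray) -> "PileupTable":
        return PileupTable(self.chrom[idx], self.pos[idx], self.counts[idx])

    def sites(self) -> Iterable[PileupSite]:
        for c, p, row in zip(self.chrom, self.pos, self.counts):
            yield PileupSite(str(c), int(p), int(row.sum()), tuple(int(x) for x in row))

    @classmethod
    def from_sites(cls, sites: Sequence[PileupSite]) -> "PileupTable":
        if not sites:
            return cls(np.empty(0, dtype="U1"), np.empty(0, np.int64), np.empty((0, 4), np.int64))
        return cls(
            np.array([s.chrom for s in sites]),
            np.array([s.pos for s in sites], dtype=np.int64),
            np.array([s.base_counts for s in sites], dtype=np.int64),
        )


@dataclass(frozen=True)
class SiteFilterConfig:
    """Depth window for usable sites; bounds inclusive."""

    min_depth: int = 4
    max_depth: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.min_depth <= self.max_depth):
            raise ValueError("require 0 < min_depth <= max_depth")


@dataclass
class ThetaEstimate:
    theta: float
    epsilon: float
    loglik: float
    n_sites: int
    flags: list[str] = field(default_factory=list)


def filter_sites(table: PileupTable, cfg: SiteFilterConfig = SiteFilterConfig()) -> PileupTable:
    """Keep sites with min_depth <= depth <= max_depth; order preserved.

    Input must be sorted by (chrom, pos); the operation is idempotent.
    """
    if not table.is_sorted():
        raise ValueError("pileup sites must be sorted by (chrom, pos)")
    d = table.depth
    return table.take((d >= cfg.min_depth) & (d <= cfg.max_depth))


def call_het(
    site: PileupSite,
    min_alt_reads: int = 2,
    min_alt_fraction: float = 0.2,
    require: str = "all",
) -> bool:
    """Heterozygous when the second-most-frequent base carries real support.

    The minor base counts as support when covered by at least
    ``min_alt_reads`` reads and by at least ``min_alt_fraction`` of the
    site's reads (the allele-support thresholds of common short-read
    callers); ``require="any"`` accepts either threshold instead. At modest
    depth the count rule dominates and misses true hets whose minor allele
    was sampled by < 2 reads; ``het_call_sensitivity`` quantifies that
    dropout so downstream rates can be corrected.
    """
    counts = np.sort(np.asarray(site.base_counts))[::-1]
    depth = counts.sum()
    if depth == 0 or counts[1] == 0:
        return False
    by_count = counts[1] >= min_alt_reads
    by_frac = counts[1] >= min_alt_fraction * depth
    return bool(by_count and by_frac) if require == "all" else bool(by_count or by_frac)


def het_mask(
    table: PileupTable,
    min_alt_reads: int = 2,
    min_alt_fraction: float = 0.2,
    require: str = "all",
) -> np.ndarray:
    """Vectorised ``call_het`` over a table."""
    if len(table) == 0:
        return np.zeros(0, dtype=bool)
    second = np.partition(table.counts, 2, axis=1)[:, 2]
    depth = table.depth
    by_count = second >= min_alt_reads
    by_frac = second >= min_alt_fraction * depth
    ok = (by_count & by_frac) if require == "all" else (by_count | by_frac)
    return ok & (second > 0) & (depth > 0)


def het_call_sensitivity(
    depths: np.ndarray,
    min_alt_reads: int = 2,
    min_alt_fraction: float = 0.2,
    require: str = "all",
) -> np.ndarray:
    """P(het is called | het site, depth) under binomial allele sampling.

    At a true het site each read carries either allele with probability 1/2
    (errors neglected), so the minor-base count is min(X, d-X) with
    X ~ Binomial(d, 1/2); the call fires when that count reaches the
    support threshold implied by the rule at depth d. Raw heterozygous-site
    fractions underestimate per-site heterozygosity by exactly this allele
    dropout; dividing the het count by the summed sensitivities of the
    covered sites removes the bias without any free parameter.
    """
    d = np.asarray(depths, dtype=np.int64)
    uniq, inv = np.unique(d, return_inverse=True)
    s = np.empty(len(uniq))
    for k, dd in enumerate(uniq):
        thr_frac = int(np.ceil(min_alt_fraction * dd - 1e-9))
        if require == "all":
            thr = max(min_alt_reads, thr_frac, 1)
        else:
            thr = max(min(min_alt_reads, thr_frac), 1)
        if 2 * thr > dd:
            s[k] = 0.0
        else:
            s[k] = stats.binom.cdf(dd - thr, dd, 0.5) - stats.binom.cdf(thr - 1, dd, 0.5)
    return s[inv]


def window_heterozygosity(
    table: PileupTable,
    window: int = 10_000,
    min_covered_fraction: float = 0.2,
    min_alt_reads: int = 2,
    min_alt_fraction: float = 0.2,
) -> pd.DataFrame:
    """Heterozygosity in non-overlapping windows tiled from coordinate 0.

    Returns one row per (chrom, window) that contains at least one covered
    site, with columns chrom, start, end (0-based half-open), n_covered,
    n_het, het_rate and ``flagged`` (True when the covered fraction of the
    window falls below ``min_covered_fraction``; flagged windows should be
    excluded from genome-wide averages).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not table.is_sorted():
        raise ValueError("pileup sites must be sorted by (chrom, pos)")
    if len(table) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_covered", "n_het", "het_rate", "flagged"]
        )
    widx = (table.pos - 1) // window
    het = het_mask(table, min_alt_reads, min_alt_fraction)
    df = pd.DataFrame({"chrom": table.chrom, "widx": widx, "het": het})
    g = df.groupby(["chrom", "widx"], sort=True)
    out = g["het"].agg(n_het="sum", n_covered="size").reset_index()
    out["start"] = out["widx"] * window
    out["end"] = out["start"] + window
    out["het_rate"] = out["n_het"] / out["n_covered"]
    out["flagged"] = out["n_covered"] < min_covered_fraction * window
    return out[["chrom", "start", "end", "n_covered", "n_het", "het_rate", "flagged"]]


# --- theta/epsilon maximum likelihood ---------------------------------------
#
# Per site, with sorted base counts n1 >= n2 >= n3 >= n4 and depth d:
#   hom: the true base is the major base; a read errs with prob eps,
#        uniformly to the 3 other bases
#        -> multinomial(p_major = 1-eps, p_other = eps/3 each)
#   het: the two true alleles are the two most frequent bases; a read picks
#        either allele with prob 1/2, then the same error process
#        -> p_allele = (1-eps)/2 + eps/6 (each of 2), p_other = eps/3 (each of 2)
# Site likelihood is the mixture (1-h) P(hom) + h P(het), h = theta/(1+theta).
# Sites with identical sorted counts are aggregated; the log-likelihood of a
# genome reduces to a weighted sum over a few thousand distinct count shapes.


def _sorted_count_classes(table: PileupTable) -> tuple[np.ndarray, np.ndarray]:
    srt = np.sort(table.counts, axis=1)[:, ::-1]
    uniq, mult = np.unique(srt, axis=0, return_counts=True)
    return uniq, mult


def _class_loglik(uniq: np.ndarray, theta: float, eps: float) -> np.ndarray:
    """Log-likelihood of each sorted-count class under the mixture."""
    eps = max(eps, 1e-12)
    n1 = uniq[:, 0].astype(float)
    n2 = uniq[:, 1].astype(float)
    rest = uniq[:, 2] + uniq[:, 3]
    d = uniq.sum(axis=1).astype(float)
    logcoef = gammaln(d + 1) - gammaln(uniq + 1.0).sum(axis=1)
    log_hom = n1 * np.log1p(-eps) + (d - n1) * np.log(eps / 3.0)
    p_allele = (1.0 - eps) / 2.0 + eps / 6.0
    log_het = (n1 + n2) * np.log(p_allele) + rest * np.log(eps / 3.0)
    h = theta / (1.0 + theta)
    if h <= 0.0:
        mix = log_hom
    elif h >= 1.0:
        mix = log_het
    else:
        mix = logsumexp(
            np.stack([log_hom + np.log1p(-h), log_het + np.log(h)]), axis=0
        )
    return logcoef + mix


def pileup_loglik(table: PileupTable, theta: float, eps: float) -> float:
    """Total log-likelihood of a filtered pileup at fixed (theta, eps)."""
    if len(table) == 0:
        raise ValueError("empty pileup")
    uniq, mult = _sorted_count_classes(table)
    return float(np.dot(mult, _class_loglik(uniq, theta, eps)))


_THETA_STARTS = (1e-4, 1e-3, 1e-2)
_EPS_STARTS = (1e-3, 1e-2)
_THETA_BOUNDS = (1e-9, 0.5)
_EPS_BOUNDS = (1e-9, 0.49)


def estimate_theta_epsilon(table: PileupTable, min_sites: int = 1000) -> ThetaEstimate:
    """Co-estimate theta and epsilon by bounded ML over the site mixture.

    Optimises in log-parameter space from a small multistart grid; mixture
    likelihoods can be flat near the boundary, so every start is polished and
    the best kept. Flags: ``low_confidence`` below ``min_sites`` sites,
    ``at_bound`` when the optimum sits on the box.
    """
    if len(table) == 0 or int(table.depth.sum()) == 0:
        raise ValueError("cannot estimate theta/epsilon from zero-depth input")
    uniq, mult = _sorted_count_classes(table)

    def nll(x: np.ndarray) -> float:
        th, ep = np.exp(x)
        return -float(np.dot(mult, _class_loglik(uniq, th, ep)))

    lb = np.log([_THETA_BOUNDS[0], _EPS_BOUNDS[0]])
    ub = np.log([_THETA_BOUNDS[1], _EPS_BOUNDS[1]])
    best = None
    for t0 in _THETA_STARTS:
        for e0 in _EPS_STARTS:
            res = minimize(
                nll,
                np.log([t0, e0]),
                method="L-BFGS-B",
                bounds=list(zip(lb, ub)),
                options={"ftol": 1e-12, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun - 1e-8:
                best = res
    theta, eps = np.exp(best.x)
    flags = []
    if len(table) < min_sites:
        flags.append("low_confidence")
    if np.any(np.isclose(best.x, lb, atol=1e-6)) or np.any(np.isclose(best.x, ub, atol=1e-6)):
        flags.append("at_bound")
    return ThetaEstimate(
        theta=float(theta),
        epsilon=float(eps),
        loglik=-float(best.fun),
        n_sites=int(len(table)),
        flags=flags,
    )
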