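"""Genotype-matrix QC and LD pruning.

Diploid genotypes are stored as alternate-allele dosages {0, 1, 2} with -1
for missing, samples x variants. QC applies, in fixed order, the standard
array-data thresholds: drop samples with >10% missing calls, then variants
missing in >5% of the retained samples, then variants with minor allele
frequency below 1%. LD is measured as the squared Pearson correlation of
dosages over pairwise-complete samples (composite, genotype-based r^2 -- no
phasing required), and pruning is greedy within sliding SNP windows until no
retained within-window pair exceeds the r^2 ceiling (default 0.10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix with variant coordinates."""

    samples: list[str]
    chrom: np.ndarray  # (m,) object
    pos: np.ndarray  # (m,) int64, 1-based
    ref: np.ndarray  # (m,) object
    alt: np.ndarray  # (m,) object
    calls: np.ndarray  # (n_samples, m) int8 in {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.pos)):
            raise ValueError("calls must be shaped (n_samples, n_variants)")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype calls restricted to {0,1,2,missing}")
        same = self.chrom[1:] == self.chrom[:-1]
        if np.any(same & (np.diff(self.pos) <= 0)):
            raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def dosage(self) -> np.ndarray:
        """Float dosage matrix with NaN for missing calls."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples), self.chrom[idx], self.pos[idx], self.ref[idx],
            self.alt[idx], self.calls[:, idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        samples = [self.samples[i] for i in np.flatnonzero(np.asarray(idx))] \
            if np.asarray(idx).dtype == bool else [self.samples[i] for i in idx]
        return GenotypeMatrix(
            samples, self.chrom, self.pos, self.ref, self.alt,
            self.calls[np.asarray(idx)],
        )

    def sample_missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def variant_missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls."""
        ok = self.calls != MISSING
        alt = np.where(ok, self.calls, 0).sum(axis=0)
        n_hap = 2 * ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_hap > 0, alt / np.maximum(n_hap, 1), np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)


def combine_panels(panels: dict[str, GenotypeMatrix]) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Stack panels sharing the same variants; returns matrix + sample->pop map."""
    mats = list(panels.values())
    first = mats[0]
    for m in mats[1:]:
        if not (np.array_equal(m.pos, first.pos) and np.array_equal(m.chrom, first.chrom)):
            raise ValueError("panels must share identical variants")
    samples, groups, blocks = [], {}, []
    for pop, m in panels.items():
        for s in m.samples:
            name = f"{pop}:{s}" if s in groups else s
            samples.append(name)
            groups[name] = pop
        blocks.append(m.calls)
    return (
        GenotypeMatrix(samples, first.chrom, first.pos, first.ref, first.alt,
                       np.vstack(blocks)),
        groups,
    )


@dataclass(frozen=True)
class QCThresholds:
    max_sample_missing: float = 0.10
    max_variant_missing: float = 0.05
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        for v in (self.max_sample_missing, self.max_variant_missing, self.min_maf):
            if not 0.0 <= v <= 1.0:
                raise ValueError("QC thresholds must lie in [0, 1]")


@dataclass
class QCReport:
    n_samples_dropped: int = 0
    n_variants_missing_dropped: int = 0
    n_variants_maf_dropped: int = 0
    steps: list[str] = field(default_factory=list)


def qc_filter(g: GenotypeMatrix, t: QCThresholds = QCThresholds()) -> tuple[GenotypeMatrix, QCReport]:
    """Sample-missingness, then variant-missingness, then MAF — in that order.

    Variant statistics are recomputed on the retained samples, so the
    operation is idempotent. Raises if no sample survives.
    """
    rep = QCReport()
    keep_s = g.sample_missing_rate() <= t.max_sample_missing
    rep.n_samples_dropped = int((~keep_s).sum())
    rep.steps.append(f"samples dropped (missing > {t.max_sample_missing}): {rep.n_samples_dropped}")
    if not keep_s.any():
        raise ValueError("QC removed every sample")
    g = g.take_samples(keep_s)

    keep_v = g.variant_missing_rate() <= t.max_variant_missing
    rep.n_variants_missing_dropped = int((~keep_v).sum())
    rep.steps.append(
        f"variants dropped (missing > {t.max_variant_missing}): {rep.n_variants_missing_dropped}"
    )
    g = g.take_variants(keep_v)

    maf = g.maf()
    keep_m = ~(np.nan_to_num(maf, nan=-1.0) < t.min_maf)
    rep.n_variants_maf_dropped = int((~keep_m).sum())
    rep.steps.append(f"variants dropped (MAF < {t.min_maf}): {rep.n_variants_maf_dropped}")
    return g.take_variants(keep_m), rep


def pairwise_r2(g: GenotypeMatrix, i: int, j: int, min_pairs: int = 5) -> float:
    """Squared dosage correlation over samples non-missing at both variants.

    Returns NaN (flagged undefined) with fewer than ``min_pairs`` complete
    pairs or when either variant is monomorphic among the complete cases.
    """
    x = g.calls[:, i]
    y = g.calls[:, j]
    ok = (x != MISSING) & (y != MISSING)
    n = int(ok.sum())
    if n < min_pairs:
        return math.nan
    xf = x[ok].astype(float)
    yf = y[ok].astype(float)
    vx = xf.var()
    vy = yf.var()
    if vx == 0.0 or vy == 0.0:
        return math.nan
    cov = ((xf - xf.mean()) * (yf - yf.mean())).mean()
    return float(min(cov * cov / (vx * vy), 1.0))


def _window_r2_matrix(g: GenotypeMatrix, idx: np.ndarray, min_pairs: int = 5) -> np.ndarray:
    """Pairwise-complete r^2 matrix for the given variant indices."""
    X = g.calls[:, idx].astype(float)
    M = (g.calls[:, idx] != MISSING).astype(float)
    X = X * M  # zero out missing
    n = M.T @ M
    sx = X.T @ M
    sxx = (X * X).T @ M
    sxy = X.T @ X
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sx.T / n)
        var_i = sxx / n - (sx / n) ** 2
        r2 = cov**2 / (var_i * var_i.T)
    r2[n < min_pairs] = np.nan
    r2[~np.isfinite(r2)] = np.nan
    np.clip(r2, 0.0, 1.0, out=r2)
    return r2


def ld_prune(
    g: GenotypeMatrix,
    r2_max: float = 0.10,
    window_snps: int = 50,
    step_snps: int = 5,
) -> GenotypeMatrix:
    """Greedy windowed LD pruning (PLINK-style windows over SNP counts).

    Within each window the worst pair with r^2 > ``r2_max`` loses its
    lower-MAF member (tie: the later position is dropped); the window then
    advances by ``step_snps``. Windows never span chromosomes. Passes over
    the panel repeat until a full pass drops nothing, so windows are always
    evaluated on the *retained* SNP sequence and the post-condition — no
    retained within-window pair above the ceiling — holds in the output
    (exhaustively checkable on small panels).
    """
    keep = np.ones(g.n_variants, dtype=bool)
    maf = g.maf()
    changed = True
    while changed:
        changed = False
        for chrom in pd_unique(g.chrom):
            cidx = np.flatnonzero((g.chrom == chrom) & keep)
            for start in range(0, max(len(cidx) - 1, 1), step_snps):
                widx = cidx[start : start + window_snps]
                widx = widx[keep[widx]]
                if len(widx) < 2:
                    continue
                r2 = _window_r2_matrix(g, widx)
                np.fill_diagonal(r2, np.nan)
                active = np.ones(len(widx), dtype=bool)
                while True:
                    sub = np.where(np.outer(active, active), r2, np.nan)
                    if not np.any(sub > r2_max):
                        break
                    a, b = np.unravel_index(np.nanargmax(sub), sub.shape)
                    va, vb = widx[a], widx[b]
                    drop_local = _pick_drop(va, vb, a, b, maf, g.pos)
                    active[drop_local] = False
                    keep[widx[drop_local]] = False
                    changed = True
                if start + window_snps >= len(cidx):
                    break
    return g.take_variants(keep)


def _pick_drop(va: int, vb: int, a: int, b: int, maf: np.ndarray, pos: np.ndarray) -> int:
    if maf[va] < maf[vb]:
        return a
    if maf[vb] < maf[va]:
        return b
    return a if pos[va] > pos[vb] else b


def pd_unique(arr: np.ndarray) -> list:
    """Unique values in order of first appearance."""
    seen: dict = {}
    for v in arr:
        seen.setdefault(v, None)
    return list(seen)
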