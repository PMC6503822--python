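"""Three-population f3 admixture test with block-jackknife errors.

f3(C; A, B) estimates E[(c - a)(c - b)] over loci, where a, b, c are allele
frequencies in the two reference populations and the target. A significantly
negative value is evidence that C is admixed between populations related to
A and B. Because the target frequency c enters the product twice, its
sampling noise biases the naive product upward; the unbiased per-locus
statistic subtracts the target's binomial sampling term:

    D_i = (c_i - a_i)(c_i - b_i) - c_i (1 - c_i) / (n_i - 1)

with n_i the number of non-missing allele copies observed in the target at
locus i. Standard errors come from a delete-one-block jackknife over
contiguous blocks of SNPs in genome order (default 1,000 SNPs per block),
which is robust to local LD; the conventional significance rule declares
admixture when Z = f3 / SE < -3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genoqc import MISSING, GenotypeMatrix


@dataclass
class AlleleFreqTable:
    pops: list[str]
    chrom: np.ndarray  # (m,)
    pos: np.ndarray  # (m,)
    freq: np.ndarray  # (n_pops, m) alt-allele frequency
    n_hap: np.ndarray  # (n_pops, m) non-missing allele copies
    n_dropped: int = 0

    def pop_index(self, pop: str) -> int:
        try:
            return self.pops.index(pop)
        except ValueError as exc:
            raise KeyError(f"unknown population {pop!r}") from exc


@dataclass
class F3Result:
    target: str
    ref_a: str
    ref_b: str
    f3: float
    se: float
    z: float
    n_snps: int
    n_blocks: int
    significant: bool
    flags: list[str]


def allele_freqs(g: GenotypeMatrix, groups: dict[str, str]) -> AlleleFreqTable:
    """Per-population alternate-allele frequencies.

    ``groups`` maps sample id -> population label. Variants with zero
    non-missing calls in any population are dropped (counted in
    ``n_dropped``). Raises if a population has no samples at all.
    """
    pops = sorted(set(groups.values()))
    idx = {p: [i for i, s in enumerate(g.samples) if groups.get(s) == p] for p in pops}
    for p, rows in idx.items():
        if not rows:
            raise ValueError(f"population {p!r} has no samples")
    freq = np.empty((len(pops), g.n_variants))
    n_hap = np.empty((len(pops), g.n_variants), dtype=np.int64)
    for k, p in enumerate(pops):
        calls = g.calls[idx[p]]
        ok = calls != MISSING
        n_hap[k] = 2 * ok.sum(axis=0)
        alt = np.where(ok, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq[k] = np.where(n_hap[k] > 0, alt / np.maximum(n_hap[k], 1), np.nan)
    keep = (n_hap > 0).all(axis=0)
    return AlleleFreqTable(
        pops=pops,
        chrom=g.chrom[keep],
        pos=g.pos[keep],
        freq=freq[:, keep],
        n_hap=n_hap[:, keep],
        n_dropped=int((~keep).sum()),
    )


def _block_jackknife(values: np.ndarray, block_size: int) -> tuple[float, float, int]:
    """Mean of ``values`` and its delete-one-block jackknife SE.

    Blocks are contiguous runs of ``block_size`` entries in input order; the
    final block may be shorter, so the weighted (delete-m_j) jackknife
    variance is used. Returns (mean, se, n_blocks).
    """
    n = len(values)
    total = values.sum()
    est = total / n
    edges = list(range(0, n, block_size)) + [n]
    sizes = np.diff(edges).astype(float)
    g = len(sizes)
    if g < 2:
        raise ValueError("need at least 2 jackknife blocks")
    block_sums = np.add.reduceat(values, edges[:-1])
    loo = (total - block_sums) / (n - sizes)  # leave-one-block-out means
    h = n / sizes
    theta_j = g * est - np.sum((1.0 - sizes / n) * loo)
    # weighted delete-m_j jackknife variance; reduces to the classical
    # variance of block means when all blocks have equal size
    var = np.mean((h * est - (h - 1.0) * loo - theta_j) ** 2 / (h - 1.0))
    return float(est), float(np.sqrt(var)), g


def f3(
    target: str,
    ref_a: str,
    ref_b: str,
    freqs: AlleleFreqTable,
    block_snps: int = 1000,
    z_threshold: float = -3.0,
) -> F3Result:
    """f3(target; ref_a, ref_b) with jackknife SE and the Z < -3 call.

    Variants monomorphic across all three populations are excluded (they
    contribute exactly zero and only dilute the jackknife). The estimate is
    symmetric in the two references and invariant to a consistent
    ref/alt label flip at any variant.
    """
    ia, ib, ic = (freqs.pop_index(p) for p in (ref_a, ref_b, target))
    a = freqs.freq[ia]
    b = freqs.freq[ib]
    c = freqs.freq[ic]
    nc = freqs.n_hap[ic]
    if np.any(nc < 2):
        raise ValueError("target needs >= 2 allele copies at every variant")
    mono = (a == b) & (b == c) & ((c == 0.0) | (c == 1.0))
    a, b, c, nc = a[~mono], b[~mono], c[~mono], nc[~mono]
    n = len(c)
    if n < 2 * block_snps:
        # still compute, but at least 2 blocks are required downstream
        pass
    d = (c - a) * (c - b) - c * (1.0 - c) / (nc - 1.0)
    est, se, n_blocks = _block_jackknife(d, block_snps)
    z = est / se if se > 0 else np.nan
    flags = []
    if np.all(nc == 2):
        flags.append("low_power_target")
    return F3Result(
        target=target,
        ref_a=ref_a,
        ref_b=ref_b,
        f3=est,
        se=se,
        z=float(z),
        n_snps=n,
        n_blocks=n_blocks,
        significant=bool(z < z_threshold),
        flags=flags,
    )


def population_f3(p_a: np.ndarray, p_b: np.ndarray, p_c: np.ndarray) -> float:
    """Population-level f3 from true (noise-free) allele frequencies.

    No sampling correction applies: this is the quantity the sample
    statistic estimates, useful as an oracle when true frequencies are known
    (e.g. from a simulation's ground truth).
    """
    return float(np.mean((p_c - p_a) * (p_c - p_b)))
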