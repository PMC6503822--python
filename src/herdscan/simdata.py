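"""Synthetic data with the statistical structure the pipeline assumes.

Three generators, each seeded and returning a ground-truth record so every
downstream estimator can be scored by parameter recovery:

* ``simulate_pileup_genome`` — a diploid genome observed through short
  reads: each site is heterozygous with probability theta (scaled by a
  residual factor inside planted low-diversity tracts), read depth is
  Poisson, and each read reports the true base except with probability
  epsilon it substitutes uniformly to one of the three other bases.
* ``simulate_admixed_panel`` — allele-frequency panels for three
  populations under Balding-Nichols drift from a shared ancestor, with the
  target C formed as an alpha : (1-alpha) mixture of the drifted A and B
  frequencies before its own drift; genotypes are binomial draws.
* ``simulate_twolocus_wf`` — many independent two-locus haplotype
  populations evolved by Wright-Fisher resampling with recombination,
  yielding sampled diploids whose mean r^2 follows Sved's 1/(1 + 4 Ne c).

Heterozygosity is parameterised directly as P(het) = theta per site — valid
for theta << 1, where theta and per-site heterozygosity coincide — keeping
every recovery target analytic; there is no coalescent machinery here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genoqc import GenotypeMatrix
from .seqdiversity import PileupTable

_CHUNK = 16_000_000  # sites simulated per block, caps peak memory


@dataclass
class SimTruth:
    """Ground truth of one simulation; sufficient to score every estimator."""

    planted_roh: list[tuple[str, int, int]] = field(default_factory=list)  # 0-based half-open bp
    theta_true: float = 0.0
    epsilon_true: float = 0.0
    alpha_true: float = 0.0
    ne_true: int = 2
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev: dict[str, int] = {}
        for chrom, start, end in self.planted_roh:
            if end <= start:
                raise ValueError("planted interval must have end > start")
            if chrom in prev and start < prev[chrom]:
                raise ValueError("planted intervals must be sorted and non-overlapping")
            prev[chrom] = end
        for p in (self.theta_true, self.epsilon_true, self.alpha_true):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.ne_true < 2:
            raise ValueError("ne_true must be >= 2")


def plant_tracts(
    genome_length: int,
    n_tracts: int,
    min_bins: int,
    max_bins: int,
    rng: np.random.Generator,
    bin_size: int = 10_000,
    min_gap_bins: int = 40,
    residual_het_factor: float = 0.0,
) -> list[tuple[int, int, float]]:
    """Place bin-aligned low-diversity tracts with a minimum separation.

    Tracts are kept at least ``min_gap_bins`` bins apart so that distinct
    tracts remain individually resolvable by a caller whose relaxation rules
    can bridge short stretches of ordinary diversity; without a separation
    floor, bin-level precision against the planted truth is ill-defined.
    """
    n_bins_total = genome_length // bin_size
    lengths = rng.integers(min_bins, max_bins + 1, size=n_tracts)
    need = int(lengths.sum()) + min_gap_bins * (n_tracts - 1)
    slack = n_bins_total - need
    if slack < 0:
        raise ValueError("genome too short for the requested tracts and separation")
    # distribute the slack as n_tracts+1 random gaps around the fixed minimum
    cuts = np.sort(rng.integers(0, slack + 1, size=n_tracts))
    extra = np.diff(np.concatenate([[0], cuts]))
    tracts = []
    cursor = int(extra[0]) if n_tracts else 0
    for i, L in enumerate(lengths):
        if i > 0:
            cursor += min_gap_bins + int(extra[i])
        start = cursor * bin_size
        end = (cursor + int(L)) * bin_size
        tracts.append((start, end, residual_het_factor))
        cursor += int(L)
    return tracts


def simulate_pileup_genome(
    genome_length: int,
    theta: float,
    epsilon: float,
    mean_depth: float,
    roh_spec: list[tuple[int, int, float]] | None = None,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[PileupTable, SimTruth]:
    """Simulate one diploid genome's per-site pileup.

    ``roh_spec`` lists (start, end, residual_het_factor) in 0-based
    half-open bp; inside a tract the per-site het probability is
    theta * factor. Sites with zero simulated depth are not emitted.
    """
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    if not 0.0 <= theta < 0.1:
        raise ValueError("theta must lie in [0, 0.1)")
    if not 0.0 <= epsilon < 0.05:
        raise ValueError("epsilon must lie in [0, 0.05)")
    roh_spec = sorted(roh_spec or [])
    prev_end = 0
    for start, end, fac in roh_spec:
        if start < prev_end:
            raise ValueError("roh_spec intervals overlap")
        if not (0 <= start < end <= genome_length):
            raise ValueError("roh_spec interval outside the genome")
        if not 0.0 <= fac <= 1.0:
            raise ValueError("residual_het_factor must lie in [0, 1]")
        prev_end = end

    rng = np.random.default_rng(seed)
    chroms, poss, counts = [], [], []
    for lo in range(0, genome_length, _CHUNK):
        hi = min(lo + _CHUNK, genome_length)
        L = hi - lo
        p_het = np.full(L, theta)
        for start, end, fac in roh_spec:
            s, e = max(start, lo), min(end, hi)
            if s < e:
                p_het[s - lo : e - lo] = theta * fac
        is_het = rng.random(L) < p_het
        depth = rng.poisson(mean_depth, L)
        b0 = rng.integers(0, 4, L)
        b1 = (b0 + rng.integers(1, 4, L)) % 4
        cnt = np.zeros((L, 4), dtype=np.int32)
        # hom sites: depth - Binomial(depth, eps) true-base reads; the error
        # reads split uniformly over the other three bases. Only the (rare)
        # sites with errors need the 3-way split.
        hom = np.flatnonzero(~is_het)
        n_err = rng.binomial(depth[hom], epsilon) if epsilon > 0 else np.zeros(len(hom), np.int64)
        cnt[hom, b0[hom]] = depth[hom] - n_err
        others = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])
        errsite = hom[n_err > 0]
        if len(errsite):
            split = rng.multinomial(n_err[n_err > 0], [1 / 3] * 3)
            tmp = cnt[errsite]
            np.put_along_axis(tmp, others[b0[errsite]], split, axis=1)
            cnt[errsite] = tmp
        # het sites (rare at small theta): full per-site multinomial
        hets = np.flatnonzero(is_het)
        if len(hets):
            p = np.full((len(hets), 4), epsilon / 3.0)
            p_allele = (1.0 - epsilon) / 2.0 + epsilon / 6.0
            rows = np.arange(len(hets))
            p[rows, b0[hets]] = p_allele
            p[rows, b1[hets]] = p_allele
            cnt[hets] = rng.multinomial(depth[hets], p)
        covered = depth > 0
        chroms.append(np.full(int(covered.sum()), chrom))
        poss.append(np.flatnonzero(covered) + lo + 1)  # 1-based
        counts.append(cnt[covered])
    table = PileupTable(
        np.concatenate(chroms) if chroms else np.empty(0, dtype="U1"),
        np.concatenate(poss) if poss else np.empty(0, np.int64),
        np.vstack(counts) if counts else np.empty((0, 4), np.int64),
    )
    truth = SimTruth(
        planted_roh=[(chrom, s, e) for s, e, _ in roh_spec],
        theta_true=theta,
        epsilon_true=epsilon,
        seed=seed,
        extras={
            "mean_depth": mean_depth,
            "genome_length": genome_length,
            "residual_factors": [f for _, _, f in roh_spec],
        },
    )
    return table, truth


def _balding_nichols(p_anc: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Drifted frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestor."""
    if F <= 0.0:
        return p_anc.copy()
    k = (1.0 - F) / F
    p = np.clip(p_anc, 1e-9, 1.0 - 1e-9)
    return rng.beta(k * p, k * (1.0 - p))


def simulate_admixed_panel(
    n_snps: int,
    f_a: float,
    f_b: float,
    f_c: float,
    alpha: float,
    n_per_pop: int,
    seed: int = 0,
) -> tuple[GenotypeMatrix, GenotypeMatrix, GenotypeMatrix, SimTruth]:
    """Three genotype panels: references A and B, and target C.

    Ancestral frequencies are uniform on [0.05, 0.95]; A and B drift with
    Balding-Nichols coefficients f_a, f_b; C's pre-drift frequency is
    alpha * p_A + (1 - alpha) * p_B, then drifts with f_c. Genotypes are
    Binomial(2, p) per individual. True frequencies are stored in the
    truth record (extras p_a / p_b / p_c) for oracle use.
    """
    for name, f in (("f_a", f_a), ("f_b", f_b), ("f_c", f_c)):
        if not 0.0 < f < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if n_per_pop < 2:
        raise ValueError("need >= 2 individuals per population (f3 correction undefined below)")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, n_snps)
    p_a = _balding_nichols(p_anc, f_a, rng)
    p_b = _balding_nichols(p_anc, f_b, rng)
    p_mix = alpha * p_a + (1.0 - alpha) * p_b
    p_c = _balding_nichols(p_mix, f_c, rng)

    chromv = np.full(n_snps, "1", dtype=object)
    pos = np.arange(1, n_snps + 1, dtype=np.int64) * 1000
    ref = np.full(n_snps, "A", dtype=object)
    alt = np.full(n_snps, "G", dtype=object)

    def panel(tag: str, p: np.ndarray) -> GenotypeMatrix:
        calls = rng.binomial(2, p, size=(n_per_pop, n_snps)).astype(np.int8)
        return GenotypeMatrix(
            [f"{tag}{i:03d}" for i in range(n_per_pop)], chromv, pos, ref, alt, calls
        )

    ga, gb, gc = panel("A", p_a), panel("B", p_b), panel("C", p_c)
    truth = SimTruth(
        alpha_true=alpha,
        seed=seed,
        extras={"p_a": p_a, "p_b": p_b, "p_c": p_c, "f_a": f_a, "f_b": f_b, "f_c": f_c},
    )
    return ga, gb, gc, truth


def simulate_twolocus_wf(
    ne: int,
    c: float,
    n_systems: int,
    n_sample: int,
    generations: int | None = None,
    seed: int = 0,
    epochs: list[tuple[int, int]] | None = None,
    cm_per_mb: float = 1.0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Many independent two-locus Wright-Fisher populations at equilibrium.

    Each system holds 2*Ne haplotypes over two biallelic loci, initialised
    at frequency 0.5 per locus in linkage equilibrium, and resampled
    multinomially each generation after deterministic recombination
    (D shrinks by a factor c per generation). The default burn-in of Ne
    generations is several times the LD relaxation time
    1 / (c + 1/(2 Ne)) whenever 4 Ne c >~ 1, so the r^2 distribution is at
    drift-recombination equilibrium, while keeping a large fraction of
    systems polymorphic (longer burns only lose systems to fixation
    without changing equilibrium LD). ``epochs`` optionally appends
    (generations, ne) phases after the burn-in, e.g. a recent bottleneck.

    Sampled diploids are returned as a genotype matrix with one chromosome
    per system and the two loci placed so that physical distance maps back
    to c at ``cm_per_mb`` (d = c / (cm_per_mb * 1e-8) bp).
    """
    if not 0.0 < c <= 0.5:
        raise ValueError("c must lie in (0, 0.5]")
    if ne < 2:
        raise ValueError("ne must be >= 2")
    if n_sample > ne:
        raise ValueError("cannot sample more diploids than the population holds")
    if generations is None:
        generations = ne
    rng = np.random.default_rng(seed)

    # haplotype order: AB, Ab, aB, ab
    sign = np.array([1.0, -1.0, -1.0, 1.0])
    hap = rng.multinomial(2 * ne, [0.25, 0.25, 0.25, 0.25], size=n_systems)

    def evolve(hap: np.ndarray, n_gen: int, size: int) -> np.ndarray:
        for _ in range(n_gen):
            x = hap / hap.sum(axis=1, keepdims=True)
            D = x[:, 0] * x[:, 3] - x[:, 1] * x[:, 2]
            gam = x - c * D[:, None] * sign
            np.clip(gam, 0.0, None, out=gam)
            gam /= gam.sum(axis=1, keepdims=True)
            hap = rng.multinomial(2 * size, gam)
        return hap

    hap = evolve(hap, generations, ne)
    sched = [("burn", generations, ne)]
    for n_gen, size in epochs or []:
        # population-size change: resample 2*size haplotypes from current freqs
        x = hap / hap.sum(axis=1, keepdims=True)
        hap = rng.multinomial(2 * size, x)
        hap = evolve(hap, n_gen, size)
        sched.append(("epoch", n_gen, size))

    # sample n_sample diploids per system without replacement
    d_bp = int(round(c / (cm_per_mb * 1e-8)))
    n_hap_sample = 2 * n_sample
    calls = np.empty((n_sample, 2 * n_systems), dtype=np.int8)
    chroms = np.empty(2 * n_systems, dtype=object)
    pos = np.empty(2 * n_systems, dtype=np.int64)
    dos1 = np.array([1, 1, 0, 0])  # allele A copies per haplotype class
    dos2 = np.array([1, 0, 1, 0])  # allele B copies
    for s in range(n_systems):
        picked = rng.multivariate_hypergeometric(hap[s], n_hap_sample)
        haps = np.repeat(np.arange(4), picked)
        rng.shuffle(haps)
        pair = haps.reshape(n_sample, 2)
        calls[:, 2 * s] = dos1[pair].sum(axis=1)
        calls[:, 2 * s + 1] = dos2[pair].sum(axis=1)
        chroms[2 * s : 2 * s + 2] = f"sys{s}"
        pos[2 * s] = 1
        pos[2 * s + 1] = 1 + d_bp
    g = GenotypeMatrix(
        [f"S{i:03d}" for i in range(n_sample)],
        chroms,
        pos,
        np.full(2 * n_systems, "A", dtype=object),
        np.full(2 * n_systems, "G", dtype=object),
        calls,
    )
    truth = SimTruth(
        ne_true=ne,
        seed=seed,
        extras={"c": c, "n_systems": n_systems, "schedule": sched, "d_bp": d_bp},
    )
    return g, truth
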