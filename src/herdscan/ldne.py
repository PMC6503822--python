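"""LD decay with physical distance and LD-based effective population size.

At drift-recombination equilibrium, Sved's approximation links expected
squared linkage disequilibrium between loci at recombination fraction c in a
population of diploid effective size Ne:

    E[r^2] ~= 1 / (1 + 4 Ne c)

Squared dosage correlations measured in a finite sample of n individuals are
inflated by roughly 1/n, so the binned means use the adjusted statistic
r^2_adj = r^2 - 1/n. Inverting the formula bin by bin,

    Ne(c) = (1 / (4 c)) * (1 / r^2_adj - alpha)

where the constant alpha encodes the mutation model (1 without mutation,
2 or 2.2 with), and each distance bin reflects the effective size roughly
t = 1 / (2 c) generations before present — short distances probe the deep
past, long distances the recent past. Physical distance is mapped to c with
a constant recombination rate (default 1 cM/Mb, i.e. c = bp x 1e-8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genoqc import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class LDDecayParams:
    min_dist: int = 5_000
    max_dist: int = 2_000_000
    n_bins: int = 50
    min_maf: float = 0.05


def _chrom_pair_r2(g: GenotypeMatrix, cidx: np.ndarray, min_pairs: int = 5):
    """All within-chromosome pair distances and adjusted r^2 (vectorised)."""
    X = g.calls[:, cidx].astype(float)
    M = (g.calls[:, cidx] != MISSING).astype(float)
    Xm = X * M
    n = M.T @ M
    sx = Xm.T @ M
    sxx = (Xm * Xm).T @ M
    sxy = Xm.T @ Xm
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sx.T / n)
        var_i = sxx / n - (sx / n) ** 2
        r2 = cov**2 / (var_i * var_i.T)
        r2_adj = r2 - 1.0 / n
    bad = (n < min_pairs) | ~np.isfinite(r2)
    pos = g.pos[cidx]
    dist = np.abs(pos[:, None] - pos[None, :])
    iu = np.triu_indices(len(cidx), k=1)
    keep = ~bad[iu]
    return dist[iu][keep], r2_adj[iu][keep]


def ld_decay(
    g: GenotypeMatrix,
    min_dist: int = 5_000,
    max_dist: int = 2_000_000,
    n_bins: int = 50,
    min_maf: float = 0.05,
    cm_per_mb: float = 1.0,
) -> pd.DataFrame:
    """Mean adjusted r^2 in equal-width physical-distance bins.

    Pairs are intra-chromosomal with min_dist <= |delta pos| <= max_dist
    (bounds inclusive); variants below ``min_maf`` are removed first.
    Columns: d_min, d_max, mean_dist, mean_c, mean_r2_adj, n_pairs; only
    bins with at least one pair are returned.
    """
    keep = np.nan_to_num(g.maf(), nan=0.0) >= min_maf
    g = g.take_variants(keep)
    dists = []
    r2s = []
    for chrom in dict.fromkeys(g.chrom):
        cidx = np.flatnonzero(g.chrom == chrom)
        if len(cidx) < 2:
            continue
        d, r = _chrom_pair_r2(g, cidx)
        sel = (d >= min_dist) & (d <= max_dist)
        dists.append(d[sel])
        r2s.append(r[sel])
    if not dists or sum(len(d) for d in dists) == 0:
        warnings.warn("no variant pairs in the requested distance range")
        return pd.DataFrame(
            columns=["d_min", "d_max", "mean_dist", "mean_c", "mean_r2_adj", "n_pairs"]
        )
    dist = np.concatenate(dists).astype(float)
    r2 = np.concatenate(r2s)
    edges = np.linspace(min_dist, max_dist, n_bins + 1)
    which = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        md = dist[sel].mean()
        rows.append(
            {
                "d_min": edges[b],
                "d_max": edges[b + 1],
                "mean_dist": md,
                "mean_c": md * cm_per_mb * 1e-8,
                "mean_r2_adj": float(r2[sel].mean()),
                "n_pairs": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def estimate_ne(
    bins: pd.DataFrame,
    alpha_const: float = 2.0,
    min_pairs: int = 100,
) -> pd.DataFrame:
    """Invert Sved's formula per distance bin into an Ne(t) trajectory.

    Bins with fewer than ``min_pairs`` pairs, non-positive adjusted r^2, or
    1/r^2 <= alpha (which would imply Ne <= 0) are skipped with a warning.
    Returns columns t (generations before present, = 1/(2c)) and ne, plus
    the source bin's mean_dist / mean_c / mean_r2_adj; rows are ordered by
    increasing distance, i.e. decreasing t.
    """
    rows = []
    skipped = 0
    for _, b in bins.iterrows():
        if b["n_pairs"] < min_pairs:
            skipped += 1
            continue
        r2 = b["mean_r2_adj"]
        c = b["mean_c"]
        if r2 <= 0 or c <= 0 or 1.0 / r2 <= alpha_const:
            skipped += 1
            continue
        ne = (1.0 / (4.0 * c)) * (1.0 / r2 - alpha_const)
        rows.append(
            {
                "t": 1.0 / (2.0 * c),
                "ne": ne,
                "mean_dist": b["mean_dist"],
                "mean_c": c,
                "mean_r2_adj": r2,
            }
        )
    if skipped:
        warnings.warn(f"estimate_ne skipped {skipped} bins (thin or out-of-domain)")
    return pd.DataFrame(rows)
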