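"""Brute-force reference for the ROH caller, used only by tests.

Re-derives the calls from first principles with explicit slice sums and an
O(n^2) enumeration of candidate run endpoints, sharing no code with the
production scanner: for every low start bin, every further low bin is
examined in order and the run mean is recomputed from scratch over the
slice; the furthest endpoint reachable without an intermediate violation is
the maximal run. Selection then walks starts left to right, emitting runs
that satisfy the length rules and skipping any start inside an emitted run.
"""

from __future__ import annotations


def _is_low(snp, nodata, i, seed_thr) -> bool:
    return (not nodata[i]) and snp[i] < seed_thr


def _max_endpoint(snp, nodata, i, seed_thr, ceil_thr, mean_thr, max_gap):
    """Furthest low bin j such that the run [i..j] satisfies every rule."""
    n = len(snp)
    best = i
    j = i + 1
    gap = 0
    while j < n:
        if nodata[j]:
            gap += 1
            if gap > max_gap:
                return best
            j += 1
            continue
        gap = 0
        if snp[j] > ceil_thr:
            return best
        if _is_low(snp, nodata, j, seed_thr):
            data = [snp[t] for t in range(i, j + 1) if not nodata[t]]
            if sum(data) / len(data) <= mean_thr:
                best = j
            else:
                return best
        j += 1
    return best


def oracle_call_roh(snp, nodata, starts_bp, ends_bp, genome_avg, params):
    """All maximal disjoint runs satisfying the seed/ceiling/mean rules.

    Returns a list of (start_bp, end_bp, n_bins) tuples for one chromosome.
    """
    seed_thr = params.seed_factor * genome_avg
    ceil_thr = params.bin_ceiling_factor * genome_avg
    mean_thr = params.run_mean_factor * genome_avg
    n = len(snp)
    out = []
    i = 0
    while i < n:
        if not _is_low(snp, nodata, i, seed_thr):
            i += 1
            continue
        j = _max_endpoint(snp, nodata, i, seed_thr, ceil_thr, mean_thr, params.max_nodata_gap)
        n_bins = j - i + 1
        length = ends_bp[j] - starts_bp[i]
        if n_bins >= params.min_bins and length >= params.effective_min_length:
            out.append((int(starts_bp[i]), int(ends_bp[j]), n_bins))
            i = j + 1
        else:
            i += 1
    return out
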