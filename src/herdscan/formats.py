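"""Readers/writers for the text formats the pipeline consumes and emits.

Coordinate conventions are centralised here: pileup and VCF positions are
1-based on disk, BED is 0-based half-open; internally intervals are always
0-based half-open and site positions 1-based. A run manifest (JSON) records
every parameter, the seed and input hashes so a run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genoqc import MISSING, GenotypeMatrix
from .roh import ROHInterval
from .seqdiversity import PileupTable

log = logging.getLogger("herdscan")

PILEUP_COLUMNS = ["chrom", "pos", "depth", "nA", "nC", "nG", "nT"]


def read_pileup(path: str | Path) -> PileupTable:
    """Read a pileup TSV (chrom, 1-based pos, depth, nA, nC, nG, nT)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=PILEUP_COLUMNS)
    counts = df[["nA", "nC", "nG", "nT"]].to_numpy(dtype=np.int64)
    depth = df["depth"].to_numpy(dtype=np.int64)
    if not np.array_equal(counts.sum(axis=1), depth):
        bad = int(np.flatnonzero(counts.sum(axis=1) != depth)[0]) + 1
        raise ValueError(f"pileup row {bad}: depth does not equal the sum of base counts")
    return PileupTable(df["chrom"].to_numpy(dtype=object), df["pos"].to_numpy(np.int64), counts)


def write_pileup(table: PileupTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": table.chrom,
            "pos": table.pos,
            "depth": table.depth,
            "nA": table.counts[:, 0],
            "nC": table.counts[:, 1],
            "nG": table.counts[:, 2],
            "nT": table.counts[:, 3],
        }
    )
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PILEUP_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_vcf(
    path: str | Path,
    min_gq: float | None = 30.0,
    min_dp: float | None = 4.0,
    max_dp: float | None = 30.0,
) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a genotype matrix.

    Only biallelic SNVs are kept; indel and multi-allelic records are
    dropped and counted in the log. Per-call GQ/DP thresholds are applied
    when the VCF carries those FORMAT fields (failing calls become
    missing); otherwise a notice is logged and calls pass through.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_indel = n_multi = 0
    saw_gq = saw_dp = False
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if not v.is_snp:
            n_indel += 1
            continue
        gt = v.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = MISSING
        if min_gq is not None:
            try:
                gq = v.gt_quals
                if gq is not None and len(gq) == len(gt) and np.any(gq >= 0):
                    saw_gq = True
                    gt[gq < min_gq] = MISSING
            except Exception:
                pass
        if min_dp is not None or max_dp is not None:
            try:
                dp = v.format("DP")
                if dp is not None:
                    saw_dp = True
                    dp = dp.reshape(-1).astype(float)
                    if min_dp is not None:
                        gt[dp < min_dp] = MISSING
                    if max_dp is not None:
                        gt[dp > max_dp] = MISSING
            except Exception:
                pass
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(gt)
    if n_indel or n_multi:
        log.info("read_vcf dropped %d indel and %d multi-allelic records", n_indel, n_multi)
    if (min_gq is not None or min_dp is not None) and not (saw_gq or saw_dp):
        log.info("read_vcf: no GQ/DP fields present; per-call quality filters skipped")
    calls = (
        np.array(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8)
    )
    return GenotypeMatrix(
        samples,
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        calls,
    )


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype columns."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.chrom):
            sel = g.chrom == chrom
            fh.write(f"##contig=<ID={chrom},length={int(g.pos[sel].max()) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        for j in range(g.n_variants):
            gts = "\t".join(gt_map[int(x)] for x in g.calls[:, j])
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t.\t{g.ref[j]}\t{g.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_bed(intervals: list[ROHInterval] | list[tuple], path: str | Path) -> None:
    """Write intervals as BED (0-based half-open, as stored internally)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if isinstance(iv, ROHInterval):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                chrom, start, end = iv[:3]
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        out.append((chrom, int(start), int(end)))
    return out


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: dict, path: str | Path, inputs: list[str | Path] | None = None) -> None:
    """JSON run manifest: parameters verbatim, seed, and input file hashes."""
    manifest = dict(config)
    manifest["inputs"] = {
        str(p): _hash_file(Path(p)) for p in (inputs or []) if Path(p).exists()
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
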