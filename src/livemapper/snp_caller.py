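"""Minimal pileup SNV caller and VCFv4.2 writer.

This is deliberately simple: only bases inside CIGAR M runs contribute to
the pileup (softclips and indel bases are excluded), calling is
depth-and-fraction gated, and the call quality is the Phred-scaled exact
binomial tail probability of seeing at least the observed alternate count
under the sequencing error rate alone.  Ploidy is ignored, matching the
squash-ploidy convention used downstream in the evaluator.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log10
from pathlib import Path

import numpy as np
import pysam

from .reference_index import ReferenceGenome

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"


class PileupError(ValueError):
    pass


@dataclass(frozen=True)
class PileupColumn:
    name: str
    pos: int  # 1-based
    ref: str
    depth: int
    counts: tuple[int, int, int, int]  # A, C, G, T
    qual_sums: tuple[int, int, int, int]


@dataclass(frozen=True)
class VcfSnp:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: int
    depth: int
    alt_fraction: float


def _region_mask(length: int, regions: list[tuple[int, int]] | None) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    if regions is None:
        mask[:] = True
    else:
        for s, e in regions:
            mask[max(0, s) : min(length, e)] = True
    return mask


def pileup(
    sam_path: str | Path,
    reference: ReferenceGenome,
    regions: dict[str, list[tuple[int, int]]] | None = None,
) -> list[PileupColumn]:
    """Per-position allele counts from the M runs of mapped SAM records.

    ``regions`` maps sequence name to 0-based half-open intervals (BED
    convention); positions outside them produce no columns.  Records that
    reference an unknown sequence are rejected.
    """
    lengths = {name: len(bases) for name, bases in reference.sequences}
    counts = {n: np.zeros((4, L), dtype=np.int32) for n, L in lengths.items()}
    qsums = {n: np.zeros((4, L), dtype=np.int64) for n, L in lengths.items()}
    covered = {n: np.zeros(L, dtype=bool) for n, L in lengths.items()}

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            name = rec.reference_name
            if name not in lengths:
                raise PileupError(f"record {rec.query_name} references unknown {name!r}")
            seq = rec.query_sequence
            quals = rec.query_qualities
            rpos = rec.reference_start
            qpos = 0
            for op, ln in rec.cigartuples:
                if op == 0:  # M: the only op contributing to the pileup
                    sub = seq[qpos : qpos + ln]
                    codes = np.frombuffer(sub.encode(), dtype=np.uint8)
                    keep = codes != ord("N")
                    idx = np.empty(len(sub), dtype=np.int8)
                    for b, i in _BASE_IDX.items():
                        idx[codes == ord(b)] = i
                    positions = np.arange(rpos, rpos + ln)
                    q = np.asarray(quals[qpos : qpos + ln], dtype=np.int64)
                    np.add.at(counts[name], (idx[keep], positions[keep]), 1)
                    np.add.at(qsums[name], (idx[keep], positions[keep]), q[keep])
                    covered[name][rpos : rpos + ln] = True
                    rpos += ln
                    qpos += ln
                elif op == 1 or op == 4:  # I, S consume query only
                    qpos += ln
                elif op == 2:  # D consumes reference only
                    rpos += ln
                else:
                    raise PileupError(f"unsupported CIGAR op {op}")

    columns: list[PileupColumn] = []
    for name, bases in reference.sequences:
        mask = covered[name] & _region_mask(
            lengths[name], regions.get(name) if regions is not None else None
        )
        for p in np.flatnonzero(mask):
            col_counts = tuple(int(c) for c in counts[name][:, p])
            depth = sum(col_counts)
            if depth == 0:
                continue
            columns.append(
                PileupColumn(
                    name,
                    int(p) + 1,
                    bases[p],
                    depth,
                    col_counts,
                    tuple(int(q) for q in qsums[name][:, p]),
                )
            )
    return columns


def binomial_tail(alt: int, depth: int, error_rate: float) -> float:
    """P(X >= alt) for X ~ Binomial(depth, error_rate), by direct summation."""
    if alt <= 0:
        return 1.0
    p = error_rate
    total = 0.0
    for j in range(alt, depth + 1):
        total += comb(depth, j) * p**j * (1 - p) ** (depth - j)
    return min(total, 1.0)


def snp_quality(alt: int, depth: int, error_rate: float) -> int:
    """Phred-scaled binomial tail, capped at 999."""
    tail = binomial_tail(alt, depth, error_rate)
    if tail <= 0.0:
        return 999
    return min(999, round(-10 * log10(tail)))


def call_snps(
    columns: list[PileupColumn],
    *,
    min_depth: int = 5,
    min_alt_fraction: float = 0.25,
    error_rate: float = 0.01,
) -> list[VcfSnp]:
    """Call SNVs from pileup columns.

    A column yields a call iff depth >= min_depth and the top non-reference
    allele reaches min_alt_fraction of the depth.
    """
    if min_depth < 1 or min_alt_fraction <= 0 or not 0 < error_rate < 1:
        raise ValueError("caller parameters out of range")
    calls: list[VcfSnp] = []
    for col in columns:
        if col.depth < min_depth or col.ref not in _BASE_IDX:
            continue
        ref_i = _BASE_IDX[col.ref]
        alt_i = max(
            (i for i in range(4) if i != ref_i),
            key=lambda i: (col.counts[i], -i),
        )
        alt_count = col.counts[alt_i]
        frac = alt_count / col.depth
        if alt_count == 0 or frac < min_alt_fraction:
            continue
        calls.append(
            VcfSnp(
                col.name,
                col.pos,
                col.ref,
                _IDX_BASE[alt_i],
                snp_quality(alt_count, col.depth, error_rate),
                col.depth,
                frac,
            )
        )
    return calls


def write_vcf_records(
    path: str | Path,
    contigs: list[tuple[str, int]],
    records: list[tuple[str, int, str, str, int, dict]],
) -> None:
    """Write bare VCFv4.2 (CHROM, POS, REF, ALT, QUAL, INFO dict)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=livemapper\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt fraction">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, qual, info in records:
            text = (
                ";".join(f"{k}={v}" for k, v in info.items()) if info else "."
            )
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\tPASS\t{text}\n")


def write_vcf(calls: list[VcfSnp], reference: ReferenceGenome, path: str | Path) -> None:
    contigs = [(n, len(b)) for n, b in reference.sequences]
    write_vcf_records(
        path,
        contigs,
        [
            (c.chrom, c.pos, c.ref, c.alt, c.qual, {"DP": c.depth, "AF": f"{c.alt_fraction:.4f}"})
            for c in calls
        ],
    )


def call_from_sam(
    sam_path: str | Path,
    reference: ReferenceGenome,
    regions: dict[str, list[tuple[int, int]]] | None,
    out_vcf: str | Path,
    **params,
) -> list[VcfSnp]:
    """pileup -> call_snps -> VCF, the per-output-cycle calling step."""
    columns = pileup(sam_path, reference, regions)
    calls = call_snps(columns, **params)
    write_vcf(calls, reference, out_vcf)
    return calls
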