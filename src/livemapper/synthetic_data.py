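"""Synthetic fixtures: reference, mutated donor, truth VCF, regions, reads.

The generator emulates, at desk scale, the statistical structure of a
resequencing experiment: a random reference with optional tandem repeats, a
haploid donor derived from it by implanted SNVs and short indels (recorded
as the truth VCF), a "high-confidence" BED that excludes repeat tracts and
indel neighbourhoods, and paired-end reads with a substitution error rate
rising linearly along the read (later sequencing cycles are noisier, which
is what motivates relaxing the aligner's error budget with read growth).

All randomness flows through ``numpy.random.default_rng`` seeded from the
spec'd seed, so every artifact is bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reference_index import ReferenceGenome, revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RepeatSpec:
    count: int = 2  # number of distinct repeat units
    unit_length: int = 200
    copies: int = 3  # tandem copies per unit


@dataclass(frozen=True)
class DonorSpec:
    """Study conditions for one synthetic data set."""

    length: int = 100_000
    gc: float = 0.5
    repeats: RepeatSpec = field(default_factory=RepeatSpec)
    snp_rate: float = 0.002
    indel_rate: float = 1e-4
    max_indel: int = 3  # matches the aligner's default indel tolerance
    seed: int = 7
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not 0 <= self.snp_rate < 1 or not 0 <= self.indel_rate < 1:
            raise ValueError("mutation rates must lie in [0, 1)")
        if not 0 < self.gc < 1:
            raise ValueError("GC fraction must lie in (0, 1)")


@dataclass(frozen=True)
class Variant:
    """A truth variant in VCF terms (1-based POS, REF/ALT strings)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


def generate_reference(spec: DonorSpec) -> tuple[ReferenceGenome, list[tuple[int, int]]]:
    """Random reference plus the 0-based half-open repeat tracts inserted.

    Repeat units are generated from the same base composition and written as
    tandem copies over the background sequence (length preserved).
    """
    rng = np.random.default_rng([spec.seed, 0])
    p = np.array(
        [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    )
    seq = rng.choice(4, size=spec.length, p=p)
    tracts: list[tuple[int, int]] = []
    rep = spec.repeats
    if rep.count > 0 and rep.unit_length > 0 and rep.copies > 0:
        tract_len = rep.unit_length * rep.copies
        for _ in range(rep.count):
            unit = rng.choice(4, size=rep.unit_length, p=p)
            # place without overlapping previously inserted tracts
            for _attempt in range(100):
                start = int(rng.integers(0, spec.length - tract_len))
                if all(
                    start + tract_len <= s or start >= e for s, e in tracts
                ):
                    break
            seq[start : start + tract_len] = np.tile(unit, rep.copies)
            tracts.append((start, start + tract_len))
    bases = "".join(_BASES[seq])
    return ReferenceGenome(((spec.chrom, bases),)), sorted(tracts)


def mutate_donor(
    reference: ReferenceGenome, spec: DonorSpec, tracts: list[tuple[int, int]] | None = None
) -> tuple[ReferenceGenome, list[Variant], list[tuple[str, int, int]]]:
    """Implant SNVs and short indels; return donor, truth variants, regions.

    Regions (BED-style, 0-based half-open) cover the chromosome minus repeat
    tracts and a +/-5 bp window around each indel — the desk-scale analog of
    a high-confidence region restriction.  Applying the truth variants to the
    reference reproduces the donor exactly.
    """
    rng = np.random.default_rng([spec.seed, 1])
    name, ref = reference.sequences[0]
    n = len(ref)
    tracts = tracts or []

    n_snp = rng.binomial(n, spec.snp_rate)
    snp_pos = rng.choice(n, size=n_snp, replace=False)
    n_indel = rng.binomial(n, spec.indel_rate)
    taken = set(snp_pos.tolist())
    indels: list[tuple[int, int]] = []  # (pos, signed length) + = ins, - = del
    guard = spec.max_indel + 2
    while len(indels) < n_indel:
        pos = int(rng.integers(1, n - guard))
        if any(abs(pos - p) <= guard for p, _ in indels) or any(
            abs(pos - p) <= guard for p in taken
        ):
            continue
        length = int(rng.integers(1, spec.max_indel + 1))
        if rng.random() < 0.5:
            length = -length
        indels.append((pos, length))

    variants: list[Variant] = []
    for pos in sorted(snp_pos.tolist()):
        refb = ref[pos]
        alt = "ACGT".replace(refb, "")[int(rng.integers(0, 3))]
        variants.append(Variant(name, pos + 1, refb, alt))
    for pos, length in sorted(indels):
        if length > 0:  # insertion after the anchor base
            ins = "".join(_BASES[rng.integers(0, 4, size=length)])
            variants.append(Variant(name, pos + 1, ref[pos], ref[pos] + ins))
        else:
            d = -length
            variants.append(Variant(name, pos + 1, ref[pos : pos + d + 1], ref[pos]))
    variants.sort(key=lambda v: v.pos)

    donor = apply_variants(reference, variants)

    excluded = list(tracts)
    for pos, length in indels:
        lo = max(0, pos - 5)
        hi = min(n, pos + abs(length) + 6)
        excluded.append((lo, hi))
    regions = _complement_intervals(name, n, excluded)
    return donor, variants, regions


def apply_variants(reference: ReferenceGenome, variants: list[Variant]) -> ReferenceGenome:
    """Apply VCF-style variants to a single-sequence reference (round-trip oracle)."""
    name, ref = reference.sequences[0]
    out: list[str] = []
    cursor = 0
    for v in sorted(variants, key=lambda x: x.pos):
        start = v.pos - 1
        if start < cursor:
            raise ValueError(f"overlapping variants near {v.pos}")
        if ref[start : start + len(v.ref)] != v.ref:
            raise ValueError(f"REF mismatch at {v.pos}")
        out.append(ref[cursor:start])
        out.append(v.alt)
        cursor = start + len(v.ref)
    out.append(ref[cursor:])
    return ReferenceGenome(((name, "".join(out)),))


def _complement_intervals(
    name: str, n: int, excluded: list[tuple[int, int]]
) -> list[tuple[str, int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(excluded):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    regions = []
    cursor = 0
    for s, e in merged:
        if s > cursor:
            regions.append((name, cursor, s))
        cursor = max(cursor, e)
    if cursor < n:
        regions.append((name, cursor, n))
    return regions


def simulate_reads(
    donor: ReferenceGenome,
    coverage: float,
    read_lengths: tuple[int, int] = (100, 100),
    *,
    error_rates: tuple[float, float] = (0.001, 0.01),
    fragment_mean: int = 300,
    fragment_sd: int = 30,
    seed: int = 7,
) -> list[tuple[str, str, tuple[int, ...], str, tuple[int, ...]]]:
    """Uniform paired-end fragments with a linearly rising substitution rate.

    Mate 1 reads the fragment 5'->3' from its start; mate 2 reads the
    opposite strand from the fragment end.  Base qualities encode the
    per-cycle error rate (Phred, capped at 41).  Returns
    (name, seq1, quals1, seq2, quals2) tuples.
    """
    rng = np.random.default_rng([seed, 2])
    name, seq = donor.sequences[0]
    n = len(seq)
    r1, r2 = read_lengths
    n_pairs = int(round(coverage * n / (r1 + r2)))
    min_frag = max(r1, r2)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)

    def errorize(bases: str, rlen: int) -> tuple[str, tuple[int, ...]]:
        e0, e1 = error_rates
        rates = np.linspace(e0, e1, rlen) if rlen > 1 else np.array([e0])
        quals = tuple(
            int(min(41, round(-10 * np.log10(max(r, 1e-5))))) for r in rates
        )
        if e1 <= 0 and e0 <= 0:
            return bases, quals
        hits = rng.random(rlen) < rates
        if not hits.any():
            return bases, quals
        out = list(bases)
        for i in np.flatnonzero(hits):
            out[i] = "ACGT".replace(out[i], "")[int(rng.integers(0, 3))]
        return "".join(out), quals

    pairs = []
    for i in range(n_pairs):
        frag = int(
            np.clip(round(rng.normal(fragment_mean, fragment_sd)), min_frag, n)
        )
        start = int(rng.integers(0, n - frag + 1))
        fwd = seq[start : start + frag]
        m1 = fwd[:r1]
        m2 = revcomp(fwd[-r2:])
        if rng.random() < 0.5:  # fragment sequenced from the other end
            m1, m2 = revcomp(fwd)[:r1], revcomp(revcomp(fwd)[-r2:])
        s1, q1 = errorize(m1, r1)
        s2, q2 = errorize(m2, r2)
        pairs.append((f"frag{i:06d}", s1, q1, s2, q2))
    return pairs


def write_fastq_pair(
    pairs: list[tuple[str, str, tuple[int, ...], str, tuple[int, ...]]],
    path1: str | Path,
    path2: str | Path,
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, s1, q1, s2, q2 in pairs:
            f1.write(f"@{name}/1\n{s1}\n+\n{''.join(chr(q + 33) for q in q1)}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{''.join(chr(q + 33) for q in q2)}\n")


def write_truth_vcf(variants: list[Variant], path: str | Path, contigs: list[tuple[str, int]]) -> None:
    from .snp_caller import write_vcf_records

    write_vcf_records(
        path,
        contigs,
        [(v.chrom, v.pos, v.ref, v.alt, 999, {}) for v in variants],
    )


def write_bed(regions: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, s, e in regions:
            fh.write(f"{name}\t{s}\t{e}\n")
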