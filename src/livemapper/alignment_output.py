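"""SAM emission for intermediate and final cycles.

Records are produced in forward-strand SAM convention (reverse-strand hits
store the reverse-complemented sequence and reversed CIGAR), tagged with
NM (errors used), AS (alignment score) and XC (output cycle), sorted by
(reference, position, name) with unmapped records last, and written through
pysam with a fixed header so the byte stream is deterministic.
"""

from __future__ import annotations

from pathlib import Path

import pysam

from . import __version__
from .live_aligner import (
    AlignmentSettings,
    ReadState,
    SeedState,
    TileState,
    min_score,
    placement,
    select_best,
)
from .reference_index import CODE_TO_BASE, FmIndex

_COMP = str.maketrans("ACGTN", "TGCAN")

FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100


def sam_header(index: FmIndex) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": len(bases)}
                for name, bases in index.genome.sequences
            ],
            "RG": [{"ID": "default", "SM": "sample"}],
            "PG": [{"ID": "livemapper", "PN": "livemapper", "VN": __version__}],
        }
    )


def _oriented(read: ReadState, seed: SeedState | None, index: FmIndex):
    """Sequence, qualities and CIGAR in SAM (forward-reference) orientation."""
    seq = "".join(CODE_TO_BASE[c] for c in read.bases)
    quals = list(read.quals)
    if seed is None:
        return seq, quals, None, None
    name, pos, strand = placement(seed, index)
    cigar = [(op, ln) for op, ln in seed.cigar]
    if strand == "-":
        seq = seq.translate(_COMP)[::-1]
        quals = quals[::-1]
        cigar = cigar[::-1]
    return seq, quals, (name, pos, strand), cigar


_CIGAR_OP_NUM = {"M": 0, "I": 1, "D": 2, "S": 4}


def to_sam_record(
    read: ReadState,
    seed: SeedState | None,
    tie_count: int,
    cycle: int,
    header: pysam.AlignmentHeader,
    index: FmIndex,
    *,
    paired: bool,
    secondary: bool = False,
) -> pysam.AlignedSegment:
    """Build one SAM record for a read's best seed (or an unmapped record).

    MAPQ is 37 for a unique best placement and 0 when the top score is tied;
    1-based POS comes from the forward-strand conversion of the seed's text
    placement.  Mate fields are filled in afterwards by the writer.
    """
    rec = pysam.AlignedSegment(header)
    seq, quals, place, cigar = _oriented(read, seed, index)
    rec.query_name = read.qname
    flag = 0
    if paired:
        flag |= FLAG_PAIRED
        flag |= FLAG_READ1 if read.mate == 0 else FLAG_READ2
    if seed is None:
        rec.flag = flag | FLAG_UNMAPPED
        rec.query_sequence = seq
        rec.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in quals)
        )
        return rec
    name, pos, strand = place
    if strand == "-":
        flag |= FLAG_REVERSE
    if secondary:
        flag |= FLAG_SECONDARY
    rec.flag = flag
    rec.reference_id = header.get_tid(name)
    rec.reference_start = pos
    rec.mapping_quality = 37 if tie_count == 1 else 0
    rec.cigartuples = [(_CIGAR_OP_NUM[op], ln) for op, ln in cigar if ln > 0]
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in quals)
    )
    rec.set_tags(
        [
            ("NM", seed.errors, "i"),
            ("AS", seed.score, "i"),
            ("XC", cycle, "i"),
            ("RG", "default", "Z"),
        ]
    )
    return rec


def _pair_up(records: list[pysam.AlignedSegment]) -> None:
    """Fill RNEXT/PNEXT/TLEN and mate flags for mate pairs present together.

    TLEN is only set when both mates mapped to the same reference at this
    output cycle; otherwise mate fields stay '*'/0 and the mate-unmapped
    flag is set."""
    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    for rec in records:
        if not rec.flag & FLAG_PAIRED or rec.flag & FLAG_SECONDARY:
            continue
        by_name.setdefault(rec.query_name, []).append(rec)
    for recs in by_name.values():
        r1 = next((r for r in recs if r.flag & FLAG_READ1), None)
        r2 = next((r for r in recs if r.flag & FLAG_READ2), None)
        for this, other in ((r1, r2), (r2, r1)):
            if this is None:
                continue
            if other is None or other.is_unmapped:
                this.flag |= FLAG_MATE_UNMAPPED
                continue
            if this.is_unmapped:
                continue
            if other.flag & FLAG_REVERSE:
                this.flag |= FLAG_MATE_REVERSE
            if this.reference_id == other.reference_id:
                this.next_reference_id = other.reference_id
                this.next_reference_start = other.reference_start
                left = min(this.reference_start, other.reference_start)
                right = max(
                    this.reference_start + this.reference_length,
                    other.reference_start + other.reference_length,
                )
                span = right - left
                this.template_length = (
                    span if this.reference_start <= other.reference_start else -span
                )


def write_cycle_output(
    tiles: list[TileState],
    index: FmIndex,
    settings: AlignmentSettings,
    cycle: int,
    path: str | Path,
    *,
    mode: str = "best",
) -> Path:
    """Write one SAM file for an output cycle across all tiles.

    ``mode='best'`` reports one best alignment per read (unmapped record when
    none qualifies); ``mode='all'`` additionally reports every other live
    seed passing the minimum score as a secondary record.
    """
    if mode not in ("best", "all"):
        raise ValueError(f"unknown output mode {mode!r}")
    header = sam_header(index)
    paired = len(tiles[0].layout.reads) > 1 if tiles else False
    records: list[pysam.AlignedSegment] = []
    for tile in tiles:
        for frag in tile.fragments:
            for read in frag:
                if not read.bases:
                    continue  # this mate has not started sequencing yet
                best, ties = select_best(read, settings, index)
                records.append(
                    to_sam_record(
                        read, best, ties, cycle, header, index, paired=paired
                    )
                )
                if mode == "all" and best is not None:
                    threshold = min_score(settings, len(read.bases))
                    for seed in read.seeds.values():
                        if seed is best or seed.score < threshold:
                            continue
                        records.append(
                            to_sam_record(
                                read,
                                seed,
                                ties,
                                cycle,
                                header,
                                index,
                                paired=paired,
                                secondary=True,
                            )
                        )
    _pair_up(records)
    records.sort(
        key=lambda r: (
            r.is_unmapped,
            r.reference_id if not r.is_unmapped else 0,
            r.reference_start if not r.is_unmapped else 0,
            r.query_name,
            r.flag,
        )
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for rec in records:
            fh.write(rec)
    return path
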