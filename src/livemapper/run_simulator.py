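"""Sequencing-run simulator: turn paired reads into a timed cycle stream.

Reads (from FASTQ or the synthetic generator) are distributed round-robin
over the tiles of a :class:`~livemapper.basecall_io.RunLayout` and written
out cycle by cycle as BCL files, optionally throttled to a fixed number of
seconds per cycle.  A timestamp log (``cycle<TAB>epoch_seconds``) records
when each cycle's data became complete; it is the single time source for
turnaround-time measurements.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .basecall_io import RunLayout, cycle_file_path, write_cycle


@dataclass(frozen=True)
class PairedRead:
    """One cluster: mate sequences and Phred qualities (integers)."""

    name: str
    mates: tuple[tuple[str, tuple[int, ...]], ...]  # ((bases, quals), ...)


@dataclass(frozen=True)
class TimingModel:
    seconds_per_cycle: float = 0.0
    start_time: float | None = None  # None = now


def load_fastq_pair(fastq1: str | Path, fastq2: str | Path | None) -> list[PairedRead]:
    """Load one or two FASTQ files into paired-read records (qualities capped at 63)."""

    def _load(path):
        out = []
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = tuple(
                min(63, q) for q in rec.letter_annotations["phred_quality"]
            )
            out.append((rec.id, str(rec.seq).upper(), quals))
        return out

    r1 = _load(fastq1)
    if fastq2 is None:
        return [PairedRead(n, ((s, q),)) for n, s, q in r1]
    r2 = _load(fastq2)
    if len(r1) != len(r2):
        raise ValueError("mate FASTQ files have different read counts")
    return [
        PairedRead(n1, ((s1, q1), (s2, q2)))
        for (n1, s1, q1), (_, s2, q2) in zip(r1, r2)
    ]


def assign_tiles(
    reads: Sequence[PairedRead], layout: RunLayout
) -> dict[tuple[int, int], list[PairedRead]]:
    """Round-robin assignment of reads to (lane, tile) slots by input order."""
    slots = [(lane, tile) for lane in layout.lanes for tile in layout.tiles]
    groups: dict[tuple[int, int], list[PairedRead]] = {s: [] for s in slots}
    for i, read in enumerate(reads):
        groups[slots[i % len(slots)]].append(read)
    return groups


def simulate_run(
    reads: Sequence[PairedRead],
    layout: RunLayout,
    timing: TimingModel,
    out_dir: str | Path,
    *,
    log_path: str | Path | None = None,
) -> Path:
    """Write every (lane, tile, cycle) BCL file in cycle order plus the log.

    Read lengths are validated against the layout before anything is written.
    Returns the path of the timestamp log.
    """
    for read in reads:
        if len(read.mates) != len(layout.reads):
            raise ValueError(
                f"read {read.name!r} has {len(read.mates)} mates, "
                f"layout expects {len(layout.reads)}"
            )
        for mate, rlen in zip(read.mates, layout.reads):
            if len(mate[0]) != rlen or len(mate[1]) != rlen:
                raise ValueError(
                    f"read {read.name!r} length {len(mate[0])} != layout {rlen}"
                )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = Path(log_path) if log_path else out_dir / "cycle_times.log"
    groups = assign_tiles(reads, layout)

    start = timing.start_time if timing.start_time is not None else time.time()
    with open(log_path, "w") as log:
        for cycle in range(1, layout.total_cycles + 1):
            if timing.seconds_per_cycle > 0:
                target = start + cycle * timing.seconds_per_cycle
                delay = target - time.time()
                if delay > 0:
                    time.sleep(delay)
            read_idx, local = layout.read_of_cycle(cycle)
            for (lane, tile), tile_reads in groups.items():
                calls = [
                    (r.mates[read_idx][0][local - 1], r.mates[read_idx][1][local - 1])
                    for r in tile_reads
                ]
                write_cycle(cycle_file_path(out_dir, lane, tile, cycle), calls)
            log.write(f"{cycle}\t{time.time():.3f}\n")
            log.flush()
    return log_path


def reassemble_reads(
    run_dir: str | Path, layout: RunLayout
) -> dict[tuple[int, int], list[tuple[tuple[str, tuple[int, ...]], ...]]]:
    """Decode a run folder back into per-tile reads (bases and qualities).

    The inverse of :func:`simulate_run` up to the N -> quality-0 rule; used
    by round-trip tests and by batch replay.
    """
    from .basecall_io import read_cycle

    out: dict[tuple[int, int], list] = {}
    for lane in layout.lanes:
        for tile in layout.tiles:
            per_mate: list[list[list[str]]] = [[] for _ in layout.reads]
            per_mate_q: list[list[list[int]]] = [[] for _ in layout.reads]
            n = None
            for cycle in range(1, layout.total_cycles + 1):
                read_idx, _ = layout.read_of_cycle(cycle)
                calls = read_cycle(cycle_file_path(run_dir, lane, tile, cycle))
                if n is None:
                    n = len(calls)
                    for m in range(len(layout.reads)):
                        per_mate[m] = [[] for _ in range(n)]
                        per_mate_q[m] = [[] for _ in range(n)]
                elif len(calls) != n:
                    raise ValueError(
                        f"tile {tile} cycle {cycle}: cluster count changed"
                    )
                for i, (b, q) in enumerate(calls):
                    per_mate[read_idx][i].append(b)
                    per_mate_q[read_idx][i].append(q)
            reads = []
            for i in range(n or 0):
                reads.append(
                    tuple(
                        ("".join(per_mate[m][i]), tuple(per_mate_q[m][i]))
                        for m in range(len(layout.reads))
                    )
                )
            out[(lane, tile)] = reads
    return out
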