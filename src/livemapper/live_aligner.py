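"""Cycle-incremental seed-and-extend mapping engine.

Reads grow by one base per sequencing cycle.  Once a read is k bases long,
every error-free occurrence of its most recent k-mer in the doubled
reference text becomes an *anchor* (a live alignment hypothesis); new
anchors of the same length are created every ``seeding_interval`` cycles, so
a read whose early bases are wrong can still be placed later, with the
unalignable prefix reported as a softclip.  Anchored alignments are extended
in the direction of sequencing only, tolerating one additional error per
``error_interval`` cycles of aligned length; hypotheses that exceed the
budget die.  At user-chosen output cycles the best hypothesis per read that
reaches the length-relative minimum score is reported.

Tiles are processed independently (the natural unit of parallelism on a
real sequencer); the engine itself is single-threaded and deterministic.
"""

from __future__ import annotations

import hashlib
import pickle
import time
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

from .basecall_io import (
    RunLayout,
    cycle_file_path,
    discover_ready_cycles,
    read_cycle,
)
from .reference_index import BASE_TO_CODE, FmIndex

MODES = ("very-fast", "fast", "balanced", "accurate", "very-accurate")

# mode -> (anchor_length, seeding_interval, error_interval, min_as_fraction)
_MODE_TABLE = {
    "very-fast": (14, 10, 24, 0.45),
    "fast": (12, 8, 20, 0.5),
    "balanced": (12, 6, 16, 0.55),
    "accurate": (12, 4, 12, 0.65),
    "very-accurate": (12, 3, 10, 0.7),
}
_SHORT_READ_MAX = 60  # reads this short get adapted (smaller) parameters


class AlignerError(ValueError):
    pass


class CheckpointError(ValueError):
    """Checkpoint cannot be used (version or settings mismatch)."""


@dataclass(frozen=True)
class AlignmentSettings:
    """All knobs of the engine; see :func:`auto_configure` for mode presets."""

    mode: str = "fast"
    anchor_length: int = 12
    seeding_interval: int = 8
    error_interval: int = 20
    min_as_fraction: float = 0.5
    max_indel_length: int = 3
    match_score: int = 1
    mismatch_penalty: int = 2
    gap_open_penalty: int = 3
    gap_extend_penalty: int = 1
    locate_cap: int = 100
    output_cycles: tuple[int, ...] = (30, 40, 55, 75, 100)  # read-local

    def __post_init__(self) -> None:
        if self.anchor_length < 8:
            raise AlignerError("anchor_length must be >= 8")
        if self.seeding_interval > self.anchor_length:
            raise AlignerError("seeding_interval must be <= anchor_length")
        if self.error_interval < 1 or self.max_indel_length < 0:
            raise AlignerError("bad error_interval / max_indel_length")
        if not 0 < self.min_as_fraction <= 1:
            raise AlignerError("min_as_fraction must be in (0, 1]")

    def digest(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(payload).hexdigest()


def auto_configure(mode: str, genome_size: int, read_length: int) -> AlignmentSettings:
    """Settings for a mode, genome size and read length.

    Short reads (<= 60 cycles) get smaller anchors and tighter intervals so
    that first output is possible by cycle 30; every field can be overridden
    afterwards with :func:`dataclasses.replace`.
    """
    if mode not in _MODE_TABLE:
        raise AlignerError(f"unknown mode {mode!r}; choose from {MODES}")
    if genome_size < 1:
        raise AlignerError("genome_size must be >= 1")
    if read_length < 20:
        raise AlignerError("read_length must be >= 20")
    k, s, e, f = _MODE_TABLE[mode]
    if read_length <= _SHORT_READ_MAX:
        k, s, e = max(8, k - 2), max(1, s - 2), max(1, e - 4)
    if read_length < k:
        raise AlignerError(f"read length {read_length} shorter than anchor {k}")
    out = tuple(c for c in (30, 40, 55, 75, 100) if c <= read_length)
    if not out or out[-1] != read_length:
        out = out + (read_length,)
    return AlignmentSettings(
        mode=mode,
        anchor_length=k,
        seeding_interval=s,
        error_interval=e,
        min_as_fraction=f,
        output_cycles=out,
    )


def allowed_errors(settings: AlignmentSettings, aligned_length: int) -> int:
    """Errors permitted for an alignment of the given aligned length.

    Zero at the anchor (anchors are error-free) and one more per
    ``error_interval`` additional cycles.
    """
    if aligned_length < settings.anchor_length:
        raise AlignerError("aligned length shorter than the anchor")
    return (aligned_length - settings.anchor_length) // settings.error_interval


def min_score(settings: AlignmentSettings, sequenced_length: int) -> int:
    """Minimum alignment score for a read of this length to be reported."""
    return ceil(settings.min_as_fraction * settings.match_score * sequenced_length)


class SeedState:
    """One live alignment hypothesis of one read.

    ``start``/``next_pos`` are offsets in the doubled indexed text; ``diag``
    is ``next_pos`` minus the read cycles consumed, i.e. the alignment
    diagonal (shifts under indels).  The CIGAR is kept in sequencing
    orientation; a non-initial seed starts with its softclip run.
    """

    __slots__ = ("start", "next_pos", "softclip", "cigar", "errors", "score", "diag")

    def __init__(self, start, next_pos, softclip, cigar, errors, score, diag):
        self.start = start
        self.next_pos = next_pos
        self.softclip = softclip
        self.cigar = cigar  # list of [op, length]
        self.errors = errors
        self.score = score
        self.diag = diag

    def clone(self) -> "SeedState":
        return SeedState(
            self.start,
            self.next_pos,
            self.softclip,
            [run[:] for run in self.cigar],
            self.errors,
            self.score,
            self.diag,
        )

    def cigar_string(self) -> str:
        return "".join(f"{l}{op}" for op, l in self.cigar)

    def ref_span(self) -> int:
        return self.next_pos - self.start

    # pickling support for __slots__
    def __getstate__(self):
        return tuple(getattr(self, s) for s in self.__slots__)

    def __setstate__(self, state):
        for s, v in zip(self.__slots__, state):
            setattr(self, s, v)


class ReadState:
    """Bases, qualities and live seeds of one read (one mate of a cluster)."""

    __slots__ = ("qname", "mate", "bases", "quals", "seeds")

    def __init__(self, qname: str, mate: int):
        self.qname = qname
        self.mate = mate  # 0-based mate index
        self.bases: list[int] = []  # alphabet codes; N stored as SEP
        self.quals: list[int] = []
        self.seeds: dict[tuple[int, int, int], SeedState] = {}

    def __getstate__(self):
        return (self.qname, self.mate, self.bases, self.quals, self.seeds)

    def __setstate__(self, state):
        self.qname, self.mate, self.bases, self.quals, self.seeds = state


@dataclass
class TileState:
    """All read states of one (lane, tile), advanced cycle by cycle."""

    lane: int
    tile: int
    layout: RunLayout
    cycle: int = 0  # last fully processed global cycle
    fragments: list[tuple[ReadState, ...]] = field(default_factory=list)

    def reads_of_mate(self, mate: int) -> list[ReadState]:
        return [frag[mate] for frag in self.fragments]


def _seed_key(seed: SeedState) -> tuple[int, int, int]:
    """Dedup key: diagonal, softclip, and the open insertion-run length.

    Seeds mid-insertion are not interchangeable with seeds whose gap is
    closed even on the same diagonal (they have different extension
    futures), so the gap state is part of the hypothesis identity.  This
    still bounds live seeds per diagonal to 1 + max_indel_length.
    """
    last = seed.cigar[-1]
    return (seed.diag, seed.softclip, last[1] if last[0] == "I" else 0)


def _offer(seeds: dict, key: tuple[int, int, int], cand: SeedState) -> None:
    """Keep the best hypothesis per key: score, then fewer errors, then
    leftmost text position."""
    cur = seeds.get(key)
    if cur is None or (cand.score, -cand.errors, -cand.start) > (
        cur.score,
        -cur.errors,
        -cur.start,
    ):
        seeds[key] = cand


def extend_seeds(read: ReadState, settings: AlignmentSettings, text: bytes) -> None:
    """Consume the read's newest base with every live seed.

    Match/mismatch extends the M run; when the error budget allows, seeds
    branch into insertion and deletion variants (a gap run costs gap_open +
    gap_extend per extra base and one error in total).  Seeds exceeding
    ``allowed_errors`` of their aligned length die, as do seeds running off
    the end of their reference segment.
    """
    if not read.seeds:
        return
    b = read.bases[-1]
    L_seq = len(read.bases)
    k = settings.anchor_length
    e = settings.error_interval
    match = settings.match_score
    mm = settings.mismatch_penalty
    go = settings.gap_open_penalty
    ge = settings.gap_extend_penalty
    maxi = settings.max_indel_length
    textlen = len(text)

    new: dict[tuple[int, int, int], SeedState] = {}
    for seed in read.seeds.values():
        allowed = (L_seq - seed.softclip - k) // e
        last_op = seed.cigar[-1][0]
        np_ = seed.next_pos

        if seed.errors + 1 <= allowed and maxi > 0:
            if last_op == "M":
                # open an insertion (read base consumed, no reference)
                cand = seed.clone()
                cand.cigar.append(["I", 1])
                cand.errors += 1
                cand.score -= go
                cand.diag -= 1
                _offer(new, _seed_key(cand), cand)
                # deletions: skip d reference bases, then place this base
                for d in range(1, maxi + 1):
                    p = np_ + d
                    if p >= textlen:
                        break
                    cref = text[p]
                    if cref < 2:  # separator: reference segment ends
                        break
                    cand = seed.clone()
                    cand.cigar.append(["D", d])
                    cand.cigar.append(["M", 1])
                    cand.score -= go + (d - 1) * ge
                    cand.errors += 1
                    if cref == b:
                        cand.score += match
                    else:
                        cand.errors += 1
                        cand.score -= mm
                        if cand.errors > allowed:
                            continue
                    cand.next_pos = p + 1
                    cand.diag += d
                    _offer(new, _seed_key(cand), cand)
            elif last_op == "I" and seed.cigar[-1][1] < maxi:
                cand = seed.clone()
                cand.cigar[-1][1] += 1
                cand.score -= ge
                cand.diag -= 1
                _offer(new, _seed_key(cand), cand)

        # plain M continuation (mutates the seed; branches cloned it above)
        if np_ < textlen:
            cref = text[np_]
            if cref >= 2:
                if cref == b:
                    seed.score += match
                else:
                    seed.errors += 1
                    seed.score -= mm
                seed.next_pos = np_ + 1
                last = seed.cigar[-1]
                if last[0] == "M":
                    last[1] += 1
                else:
                    seed.cigar.append(["M", 1])
                if seed.errors <= allowed:
                    _offer(new, _seed_key(seed), seed)
    read.seeds = new


def seed_new_anchors(
    read: ReadState, index: FmIndex, settings: AlignmentSettings
) -> None:
    """Create anchors from the most recently sequenced k-mer.

    Called at read-local cycles k, k + s, k + 2s, ...; a k-mer containing an
    N yields no anchors, and placements already covered by a live seed on
    the same diagonal are not re-created.
    """
    k = settings.anchor_length
    L_seq = len(read.bases)
    kmer = read.bases[-k:]
    if min(kmer) < 2:  # contains N
        return
    interval = index.backward_search(kmer)
    offsets, _repetitive = index.locate_offsets(interval, settings.locate_cap)
    if not offsets:
        return
    softclip = L_seq - k
    live_diags = {key[0] for key in read.seeds}
    score = k * settings.match_score
    for o in offsets:
        diag = o + k - L_seq
        if diag in live_diags:
            continue
        cigar = [["S", softclip]] if softclip else []
        cigar.append(["M", k])
        read.seeds[(diag, softclip, 0)] = SeedState(
            o, o + k, softclip, cigar, 0, score, diag
        )


def is_seeding_cycle(local_cycle: int, settings: AlignmentSettings) -> bool:
    k, s = settings.anchor_length, settings.seeding_interval
    return local_cycle >= k and (local_cycle - k) % s == 0


def process_cycle(
    tile: TileState,
    calls: list[tuple[str, int]],
    index: FmIndex,
    settings: AlignmentSettings,
    cycle: int,
) -> None:
    """Advance one tile by one global cycle (extend, then seed)."""
    if cycle != tile.cycle + 1:
        raise AlignerError(
            f"tile {tile.tile}: got cycle {cycle}, expected {tile.cycle + 1}"
        )
    mate, local = tile.layout.read_of_cycle(cycle)
    if not tile.fragments:
        tile.fragments = [
            tuple(
                ReadState(f"L{tile.lane}T{tile.tile}C{i:06d}", m)
                for m in range(len(tile.layout.reads))
            )
            for i in range(len(calls))
        ]
    if len(calls) != len(tile.fragments):
        raise AlignerError(
            f"tile {tile.tile} cycle {cycle}: {len(calls)} calls for "
            f"{len(tile.fragments)} clusters"
        )
    text = getattr(index, "_text_bytes", None)
    if text is None:
        text = index.indexed.text.tobytes()
        index._text_bytes = text
    seeding = is_seeding_cycle(local, settings)
    for frag, (base, qual) in zip(tile.fragments, calls):
        read = frag[mate]
        read.bases.append(BASE_TO_CODE[base])
        read.quals.append(qual)
        extend_seeds(read, settings, text)
        if seeding:
            seed_new_anchors(read, index, settings)
    tile.cycle = cycle


def select_best(
    read: ReadState, settings: AlignmentSettings, index: FmIndex
) -> tuple[SeedState | None, int]:
    """Best reportable seed at the current cycle plus the score-tie count.

    Seeds must reach the length-relative minimum score.  Ties on score break
    by fewer errors, longer aligned length, then lexicographically smallest
    (name, forward position, strand); the tie count (seeds sharing the top
    score) drives MAPQ.
    """
    L_seq = len(read.bases)
    if L_seq < settings.anchor_length or not read.seeds:
        return None, 0
    threshold = min_score(settings, L_seq)
    cands = [s for s in read.seeds.values() if s.score >= threshold]
    if not cands:
        return None, 0
    best_score = max(s.score for s in cands)
    top = [s for s in cands if s.score == best_score]

    def order(s: SeedState):
        name, pos, strand = placement(s, index)
        return (s.errors, s.softclip, name, pos, 0 if strand == "+" else 1)

    return min(top, key=order), len(top)


def placement(seed: SeedState, index: FmIndex) -> tuple[str, int, str]:
    """Forward-strand (name, 0-based SAM start, strand) of a seed."""
    idx = index.indexed
    seg = idx.segment_at(seed.start)
    if seg.strand == "+":
        return seg.name, seed.start - seg.start, "+"
    # reverse-strand: SAM start is the forward position of the last ref base
    name, pos, _ = idx.offset_map(seed.next_pos - 1)
    return seg.name, pos, "-"


# ---------------------------------------------------------------------------
# checkpoint / resume

_CKPT_VERSION = 1


def checkpoint_save(tile: TileState, settings: AlignmentSettings, path: str | Path) -> None:
    payload = {
        "version": _CKPT_VERSION,
        "cycle": tile.cycle,
        "settings_digest": settings.digest(),
        "tile": tile,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump(payload, fh, protocol=4)


def checkpoint_resume(path: str | Path, settings: AlignmentSettings) -> TileState:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != _CKPT_VERSION:
        raise CheckpointError(f"unsupported checkpoint version in {path}")
    if payload["settings_digest"] != settings.digest():
        raise CheckpointError(
            "checkpoint was written with different alignment settings"
        )
    return payload["tile"]


# ---------------------------------------------------------------------------
# run drivers

def global_output_cycles(settings: AlignmentSettings, layout: RunLayout) -> list[int]:
    """Translate read-local output cycles into global cycle numbers."""
    cycles = []
    offset = 0
    for rlen in layout.reads:
        cycles.extend(offset + c for c in settings.output_cycles if c <= rlen)
        offset += rlen
    return sorted(set(cycles))


def _make_tiles(layout: RunLayout) -> list[TileState]:
    return [
        TileState(lane, tile, layout)
        for lane in layout.lanes
        for tile in layout.tiles
    ]


def run_mapping(
    index: FmIndex,
    settings: AlignmentSettings,
    layout: RunLayout,
    run_dir: str | Path,
    out_dir: str | Path,
    *,
    live: bool = False,
    poll_interval: float = 0.05,
    timeout: float = 600.0,
    checkpoint_dir: str | Path | None = None,
    output_mode: str = "best",
) -> dict[int, Path]:
    """Map a run folder, writing one SAM per output cycle.

    In batch mode all cycles are replayed immediately; with ``live=True`` the
    run directory is polled and cycles are consumed as they become complete.
    Both paths produce byte-identical output.  Returns {cycle: sam path}.
    """
    from .alignment_output import write_cycle_output

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiles = _make_tiles(layout)
    out_cycles = set(global_output_cycles(settings, layout))
    written: dict[int, Path] = {}
    last = 0
    deadline = time.monotonic() + timeout
    while last < layout.total_cycles:
        ready = discover_ready_cycles(run_dir, layout, last)
        if not ready:
            if not live:
                raise AlignerError(
                    f"run folder incomplete: cycle {last + 1} missing in batch mode"
                )
            if time.monotonic() > deadline:
                raise AlignerError(f"timed out waiting for cycle {last + 1}")
            time.sleep(poll_interval)
            continue
        for cycle in ready:
            for tile in tiles:
                calls = read_cycle(
                    cycle_file_path(run_dir, tile.lane, tile.tile, cycle)
                )
                process_cycle(tile, calls, index, settings, cycle)
            if cycle in out_cycles:
                path = out_dir / f"cycle_{cycle}.sam"
                write_cycle_output(tiles, index, settings, cycle, path, mode=output_mode)
                written[cycle] = path
                if checkpoint_dir is not None:
                    for tile in tiles:
                        checkpoint_save(
                            tile,
                            settings,
                            Path(checkpoint_dir)
                            / f"cycle_{cycle}_L{tile.lane}_T{tile.tile}.ckpt",
                        )
            last = cycle
    return written


def resume_mapping(
    index: FmIndex,
    settings: AlignmentSettings,
    layout: RunLayout,
    run_dir: str | Path,
    out_dir: str | Path,
    checkpoint_dir: str | Path,
    resume_cycle: int,
    *,
    output_mode: str = "best",
) -> dict[int, Path]:
    """Continue an interrupted run from per-tile checkpoints at resume_cycle."""
    from .alignment_output import write_cycle_output

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiles = [
        checkpoint_resume(
            Path(checkpoint_dir) / f"cycle_{resume_cycle}_L{lane}_T{tile}.ckpt",
            settings,
        )
        for lane in layout.lanes
        for tile in layout.tiles
    ]
    out_cycles = set(global_output_cycles(settings, layout))
    written: dict[int, Path] = {}
    for cycle in range(resume_cycle + 1, layout.total_cycles + 1):
        for tile in tiles:
            calls = read_cycle(cycle_file_path(run_dir, tile.lane, tile.tile, cycle))
            process_cycle(tile, calls, index, settings, cycle)
        if cycle in out_cycles:
            path = out_dir / f"cycle_{cycle}.sam"
            write_cycle_output(tiles, index, settings, cycle, path, mode=output_mode)
            written[cycle] = path
    return written


def reemit_output(
    checkpoint_paths: list[str | Path],
    index: FmIndex,
    settings: AlignmentSettings,
    cycle: int,
    path: str | Path,
    *,
    mode: str = "best",
) -> Path:
    """Re-write the output of an already-processed cycle from its checkpoints,
    e.g. with all qualifying alignments instead of the single best, without
    recomputing any alignment."""
    from .alignment_output import write_cycle_output

    tiles = [checkpoint_resume(p, settings) for p in checkpoint_paths]
    for tile in tiles:
        if tile.cycle != cycle:
            raise CheckpointError(
                f"checkpoint at cycle {tile.cycle} cannot re-emit cycle {cycle}"
            )
    write_cycle_output(tiles, index, settings, cycle, path, mode=mode)
    return Path(path)
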