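"""Per-tile, per-cycle base-call (BCL) file dialect and run-folder layout.

One file per (lane, tile, cycle) under ``run/L00<lane>/C<cycle>.1/
s_<lane>_<tile>.bcl``: a little-endian uint32 cluster count N followed by N
payload bytes, each ``(quality << 2) | base`` with A=0, C=1, G=2, T=3.  The
zero byte is the no-call: it decodes as ('N', 0).  Files are uncompressed so
round trips are bit-exact.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

_BASE2BIT = {"A": 0, "C": 1, "G": 2, "T": 3}
_BIT2BASE = "ACGT"


class BclFormatError(ValueError):
    """Raised for truncated files or count/payload mismatches."""


@dataclass(frozen=True)
class RunLayout:
    """Geometry of a sequencing run: lanes, tiles per lane, read lengths.

    Cycle numbering is 1-based and global across reads: for reads [R1, R2],
    read 2 occupies global cycles R1+1 .. R1+R2.
    """

    lanes: tuple[int, ...] = (1,)
    tiles: tuple[int, ...] = (1,)
    reads: tuple[int, ...] = (100, 100)

    def __post_init__(self) -> None:
        if not self.lanes or not self.tiles:
            raise ValueError("layout needs at least one lane and one tile")
        if not self.reads or any(r < 1 for r in self.reads):
            raise ValueError("read lengths must be >= 1")

    @property
    def total_cycles(self) -> int:
        return sum(self.reads)

    def read_of_cycle(self, cycle: int) -> tuple[int, int]:
        """Map a global cycle to (read index, 1-based read-local cycle)."""
        if not 1 <= cycle <= self.total_cycles:
            raise ValueError(f"cycle {cycle} outside run of {self.total_cycles}")
        offset = 0
        for i, rlen in enumerate(self.reads):
            if cycle <= offset + rlen:
                return i, cycle - offset
            offset += rlen
        raise AssertionError("unreachable")


def cycle_file_path(run_dir: str | Path, lane: int, tile: int, cycle: int) -> Path:
    return Path(run_dir) / f"L{lane:03d}" / f"C{cycle}.1" / f"s_{lane}_{tile}.bcl"


def encode_call(base: str, quality: int) -> int:
    """Encode one base call as a single BCL byte; N forces the zero byte."""
    if not 0 <= quality <= 63:
        raise ValueError(f"quality {quality} outside 0..63")
    if base == "N":
        return 0
    if base not in _BASE2BIT:
        raise ValueError(f"illegal base {base!r}")
    return (quality << 2) | _BASE2BIT[base]


def decode_call(byte: int) -> tuple[str, int]:
    """Inverse of :func:`encode_call`; byte 0 is the no-call ('N', 0)."""
    if byte == 0:
        return "N", 0
    return _BIT2BASE[byte & 3], byte >> 2


def write_cycle(path: str | Path, calls: list[tuple[str, int]]) -> None:
    """Write one tile's calls for one cycle (count header + payload)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = bytes(encode_call(b, q) for b, q in calls)
    with open(path, "wb") as fh:
        fh.write(struct.pack("<I", len(calls)))
        fh.write(payload)


def read_cycle(path: str | Path) -> list[tuple[str, int]]:
    with open(path, "rb") as fh:
        head = fh.read(4)
        if len(head) != 4:
            raise BclFormatError(f"{path}: missing count header")
        (n,) = struct.unpack("<I", head)
        payload = fh.read()
    if len(payload) != n:
        raise BclFormatError(
            f"{path}: count says {n} clusters but payload has {len(payload)} bytes"
        )
    return [decode_call(b) for b in payload]


def cycle_is_complete(path: Path) -> bool:
    """A cycle file is complete when its size is exactly 4 + its own count."""
    try:
        size = path.stat().st_size
    except OSError:
        return False
    if size < 4:
        return False
    with open(path, "rb") as fh:
        (n,) = struct.unpack("<I", fh.read(4))
    return size == 4 + n


def discover_ready_cycles(
    run_dir: str | Path, layout: RunLayout, last_seen: int
) -> list[int]:
    """Cycles after ``last_seen`` for which every tile's file is complete.

    Cycles are reported contiguously in order (a complete later cycle behind
    a missing one is withheld until the gap fills), so repeated calls are
    monotone non-decreasing.
    """
    ready: list[int] = []
    for cycle in range(last_seen + 1, layout.total_cycles + 1):
        ok = all(
            cycle_is_complete(cycle_file_path(run_dir, lane, tile, cycle))
            for lane in layout.lanes
            for tile in layout.tiles
        )
        if not ok:
            break
        ready.append(cycle)
    return ready
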