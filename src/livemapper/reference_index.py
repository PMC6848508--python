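"""Reference genome model and FM-index used for anchor seeding.

The index is built over the *strand-doubled* text: the forward sequence of
every reference record followed by the reverse complement of every record,
with separator characters between segments.  Matching a read k-mer against
this text finds both forward- and reverse-strand placements with a single
backward search, and seed extension is always rightward in text coordinates;
conversion back to forward-strand SAM coordinates happens only at output.

Alphabet codes used throughout the package::

    0  terminal sentinel (one per index, smallest)
    1  separator / N
    2..5  A, C, G, T
"""

from __future__ import annotations

import pickle
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

SENTINEL = 0
SEP = 1
CODE_A, CODE_C, CODE_G, CODE_T = 2, 3, 4, 5

BASE_TO_CODE = {"A": CODE_A, "C": CODE_C, "G": CODE_G, "T": CODE_T, "N": SEP}
CODE_TO_BASE = {SEP: "N", CODE_A: "A", CODE_C: "C", CODE_G: "G", CODE_T: "T"}
# complement in code space: A<->T, C<->G; separator is its own complement
CODE_COMPLEMENT = np.array([0, 1, 5, 4, 3, 2], dtype=np.uint8)

_MAGIC = b"LVIX"
_FORMAT_VERSION = 1


class ReferenceError(ValueError):
    """Invalid reference genome (empty, duplicate names, bad alphabet)."""


class IndexFormatError(ValueError):
    """Index file is truncated, has the wrong magic or an unknown version."""


def encode_bases(s: str) -> np.ndarray:
    """Encode an A/C/G/T/N string into the package's code alphabet."""
    out = np.empty(len(s), dtype=np.uint8)
    for i, ch in enumerate(s):
        out[i] = BASE_TO_CODE[ch]
    return out


def decode_bases(codes: Iterable[int]) -> str:
    return "".join(CODE_TO_BASE[int(c)] for c in codes)


def revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass(frozen=True)
class ReferenceGenome:
    """An ordered multi-FASTA reference restricted to the A/C/G/T/N alphabet."""

    sequences: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ReferenceError("reference genome has no sequences")
        names = [n for n, _ in self.sequences]
        if len(set(names)) != len(names):
            raise ReferenceError("duplicate sequence names in reference")
        for name, bases in self.sequences:
            if not bases:
                raise ReferenceError(f"sequence {name!r} is empty")
            if set(bases) - set("ACGTN"):
                bad = sorted(set(bases) - set("ACGTN"))
                raise ReferenceError(
                    f"sequence {name!r} contains illegal characters {bad}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(b) for _, b in self.sequences)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.sequences]

    def get(self, name: str) -> str:
        for n, b in self.sequences:
            if n == name:
                return b
        raise KeyError(name)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        records = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(tuple(records))

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, bases in self.sequences:
                fh.write(f">{name}\n")
                for i in range(0, len(bases), width):
                    fh.write(bases[i : i + width] + "\n")


@dataclass(frozen=True)
class Segment:
    start: int  # text offset of first base
    length: int
    name: str
    strand: str  # '+' or '-'


class IndexedText:
    """Forward + reverse-complement concatenation with separators.

    ``text`` excludes the terminal sentinel; its length is
    ``2 * total_length + (number of inter-segment separators)``.
    ``offset_map`` is a bijection from non-separator text offsets to
    (sequence name, forward-strand 0-based position, strand).
    """

    def __init__(self, genome: ReferenceGenome):
        segs: list[Segment] = []
        chunks: list[np.ndarray] = []
        pos = 0
        for strand in "+-":
            for name, bases in genome.sequences:
                if strand == "+":
                    codes = encode_bases(bases)
                else:
                    codes = CODE_COMPLEMENT[encode_bases(bases)][::-1]
                if segs:  # separator between consecutive segments
                    chunks.append(np.array([SEP], dtype=np.uint8))
                    pos += 1
                segs.append(Segment(pos, len(codes), name, strand))
                chunks.append(codes)
                pos += len(codes)
        self.text: np.ndarray = np.concatenate(chunks)
        self.segments: tuple[Segment, ...] = tuple(segs)
        self._starts = [s.start for s in segs]
        self.n_separators = len(segs) - 1
        assert len(self.text) == 2 * genome.total_length + self.n_separators

    def __len__(self) -> int:
        return len(self.text)

    def segment_at(self, offset: int) -> Segment:
        i = bisect_right(self._starts, offset) - 1
        return self.segments[i]

    def offset_map(self, offset: int) -> tuple[str, int, str]:
        """Map a text offset to (name, forward-strand 0-based position, strand)."""
        seg = self.segment_at(offset)
        rel = offset - seg.start
        if rel >= seg.length:
            raise ValueError(f"offset {offset} falls on a separator")
        if seg.strand == "+":
            return seg.name, rel, "+"
        return seg.name, seg.length - 1 - rel, "-"

    def text_offset(self, name: str, position: int, strand: str) -> int:
        """Inverse of :meth:`offset_map`."""
        for seg in self.segments:
            if seg.name == name and seg.strand == strand:
                if not 0 <= position < seg.length:
                    raise ValueError("position out of range")
                rel = position if strand == "+" else seg.length - 1 - position
                return seg.start + rel
        raise KeyError((name, strand))


def _suffix_array(t: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), vectorized)."""
    n = len(t)
    rank = t.astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    k = 1
    while True:
        key1 = rank
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, key1))
        r1 = key1[sa]
        r2 = key2[sa]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new = np.cumsum(changed)
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = new
        if new[-1] == n - 1:
            return sa
        k *= 2


@dataclass(frozen=True)
class SaInterval:
    """Half-open interval [lower, upper) of suffix-array rows."""

    lower: int
    upper: int

    @property
    def width(self) -> int:
        return self.upper - self.lower

    @property
    def empty(self) -> bool:
        return self.upper <= self.lower


class FmIndex:
    """FM-index (BWT + C array + sampled occ/SA) over the doubled text.

    occ checkpoints are stored every ``occ_rate`` BWT positions and suffix
    array values for every text position divisible by ``sa_rate``; both are
    configurable at build time.
    """

    def __init__(
        self,
        genome: ReferenceGenome,
        *,
        occ_rate: int = 128,
        sa_rate: int = 32,
        _from_state: dict | None = None,
    ):
        if _from_state is not None:
            self.__dict__.update(_from_state)
            return
        self.genome = genome
        self.indexed = IndexedText(genome)
        self.occ_rate = int(occ_rate)
        self.sa_rate = int(sa_rate)
        text = np.concatenate(
            [self.indexed.text, np.array([SENTINEL], dtype=np.uint8)]
        )
        sa = _suffix_array(text)
        n = len(text)
        self.n_rows = n
        bwt = text[(sa - 1) % n]
        self.bwt = bwt
        # C array: counts[c] = number of text characters strictly smaller than c
        hist = np.bincount(text, minlength=6).astype(np.int64)
        self.counts = np.concatenate([[0], np.cumsum(hist)])[:6]
        # occ checkpoints: occ[j, c] = occurrences of c in bwt[: j*occ_rate]
        ncheck = n // self.occ_rate + 1
        onehot = np.zeros((n + 1, 6), dtype=np.int64)
        onehot[np.arange(1, n + 1), bwt] = 1
        cum = np.cumsum(onehot, axis=0)
        self.occ = cum[np.arange(ncheck) * self.occ_rate]
        # sampled SA: rows whose suffix position is divisible by sa_rate
        mask = sa % self.sa_rate == 0
        rows = np.flatnonzero(mask)
        self._sa_rows = rows
        self._sa_vals = sa[rows]
        self._sa_lookup = dict(zip(rows.tolist(), sa[rows].tolist()))

    # -- low-level queries ---------------------------------------------------

    def rank(self, c: int, i: int) -> int:
        """Occurrences of character c in bwt[:i]."""
        j = i // self.occ_rate
        base = int(self.occ[j, c])
        lo = j * self.occ_rate
        if lo == i:
            return base
        return base + int(np.count_nonzero(self.bwt[lo:i] == c))

    def lf(self, row: int) -> int:
        c = int(self.bwt[row])
        return int(self.counts[c]) + self.rank(c, row)

    def sa_value(self, row: int) -> int:
        steps = 0
        r = row
        while r not in self._sa_lookup:
            r = self.lf(r)
            steps += 1
        return (self._sa_lookup[r] + steps) % self.n_rows

    # -- search --------------------------------------------------------------

    def backward_search(self, pattern: str | Sequence[int]) -> SaInterval:
        """Exact backward search; patterns containing N give the empty interval.

        The empty pattern matches every suffix (width ``len(text) + 1``).
        """
        if isinstance(pattern, str):
            try:
                codes = [BASE_TO_CODE[ch] for ch in pattern]
            except KeyError as exc:
                raise ValueError(f"illegal pattern character {exc.args[0]!r}")
        else:
            codes = [int(c) for c in pattern]
        lo, hi = 0, self.n_rows
        for c in reversed(codes):
            if c <= SEP:  # N or separator never matches
                return SaInterval(0, 0)
            lo = int(self.counts[c]) + self.rank(c, lo)
            hi = int(self.counts[c]) + self.rank(c, hi)
            if lo >= hi:
                return SaInterval(0, 0)
        return SaInterval(lo, hi)

    def locate_offsets(self, interval: SaInterval, cap: int) -> tuple[list[int], bool]:
        """Text offsets for every row of the interval, or the repetitive flag.

        Returns ``(offsets, repetitive)``; when the interval is wider than
        ``cap`` no offsets are resolved and the repetitive flag is set.
        """
        if cap < 1:
            raise ValueError("cap must be >= 1")
        if interval.empty:
            return [], False
        if interval.width > cap:
            return [], True
        return (
            sorted(self.sa_value(r) for r in range(interval.lower, interval.upper)),
            False,
        )

    def locate(
        self, interval: SaInterval, cap: int
    ) -> tuple[list[tuple[str, int, str]], bool]:
        """Occurrences as (name, forward-strand position, strand), sorted."""
        offsets, repetitive = self.locate_offsets(interval, cap)
        hits = [self.indexed.offset_map(o) for o in offsets]
        return sorted(hits), repetitive

    def count(self, pattern: str | Sequence[int]) -> int:
        return self.backward_search(pattern).width

    # -- reconstruction / persistence ---------------------------------------

    def invert_bwt(self) -> np.ndarray:
        """Rebuild the text (sentinel excluded) from the BWT via LF-mapping."""
        n = self.n_rows
        out = np.empty(n - 1, dtype=np.uint8)
        r = 0  # row of the rotation starting at the sentinel
        for i in range(n - 2, -1, -1):
            out[i] = self.bwt[r]
            r = self.lf(r)
        return out

    def save(self, path: str | Path) -> None:
        state = {
            "genome_sequences": self.genome.sequences,
            "occ_rate": self.occ_rate,
            "sa_rate": self.sa_rate,
            "n_rows": self.n_rows,
            "bwt": self.bwt,
            "counts": self.counts,
            "occ": self.occ,
            "sa_rows": self._sa_rows,
            "sa_vals": self._sa_vals,
        }
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(bytes([_FORMAT_VERSION]))
            pickle.dump(state, fh, protocol=4)

    @classmethod
    def load(cls, path: str | Path) -> "FmIndex":
        with open(path, "rb") as fh:
            magic = fh.read(4)
            if magic != _MAGIC:
                raise IndexFormatError(f"bad magic {magic!r}; not a livemapper index")
            ver = fh.read(1)
            if len(ver) != 1 or ver[0] != _FORMAT_VERSION:
                raise IndexFormatError(
                    f"unsupported index format version {ver!r} "
                    f"(expected {_FORMAT_VERSION})"
                )
            try:
                state = pickle.load(fh)
            except Exception as exc:
                raise IndexFormatError(f"truncated or corrupt index file: {exc}")
        genome = ReferenceGenome(state["genome_sequences"])
        obj_state = {
            "genome": genome,
            "indexed": IndexedText(genome),
            "occ_rate": state["occ_rate"],
            "sa_rate": state["sa_rate"],
            "n_rows": state["n_rows"],
            "bwt": state["bwt"],
            "counts": state["counts"],
            "occ": state["occ"],
            "_sa_rows": state["sa_rows"],
            "_sa_vals": state["sa_vals"],
            "_sa_lookup": dict(
                zip(state["sa_rows"].tolist(), state["sa_vals"].tolist())
            ),
        }
        return cls(genome, _from_state=obj_state)


def build_index(
    genome: ReferenceGenome, *, occ_rate: int = 128, sa_rate: int = 32
) -> FmIndex:
    """Build the FM-index of a reference genome (both strands)."""
    return FmIndex(genome, occ_rate=occ_rate, sa_rate=sa_rate)
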