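"""Independent reference implementations used to verify the package.

Everything here is deliberately naive: direct string scanning for pattern
location, an exhaustive scheduled-DP search over the alignment rule space,
a cursor-based variant applier, and scipy's binomial tail.  None of it
shares code with the implementations under test.
"""

from __future__ import annotations

from dataclasses import dataclass

from livemapper.live_aligner import AlignmentSettings, min_score
from livemapper.reference_index import CODE_TO_BASE, IndexedText


def indexed_text_string(indexed: IndexedText) -> str:
    """The doubled text as a plain string ('$' for separators)."""
    table = {0: "#", 1: "$", 2: "A", 3: "C", 4: "G", 5: "T"}
    return "".join(table[int(c)] for c in indexed.text)


def naive_locate(indexed: IndexedText, pattern: str) -> list[tuple[str, int, str]]:
    """All occurrences of pattern in the doubled text, via offset_map."""
    text = indexed_text_string(indexed)
    hits = []
    start = text.find(pattern)
    while start != -1:
        hits.append(indexed.offset_map(start))
        start = text.find(pattern, start + 1)
    return sorted(hits)


def naive_count(indexed: IndexedText, pattern: str) -> int:
    text = indexed_text_string(indexed)
    n = 0
    start = text.find(pattern)
    while start != -1:
        n += 1
        start = text.find(pattern, start + 1)
    return n


# ---------------------------------------------------------------------------
# exhaustive alignment oracle


@dataclass(frozen=True)
class OracleResult:
    placement: tuple[str, int, str]  # (name, forward 0-based SAM start, strand)
    score: int
    errors: int
    softclip: int


def _anchor_occurrences(text: str, kmer: str) -> list[int]:
    out = []
    start = text.find(kmer)
    while start != -1:
        out.append(start)
        start = text.find(kmer, start + 1)
    return out


def oracle_align(
    read: str, indexed: IndexedText, settings: AlignmentSettings
) -> tuple[OracleResult | None, bool]:
    """Exhaustive search over the engine's declared alignment space.

    Anchors are exact matches of the read k-mer ending at every seeding
    cycle; extension allows matches, mismatches and gap runs up to the
    maximum indel length (one error per mismatch or gap run, gap_open +
    gap_extend*(len-1) cost), with the running error count never exceeding
    (aligned_length - k) // error_interval.  Returns the best final
    alignment meeting the minimum score, and whether its placement is
    unique among optimal-score alignments.
    """
    text = indexed_text_string(indexed)
    k = settings.anchor_length
    s = settings.seeding_interval
    e = settings.error_interval
    maxi = settings.max_indel_length
    L = len(read)
    threshold = min_score(settings, L)
    finals: dict[tuple[tuple[str, int, str], int], tuple[int, int]] = {}

    def schedule_ok(i_abs: int, sc: int, errors: int) -> bool:
        aligned = i_abs + 1 - sc
        return errors <= (aligned - k) // e

    for sc in range(0, L - k + 1, s):
        kmer = read[sc : sc + k]
        if "N" in kmer:
            continue
        for o in _anchor_occurrences(text, kmer):
            # states: (i, j, errors, last_op, runlen) -> best score
            # i = read bases consumed (absolute), j = next text offset
            states = {(sc + k, o + k, 0, "M", 0): k * settings.match_score}
            for i in range(sc + k, L):
                nxt: dict = {}

                def offer(key, sc_):
                    if nxt.get(key, -(10**9)) < sc_:
                        nxt[key] = sc_

                b = read[i]
                for (ii, j, errors, last, runlen), score in states.items():
                    assert ii == i
                    allowed = (i + 1 - sc - k) // e
                    # M step
                    if j < len(text) and text[j] not in "#$":
                        if text[j] == b:
                            offer((i + 1, j + 1, errors, "M", 0), score + settings.match_score)
                        elif errors + 1 <= allowed:
                            offer(
                                (i + 1, j + 1, errors + 1, "M", 0),
                                score - settings.mismatch_penalty,
                            )
                    if errors + 1 <= allowed and maxi > 0:
                        if last == "M":
                            # open insertion
                            offer(
                                (i + 1, j, errors + 1, "I", 1),
                                score - settings.gap_open_penalty,
                            )
                            # deletion run + consume base
                            for d in range(1, maxi + 1):
                                p = j + d
                                if p >= len(text) or text[p] in "#$":
                                    break
                                cost = settings.gap_open_penalty + (
                                    d - 1
                                ) * settings.gap_extend_penalty
                                if text[p] == b:
                                    offer(
                                        (i + 1, p + 1, errors + 1, "M", 0),
                                        score - cost + settings.match_score,
                                    )
                                elif errors + 2 <= allowed:
                                    offer(
                                        (i + 1, p + 1, errors + 2, "M", 0),
                                        score - cost - settings.mismatch_penalty,
                                    )
                        elif last == "I" and runlen < maxi:
                            offer(
                                (i + 1, j, errors, "I", runlen + 1),
                                score - settings.gap_extend_penalty,
                            )
                states = nxt
                if not states:
                    break
            for (ii, j, errors, last, runlen), score in states.items():
                if score < threshold:
                    continue
                place = _placement(indexed, o, j)
                key = (place, sc)
                cur = finals.get(key)
                if cur is None or (score, -errors) > cur:
                    finals[key] = (score, -errors)
    if not finals:
        return None, False
    best_score = max(v[0] for v in finals.values())
    top = [
        (place, sc, v[0], -v[1]) for (place, sc), v in finals.items() if v[0] == best_score
    ]
    placements = {t[0] for t in top}
    unique = len(placements) == 1
    place, sc, score, errors = min(top, key=lambda t: (t[3], t[1], t[0]))
    return OracleResult(place, score, errors, sc), unique


def _placement(indexed: IndexedText, start: int, end: int) -> tuple[str, int, str]:
    seg = indexed.segment_at(start)
    if seg.strand == "+":
        return seg.name, start - seg.start, "+"
    name, pos, _ = indexed.offset_map(end - 1)
    return seg.name, pos, "-"


# ---------------------------------------------------------------------------
# variant application oracle


def apply_vcf_naive(reference: str, variants: list[tuple[int, str, str]]) -> str:
    """Apply (1-based pos, ref, alt) records to a sequence, simple cursor walk."""
    parts = []
    cursor = 0
    for pos, ref, alt in sorted(variants):
        start = pos - 1
        assert reference[start : start + len(ref)] == ref
        parts.append(reference[cursor:start])
        parts.append(alt)
        cursor = start + len(ref)
    parts.append(reference[cursor:])
    return "".join(parts)
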