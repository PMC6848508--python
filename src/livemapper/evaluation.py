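"""vcfeval-lite: match SNV calls to a truth set, PR curves and APR.

Matching is genotype-insensitive ("squash ploidy") and exact on
(CHROM, POS, REF, ALT) after atomization: multi-allelic records are split
per ALT and same-length MNPs are decomposed into per-base SNVs, so a call
matches iff the identical atomic SNV exists in the truth set inside the
evaluation regions.  The area under the precision-recall curve (APR) uses
the step-function rule: sum over descending quality thresholds of
(recall_i - recall_{i-1}) * precision_i with recall_0 = 0.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path


class VcfParseError(ValueError):
    """Malformed VCF line; the message carries the 1-based line number."""


@dataclass(frozen=True)
class AtomicSnv:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass(frozen=True)
class LabeledCall:
    snv: AtomicSnv
    qual: float
    is_tp: bool


@dataclass(frozen=True)
class PrPoint:
    threshold: float
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")


@dataclass(frozen=True)
class PrCurve:
    points: tuple[PrPoint, ...]  # descending thresholds
    apr: float


# ---------------------------------------------------------------------------
# parsing

def parse_vcf_snvs(path: str | Path) -> list[tuple[AtomicSnv, float]]:
    """Read a VCF, atomize records to SNVs, return (snv, qual) pairs.

    Multi-allelic ALTs are split; same-length multi-base records become one
    SNV per differing base; indels (length-changing records) are skipped —
    this evaluator scores SNVs only.
    """
    out: list[tuple[AtomicSnv, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise VcfParseError(
                    f"{path}:{lineno}: expected >= 8 tab-separated fields"
                )
            chrom, pos_s, _id, ref, alts, qual_s = fields[:6]
            try:
                pos = int(pos_s)
            except ValueError:
                raise VcfParseError(f"{path}:{lineno}: bad POS {pos_s!r}")
            if pos < 1 or not ref:
                raise VcfParseError(f"{path}:{lineno}: bad POS/REF")
            try:
                qual = 0.0 if qual_s == "." else float(qual_s)
            except ValueError:
                raise VcfParseError(f"{path}:{lineno}: bad QUAL {qual_s!r}")
            for alt in alts.split(","):
                if not alt or alt == ".":
                    continue
                if len(alt) != len(ref):
                    continue  # indel: out of scope for SNV scoring
                for i, (r, a) in enumerate(zip(ref, alt)):
                    if r != a:
                        out.append((AtomicSnv(chrom, pos + i, r, a), qual))
    return out


def parse_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """0-based half-open BED intervals, merged and sorted per sequence."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs 3 columns")
            raw.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    merged: dict[str, list[tuple[int, int]]] = {}
    for name, ivs in raw.items():
        ivs.sort()
        acc: list[tuple[int, int]] = []
        for s, e in ivs:
            if acc and s <= acc[-1][1]:
                acc[-1] = (acc[-1][0], max(acc[-1][1], e))
            else:
                acc.append((s, e))
        merged[name] = acc
    return merged


def in_regions(
    regions: dict[str, list[tuple[int, int]]] | None, chrom: str, pos: int
) -> bool:
    """Membership of a 1-based position in BED regions (None = everywhere)."""
    if regions is None:
        return True
    ivs = regions.get(chrom)
    if not ivs:
        return False
    p0 = pos - 1
    i = bisect_right(ivs, (p0, float("inf"))) - 1
    return i >= 0 and ivs[i][0] <= p0 < ivs[i][1]


# ---------------------------------------------------------------------------
# matching and curves

def match_calls(
    calls: list[tuple[AtomicSnv, float]],
    truth: list[tuple[AtomicSnv, float]],
    regions: dict[str, list[tuple[int, int]]] | None,
) -> tuple[list[LabeledCall], set[AtomicSnv]]:
    """Label calls TP/FP against the truth set inside the regions.

    Labels are threshold-independent; the returned FN set contains truth
    SNVs never matched by any call (regardless of quality).
    """
    truth_set = {
        snv for snv, _ in truth if in_regions(regions, snv.chrom, snv.pos)
    }
    labeled: list[LabeledCall] = []
    matched: set[AtomicSnv] = set()
    for snv, qual in calls:
        if not in_regions(regions, snv.chrom, snv.pos):
            continue  # calls outside the evaluation regions are ignored
        is_tp = snv in truth_set
        if is_tp:
            matched.add(snv)
        labeled.append(LabeledCall(snv, qual, is_tp))
    return labeled, truth_set - matched


def pr_curve(labeled: list[LabeledCall], truth_size: int) -> PrCurve:
    """PR point per distinct call quality (calls with QUAL >= t counted)."""
    thresholds = sorted({c.qual for c in labeled}, reverse=True)
    points: list[PrPoint] = []
    apr = 0.0
    prev_recall = 0.0
    for t in thresholds:
        sel = [c for c in labeled if c.qual >= t]
        tp = len({c.snv for c in sel if c.is_tp})
        fp = sum(1 for c in sel if not c.is_tp)
        fn = truth_size - tp
        pt = PrPoint(t, tp, fp, fn)
        points.append(pt)
        recall = pt.recall if truth_size else 0.0
        apr += (recall - prev_recall) * pt.precision
        prev_recall = recall
    return PrCurve(tuple(points), apr)


def precision_recall_at(
    labeled: list[LabeledCall], truth_size: int, threshold: float
) -> tuple[float, float]:
    sel = [c for c in labeled if c.qual >= threshold]
    tp = len({c.snv for c in sel if c.is_tp})
    fp = sum(1 for c in sel if not c.is_tp)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / truth_size if truth_size else float("nan")
    return precision, recall


def evaluate_cycles(
    cycle_vcfs: dict[int, str | Path],
    truth_vcf: str | Path,
    bed_path: str | Path | None,
    *,
    quality_threshold: float = 1.0,
) -> list[dict]:
    """Per-cycle precision/recall at the quality threshold, plus APR.

    Returns one row dict per cycle, sorted by cycle; recall is NaN when the
    truth set inside the regions is empty (reported as NA in the TSV).
    """
    regions = parse_bed(bed_path) if bed_path else None
    truth = parse_vcf_snvs(truth_vcf)
    rows = []
    for cycle in sorted(cycle_vcfs):
        calls = parse_vcf_snvs(cycle_vcfs[cycle])
        labeled, fn_set = match_calls(calls, truth, regions)
        truth_size = len(fn_set) + len({c.snv for c in labeled if c.is_tp})
        precision, recall = precision_recall_at(labeled, truth_size, quality_threshold)
        curve = pr_curve(labeled, truth_size)
        rows.append(
            {
                "cycle": cycle,
                "precision": precision,
                "recall": recall,
                "apr": curve.apr,
                "n_calls": len(labeled),
                "truth_size": truth_size,
            }
        )
    return rows


def write_eval_tsv(rows: list[dict], path: str | Path) -> None:
    cols = ["cycle", "precision", "recall", "apr", "n_calls", "truth_size"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            vals = []
            for c in cols:
                v = row[c]
                if isinstance(v, float):
                    vals.append("NA" if v != v else f"{v:.6g}")
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")
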