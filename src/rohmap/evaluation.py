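"""Benchmarking of region calls against a gold standard.

Variants are classified per site: positive under a region set when they
fall inside one of its regions (1-based inclusive).  True/false
positives and negatives follow from agreement between the predicted and
gold-standard sets, giving TPR (sensitivity) and TNR (specificity).

The optimizer's fitness is the megabase discordance between two region
sets: the total length of their symmetric difference in Mb (lower is
better, zero iff the sets cover identical bases).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .io_formats import Region, RegionSet


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


def _round4(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.0001"), ROUND_HALF_UP))


def rates(counts: ConfusionCounts) -> tuple[float | None, float | None]:
    """(TPR, TNR) rounded half-up to 4 decimals; None where the
    denominator is zero (undefined, never reported as 0)."""
    tpr = (
        _round4(counts.tp / (counts.tp + counts.fn))
        if counts.tp + counts.fn > 0
        else None
    )
    tnr = (
        _round4(counts.tn / (counts.tn + counts.fp))
        if counts.tn + counts.fp > 0
        else None
    )
    return tpr, tnr


# ---------------------------------------------------------------------------
# per-variant classification
# ---------------------------------------------------------------------------

def _membership(
    positions: np.ndarray, regions: Sequence[Region]
) -> np.ndarray:
    """Boolean: position inside any region (start <= pos <= end)."""
    inside = np.zeros(len(positions), dtype=bool)
    if len(regions) == 0 or len(positions) == 0:
        return inside
    starts = np.array([r.start for r in regions])
    ends = np.array([r.end for r in regions])
    # regions sorted, non-overlapping: locate candidate region per pos
    idx = np.searchsorted(starts, positions, side="right") - 1
    valid = idx >= 0
    inside[valid] = positions[valid] <= ends[idx[valid]]
    return inside


def classify_variants(
    positions: Mapping[str, Sequence[int]],
    predicted: RegionSet,
    gold: RegionSet,
) -> ConfusionCounts:
    """Confusion counts of per-variant autozygosity classification.

    ``positions`` maps chromosome -> sorted variant positions.  TP =
    positive under both sets, TN = negative under both, FN = gold-only
    positive, FP = predicted-only positive.
    """
    pred_by = predicted.by_chrom()
    gold_by = gold.by_chrom()
    tp = fp = tn = fn = 0
    for chrom, pos_list in positions.items():
        pos = np.asarray(pos_list, dtype=np.int64)
        in_pred = _membership(pos, pred_by.get(chrom, []))
        in_gold = _membership(pos, gold_by.get(chrom, []))
        tp += int((in_pred & in_gold).sum())
        fp += int((in_pred & ~in_gold).sum())
        fn += int((~in_pred & in_gold).sum())
        tn += int((~in_pred & ~in_gold).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# interval arithmetic (1-based inclusive <-> half-open internally)
# ---------------------------------------------------------------------------

def _to_halfopen(regions: Sequence[Region]) -> list[tuple[int, int]]:
    ivs = sorted((r.start, r.end + 1) for r in regions)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            if b[k][0] > cur:
                out.append((cur, b[k][0]))
            cur = max(cur, b[k][1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def _length(ivs: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in ivs)


def megabase_difference_score(
    predicted: RegionSet, gold: RegionSet
) -> float:
    """Length of the symmetric difference of the two interval sets, in
    Mb.  Zero iff the sets cover identical bases; lower is better."""
    chroms = set(predicted.by_chrom()) | set(gold.by_chrom())
    pred_by = predicted.by_chrom()
    gold_by = gold.by_chrom()
    diff_bp = 0
    for chrom in chroms:
        a = _to_halfopen(pred_by.get(chrom, []))
        b = _to_halfopen(gold_by.get(chrom, []))
        diff_bp += _length(_subtract(a, b)) + _length(_subtract(b, a))
    return diff_bp / 1_000_000


def summed_megabase_difference(
    pairs: Sequence[tuple[RegionSet, RegionSet]]
) -> float:
    """Multi-sample fitness: sum of per-sample Mb discordances."""
    return sum(megabase_difference_score(p, g) for p, g in pairs)


def jaccard(predicted: RegionSet, gold: RegionSet) -> float:
    """Base-pair Jaccard index between two region sets (1 when both are
    empty)."""
    chroms = set(predicted.by_chrom()) | set(gold.by_chrom())
    pred_by = predicted.by_chrom()
    gold_by = gold.by_chrom()
    inter = union = 0
    for chrom in chroms:
        a = _to_halfopen(pred_by.get(chrom, []))
        b = _to_halfopen(gold_by.get(chrom, []))
        ab = _length(_intersect(a, b))
        inter += ab
        union += _length(a) + _length(b) - ab
    return inter / union if union else 1.0


# ---------------------------------------------------------------------------
# shared regions across samples
# ---------------------------------------------------------------------------

def shared_regions(
    affected: Sequence[RegionSet],
    unaffected: Sequence[RegionSet] = (),
    subtract_unaffected: bool = False,
    sample_id: str = "shared",
) -> RegionSet:
    """Regions common to all affected samples; optionally minus any
    interval autozygous in an unaffected sample (candidate-locus
    refinement in recessive pedigrees)."""
    if not affected:
        raise ValueError("at least one affected RegionSet is required")
    chroms: set[str] = set()
    for rs in affected:
        chroms |= set(rs.by_chrom())
    out: list[Region] = []
    for chrom in chroms:
        common: list[tuple[int, int]] | None = None
        for rs in affected:
            ivs = _to_halfopen(rs.by_chrom().get(chrom, []))
            common = ivs if common is None else _intersect(common, ivs)
            if not common:
                break
        if not common:
            continue
        if subtract_unaffected:
            for rs in unaffected:
                common = _subtract(common, _to_halfopen(rs.by_chrom().get(chrom, [])))
                if not common:
                    break
        for s, e in common or []:
            out.append(Region(chrom=chrom, start=s, end=e - 1))
    return RegionSet(sample_id=sample_id, regions=out)
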