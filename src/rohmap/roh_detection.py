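"""Autozygous-region detection: density scaling, heterozygote smoothing,
run calling and region post-processing.

The detector adapts to variant density by scaling its two count-valued
thresholds (``x_filter``, ``x_call``) with the ratio of the sample's
chromosome 1 variant count to 70,700 (the approximate chromosome 1 SNP
count of the Affymetrix SNP6 array).  Scaled thresholds are rounded
half-up with a floor of 1; fraction-valued parameters are never scaled.

Stages, per chromosome, on position-sorted genotyped variants:

1. *Smoothing* — a heterozygote embedded in a long homozygous run is
   presumed to be a genotyping error and removed when the combined
   count of consecutive homozygotes immediately before and after it
   (runs broken by any other heterozygote) reaches the scaled
   ``x_filter``, with at least one homozygote on each side.  Decisions
   are made in a single pass against the original list.
2. *Run calling* — maximal stretches with homozygous endpoints whose
   aggregate heterozygote fraction is at most ``x_minimum`` become
   regions when they contain at least the scaled ``x_call`` variants.
   Two heterozygous calls at distinct adjacent sites are treated as
   definitive evidence of non-autozygosity and always terminate a
   stretch: a single surviving heterozygote may be a genotyping error,
   but two in a row inside an autozygous tract are vanishingly
   unlikely, and without this break rule a stretch could legally absorb
   a long heterozygote-rich tail while staying under the aggregate cap.
3. *Post-processing* — closely adjacent regions (gap < 100 kb) are
   amalgamated, then regions shorter than 1.5 Mb are discounted, since
   only extended runs reflect recent inbreeding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genotyping import (
    GenotypeClass,
    GenotypedVariant,
    GenotypingParams,
    genotype_sample,
    microarray_to_genotyped,
)
from .io_formats import Region, RegionSet, read_microarray_table, read_vcf

logger = logging.getLogger(__name__)

#: chromosome 1 SNP count of the reference array panel the density
#: scaling is anchored to
CHR1_REFERENCE_COUNT = 70_700

_HET = GenotypeClass.HET.value
_HOM_CODES = (GenotypeClass.HOM_REF.value, GenotypeClass.HOM_ALT.value)


@dataclass(frozen=True)
class ScaleFactor:
    """Density scale: chromosome 1 variant count over 70,700."""

    chr1_variant_count: int
    reference_count: int = CHR1_REFERENCE_COUNT

    @property
    def value(self) -> float:
        return self.chr1_variant_count / self.reference_count


@dataclass(frozen=True)
class RohConstants:
    """Post-processing constants: minimum reportable region length and
    the gap below which adjacent regions are amalgamated."""

    min_region_bp: int = 1_500_000
    merge_gap_bp: int = 100_000
    merge_first: bool = True  # amalgamate before the length filter


def scaled_threshold(base: float, scale: ScaleFactor | float) -> int:
    """Scale a count-valued threshold by variant density; half-up
    rounding, floor of 1."""
    s = scale.value if isinstance(scale, ScaleFactor) else scale
    return max(1, int(np.floor(base * s + 0.5)))


def compute_scale_factor(variants: Sequence[GenotypedVariant]) -> ScaleFactor:
    """Scale factor from the genotyped chromosome 1 variant count."""
    n_chr1 = sum(1 for v in variants if v.chrom == "1")
    if n_chr1 == 0:
        raise ValueError(
            "no genotyped chromosome 1 variants: cannot compute the density "
            "scale factor"
        )
    return ScaleFactor(chr1_variant_count=n_chr1)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _smooth_mask(codes: np.ndarray, threshold: int) -> np.ndarray:
    """Boolean keep-mask for one chromosome's genotype codes."""
    keep = np.ones(len(codes), dtype=bool)
    het_idx = np.flatnonzero(codes == _HET)
    if het_idx.size == 0:
        return keep
    left = np.diff(het_idx, prepend=-1) - 1
    right = np.diff(het_idx, append=len(codes)) - 1
    remove = (left >= 1) & (right >= 1) & (left + right >= threshold)
    keep[het_idx[remove]] = False
    return keep


def remove_aberrant_hets(
    variants: Sequence[GenotypedVariant],
    params: GenotypingParams,
    scale: ScaleFactor,
) -> tuple[list[GenotypedVariant], int]:
    """Single-pass removal of aberrant heterozygotes on one chromosome.

    A heterozygote is removed when its combined flanking consecutive
    homozygote count (each side at least one, runs broken by any other
    heterozygote, counted against the original list) reaches
    ``round(x_filter * scale)``.  Returns (retained, n_removed).
    """
    codes = np.fromiter(
        (v.genotype.value for v in variants), dtype=np.int8, count=len(variants)
    )
    keep = _smooth_mask(codes, scaled_threshold(params.x_filter, scale))
    retained = [v for v, k in zip(variants, keep) if k]
    return retained, int((~keep).sum())


# ---------------------------------------------------------------------------
# run calling
# ---------------------------------------------------------------------------

def _call_runs_arrays(
    pos: np.ndarray,
    codes: np.ndarray,
    x_minimum: float,
    min_count: int,
    chrom: str,
) -> list[Region]:
    """Greedy left-to-right maximal-stretch scan on one chromosome."""
    n = len(pos)
    if n == 0:
        return []
    is_hom = codes != _HET
    is_het = ~is_hom
    # boundaries a stretch may not cross: k is the first member of an
    # adjacent heterozygote pair at distinct positions
    pair = is_het[:-1] & is_het[1:] & (pos[:-1] != pos[1:])
    pair_idx = np.flatnonzero(pair)  # stretch may include k but not k+1
    het_cum = np.concatenate([[0], np.cumsum(is_het)])
    regions: list[Region] = []
    scan = 0
    while scan < n:
        hom_ahead = np.flatnonzero(is_hom[scan:])
        if hom_ahead.size == 0:
            break
        i = scan + int(hom_ahead[0])
        p = np.searchsorted(pair_idx, i)
        end = int(pair_idx[p]) + 1 if p < len(pair_idx) else n  # exclusive
        # largest hom j in [i, end) with het fraction of [i..j] <= x_minimum
        js = np.arange(i, end)
        hets = het_cum[i + 1 : end + 1] - het_cum[i]
        ok = is_hom[i:end] & (hets <= x_minimum * (js - i + 1))
        j = i + int(np.flatnonzero(ok)[-1])  # j = i always qualifies
        count = j - i + 1
        if count >= min_count:
            regions.append(
                Region(chrom=chrom, start=int(pos[i]), end=int(pos[j]), n_variants=count)
            )
        scan = j + 1
    return regions


def call_runs(
    variants: Sequence[GenotypedVariant],
    params: GenotypingParams,
    scale: ScaleFactor,
) -> list[Region]:
    """Call candidate autozygous runs on one chromosome (post-smoothing).

    A stretch grows greedily left-to-right from each uncovered
    homozygote to the last homozygote keeping the aggregate heterozygote
    fraction at or below ``x_minimum``, never crossing an adjacent
    heterozygote pair; it becomes a region when it holds at least
    ``round(x_call * scale)`` variants.
    """
    if not variants:
        return []
    chrom = variants[0].chrom
    pos = np.fromiter((v.pos for v in variants), dtype=np.int64, count=len(variants))
    codes = np.fromiter(
        (v.genotype.value for v in variants), dtype=np.int8, count=len(variants)
    )
    return _call_runs_arrays(
        pos, codes, params.x_minimum, scaled_threshold(params.x_call, scale), chrom
    )


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def _merge_adjacent(regions: list[Region], merge_gap_bp: int) -> list[Region]:
    out: list[Region] = []
    for r in regions:
        if out and out[-1].chrom == r.chrom and r.start - out[-1].end - 1 < merge_gap_bp:
            prev = out.pop()
            out.append(
                Region(
                    chrom=r.chrom,
                    start=prev.start,
                    end=max(prev.end, r.end),
                    n_variants=prev.n_variants + r.n_variants,
                )
            )
        else:
            out.append(r)
    return out


def postprocess_regions(
    regions: Iterable[Region],
    constants: RohConstants = RohConstants(),
    sample_id: str = "sample",
) -> RegionSet:
    """Amalgamate closely adjacent regions (gap < merge_gap_bp), then
    discount regions shorter than min_region_bp.  Idempotent."""
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start))
    if constants.merge_first:
        merged = _merge_adjacent(ordered, constants.merge_gap_bp)
        kept = [r for r in merged if r.length >= constants.min_region_bp]
    else:
        long_enough = [r for r in ordered if r.length >= constants.min_region_bp]
        kept = _merge_adjacent(long_enough, constants.merge_gap_bp)
    return RegionSet(sample_id=sample_id, regions=kept)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def detect_from_genotyped(
    variants: Sequence[GenotypedVariant],
    params: GenotypingParams = GenotypingParams(),
    constants: RohConstants = RohConstants(),
    sample_id: str = "sample",
) -> tuple[RegionSet, dict]:
    """Smoothing, run calling and post-processing on an already
    genotyped, position-sorted variant list."""
    scale = compute_scale_factor(variants)
    by_chrom: dict[str, list[GenotypedVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    raw: list[Region] = []
    n_removed = 0
    for chrom in sorted(by_chrom, key=lambda c: (len(c), c)):
        retained, removed = remove_aberrant_hets(by_chrom[chrom], params, scale)
        n_removed += removed
        raw.extend(call_runs(retained, params, scale))
    region_set = postprocess_regions(raw, constants, sample_id=sample_id)
    report = {
        "n_genotyped": len(variants),
        "scale_factor": scale.value,
        "chr1_variant_count": scale.chr1_variant_count,
        "x_filter_scaled": scaled_threshold(params.x_filter, scale),
        "x_call_scaled": scaled_threshold(params.x_call, scale),
        "n_aberrant_hets_removed": n_removed,
        "n_raw_runs": len(raw),
        "n_regions": len(region_set),
        "autozygous_bp": region_set.total_bp(),
    }
    return region_set, report


def detect_autozygous_regions(
    vcf: str | Path | None = None,
    microarray: str | Path | None = None,
    params: GenotypingParams = GenotypingParams(),
    constants: RohConstants = RohConstants(),
    sample_id: str | None = None,
) -> tuple[RegionSet, dict]:
    """Full detection pipeline from a VCF/gVCF or a microarray table.

    Sequencing variants are basic-filtered and re-genotyped from allele
    depths; microarray calls map directly to genotype classes and join
    at the smoothing stage.  Returns the post-processed RegionSet and a
    per-stage run report.
    """
    if (vcf is None) == (microarray is None):
        raise ValueError("provide exactly one of vcf= or microarray=")
    if vcf is not None:
        sid = sample_id or Path(vcf).stem
        records = read_vcf(vcf, require_rs=params.require_rs)
        genotyped, attrition = genotype_sample(records, params)
        report_head = {"input": str(vcf), "attrition": attrition.as_dict()}
    else:
        sid = sample_id or Path(microarray).stem
        calls = read_microarray_table(microarray)
        genotyped = microarray_to_genotyped(calls)
        report_head = {"input": str(microarray)}
    region_set, report = detect_from_genotyped(
        genotyped, params, constants, sample_id=sid
    )
    report = {**report_head, **report, "params": params.as_dict()}
    logger.info("detected %d regions for %s", len(region_set), sid)
    return region_set, report
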