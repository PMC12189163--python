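"""Readers and writers for every external representation the tool touches.

Variant data arrives as single-sample VCF/gVCF (allele depths in the AD
format field), SNP-microarray genotypes as tab-delimited tables
(chromosome, position, AA/AB/BB call), and autozygous regions as
tab-delimited region tables.  Coordinates are 1-based inclusive
everywhere except BED export, which follows the 0-based half-open BED
convention.

Only autosomes 1-22 are processed by default; chromosome labels are
normalised by stripping a leading ``chr``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(str(c) for c in range(1, 23))


class FormatError(ValueError):
    """Raised for unparseable or contract-violating input files."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One variant site with the raw per-allele read evidence.

    ``ref_depth``/``alt_depth`` are the read counts supporting the
    reference and the *first* alternate allele; ``total_depth`` is the
    site depth (DP) when reported.  ``reported_genotype`` is whatever
    the source file stated and is never consulted by re-genotyping.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    rs_id: str | None = None
    ref_depth: int = 0
    alt_depth: int = 0
    total_depth: int | None = None
    reported_genotype: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("allele depths must be non-negative")


@dataclass(frozen=True)
class ArrayGenotype:
    """One microarray SNP genotype call (AA/AB/BB; NoCall rows are dropped
    by the reader before they reach here)."""

    chrom: str
    pos: int
    call: str  # "AA" | "AB" | "BB"


@dataclass(frozen=True)
class Region:
    """A run of homozygosity: 1-based inclusive interval with the number
    of post-smoothing variants supporting it."""

    chrom: str
    start: int
    end: int
    n_variants: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionSet:
    """Per-sample collection of regions, sorted and non-overlapping
    within each chromosome."""

    sample_id: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(
            self.regions, key=lambda r: (_chrom_sort_key(r.chrom), r.start)
        )
        self._validate()

    def _validate(self) -> None:
        for prev, cur in zip(self.regions, self.regions[1:]):
            if prev.chrom == cur.chrom and cur.start <= prev.end:
                raise ValueError(
                    f"overlapping regions in sample {self.sample_id}: "
                    f"{prev.chrom}:{prev.start}-{prev.end} and "
                    f"{cur.chrom}:{cur.start}-{cur.end}"
                )

    def by_chrom(self) -> dict[str, list[Region]]:
        out: dict[str, list[Region]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        return out

    def total_bp(self) -> int:
        return sum(r.length for r in self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.sample_id == other.sample_id and self.regions == other.regions


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (1_000, chrom)


def normalize_chrom(label: str) -> str:
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


# ---------------------------------------------------------------------------
# attrition accounting
# ---------------------------------------------------------------------------

class AttritionLog(Counter):
    """Counts dropped records by reason; ``seen``/``kept`` complete the
    invariant kept + dropped == seen."""

    def __init__(self) -> None:
        super().__init__()
        self.seen = 0
        self.kept = 0

    def drop(self, reason: str) -> None:
        self[reason] += 1

    @property
    def dropped(self) -> int:
        return sum(self.values())

    def as_dict(self) -> dict[str, int]:
        return {"seen": self.seen, "kept": self.kept, **self}


# ---------------------------------------------------------------------------
# VCF / gVCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    require_rs: bool = False,
    sample: str | None = None,
    autosomes_only: bool = True,
    missing_ad_fatal: bool = False,
    attrition: AttritionLog | None = None,
) -> Iterator[VariantRecord]:
    """Yield :class:`VariantRecord` per variant line of a VCF/gVCF.

    gVCF non-variant reference blocks are skipped.  With ``require_rs``
    records whose ID column is missing/"." are dropped here (an optional
    filter against artefactual calls, mainly for genome data).  Records
    without a usable AD annotation are dropped (or fatal when
    ``missing_ad_fatal``).  Out-of-order records are a fatal error.
    """
    from cyvcf2 import VCF  # deferred: import is the slow part

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    log = attrition if attrition is not None else AttritionLog()
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise FormatError(f"unparseable VCF {path}: {exc}") from exc
    if sample is not None:
        vcf.set_samples([sample])
    elif len(vcf.samples) > 1:
        vcf.set_samples([vcf.samples[0]])

    last: tuple[str, int] | None = None
    for v in vcf:
        log.seen += 1
        chrom = normalize_chrom(v.CHROM)
        alts = tuple(a for a in (v.ALT or []))
        if not alts or alts == ("<NON_REF>",):
            log.drop("non_variant_block")
            continue
        alts = tuple(a for a in alts if a != "<NON_REF>")
        if autosomes_only and chrom not in AUTOSOMES:
            log.drop("non_autosome")
            continue
        if last is not None and last[0] == chrom and v.POS < last[1]:
            raise FormatError(
                f"{path}: out-of-order record {chrom}:{v.POS} after {last[1]}"
            )
        last = (chrom, v.POS)
        rs_id = v.ID if v.ID not in (None, ".", "") else None
        if require_rs and rs_id is None:
            log.drop("no_rs_id")
            continue
        ad = v.format("AD")
        if ad is None or ad.shape[1] < 2 or int(ad[0][0]) < 0:
            if missing_ad_fatal:
                raise FormatError(
                    f"{path}: record {chrom}:{v.POS} lacks AD annotation"
                )
            log.drop("no_allele_depth")
            continue
        ref_d = int(ad[0][0])
        alt_d = int(ad[0][1])
        try:
            dp = int(v.format("DP")[0][0]) if v.format("DP") is not None else None
        except (TypeError, IndexError):
            dp = None
        gts = v.genotypes
        gt = None
        if gts:
            a, b = gts[0][0], gts[0][1]
            if a >= 0 and b >= 0:
                gt = f"{a}/{b}"
        log.kept += 1
        yield VariantRecord(
            chrom=chrom,
            pos=v.POS,
            ref_allele=v.REF,
            alt_alleles=alts,
            rs_id=rs_id,
            ref_depth=max(ref_d, 0),
            alt_depth=max(alt_d, 0),
            total_depth=dp,
            reported_genotype=gt,
        )
    if attrition is None and log.dropped:
        logger.info("read_vcf(%s): attrition %s", path.name, dict(log))


# ---------------------------------------------------------------------------
# microarray genotype tables
# ---------------------------------------------------------------------------

#: default column mapping for microarray tables; override for other dialects
DEFAULT_ARRAY_COLUMNS = {"chrom": "chrom", "pos": "pos", "call": "call"}

_NOCALL_STRINGS = {"NC", "NOCALL", "NO CALL", "--", "---", ""}


def read_microarray_table(
    path: str | Path,
    columns: dict[str, str] | None = None,
    autosomes_only: bool = True,
    attrition: AttritionLog | None = None,
) -> Iterator[ArrayGenotype]:
    """Yield sorted :class:`ArrayGenotype` from a tab-delimited table.

    NoCall rows are excluded and counted.  The column mapping is
    configurable because array export dialects vary.
    """
    cols = columns or DEFAULT_ARRAY_COLUMNS
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    log = attrition if attrition is not None else AttritionLog()
    last: tuple[str, int] | None = None
    for _, row in df.iterrows():
        log.seen += 1
        chrom = normalize_chrom(row[cols["chrom"]])
        pos = int(row[cols["pos"]])
        call = str(row[cols["call"]]).strip().upper()
        if autosomes_only and chrom not in AUTOSOMES:
            log.drop("non_autosome")
            continue
        if call in _NOCALL_STRINGS or call == "NOCALL":
            log.drop("no_call")
            continue
        if call not in ("AA", "AB", "BB"):
            raise FormatError(f"{path}: unknown genotype call {call!r}")
        if last is not None and last[0] == chrom and pos < last[1]:
            raise FormatError(
                f"{path}: out-of-order row {chrom}:{pos} after {last[1]}"
            )
        last = (chrom, pos)
        log.kept += 1
        yield ArrayGenotype(chrom=chrom, pos=pos, call=call)


# ---------------------------------------------------------------------------
# region tables
# ---------------------------------------------------------------------------

REGION_TABLE_COLUMNS = ["sample", "chromosome", "start", "end", "n_variants"]


def read_region_table(path: str | Path) -> dict[str, RegionSet]:
    """Read a tab-delimited region table into per-sample RegionSets.

    Columns: sample, chromosome, start, end[, n_variants]; coordinates
    1-based inclusive.  Inverted or overlapping intervals are fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = REGION_TABLE_COLUMNS[:4]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out: dict[str, list[Region]] = {}
    for i, row in df.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if start > end:
            raise FormatError(
                f"{path}: row {i + 2}: start {start} > end {end}"
            )
        n_var = int(row["n_variants"]) if "n_variants" in df.columns and not pd.isna(row.get("n_variants")) else 0
        out.setdefault(str(row["sample"]), []).append(
            Region(
                chrom=normalize_chrom(row["chromosome"]),
                start=start,
                end=end,
                n_variants=n_var,
            )
        )
    try:
        return {s: RegionSet(sample_id=s, regions=rs) for s, rs in out.items()}
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_region_table(
    region_sets: dict[str, RegionSet] | Sequence[RegionSet], path: str | Path
) -> None:
    """Write RegionSets as a tab-delimited table, deterministically
    ordered by (sample, chromosome, start)."""
    if isinstance(region_sets, dict):
        sets = [region_sets[k] for k in sorted(region_sets)]
    else:
        sets = sorted(region_sets, key=lambda rs: rs.sample_id)
    rows = [
        (rs.sample_id, r.chrom, r.start, r.end, r.n_variants)
        for rs in sets
        for r in rs.regions
    ]
    df = pd.DataFrame(rows, columns=REGION_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def export_bed(region_set: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED3 (0-based half-open)."""
    with open(path, "w") as fh:
        for r in region_set.regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")


# ---------------------------------------------------------------------------
# helpers shared with the pipeline
# ---------------------------------------------------------------------------

def collect(records: Iterable) -> list:
    """Materialise a record stream (mostly for readable call sites)."""
    return list(records)
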