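"""Variant filtering and allele-depth re-genotyping.

Sequencing genotype calls are of uncertain quality, so each variant's
genotype is re-called from its allele read fractions rather than trusted
from the source file.  With informative depth d = ref_depth + alt_depth,
p_ref = ref_depth/d and p_alt = alt_depth/d, the ordered rules are:

1. p_alt >= 1 - n_bb            -> homozygous non-reference
2. 0.5 - n_het <= p_ref <= 0.5 + n_het -> heterozygous
3. p_ref >= n_aa                -> homozygous reference
4. otherwise                    -> discarded (ungenotyped)

The order matters: with the default thresholds the heterozygous band
[0.33, 0.67] overlaps the homozygous-reference region [0.64, 1], and the
heterozygous rule wins on [0.64, 0.67].

Before re-genotyping, basic filtering removes (in order) variants
lacking an RS id when required, non-single-base variants, sites with
more than two alleles, and sites below the minimum read depth.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import ArrayGenotype, AttritionLog, VariantRecord


@dataclass(frozen=True)
class GenotypingParams:
    """The seven tunable parameters of the detector.

    Defaults are the optimized values recommended for all analyses:
    n_r=5, n_aa=0.64, n_bb=0.17, n_het=0.17, x_filter=386,
    x_minimum=0.1, x_call=575.

    n_r        minimum read depth for a variant to be genotyped
    n_aa       minimum reference read fraction for a hom-ref call
    n_bb       1 - n_bb is the minimum non-reference read fraction
               for a hom-alt call
    n_het      half-width of the heterozygous band around 0.5
    x_filter   baseline combined flanking-homozygote count at which an
               isolated heterozygote is discounted (density-scaled)
    x_minimum  maximum tolerated heterozygous fraction inside a run
    x_call     baseline variant count required to call a run
               (density-scaled)
    require_rs drop variants without a dbSNP RS id (mainly for WGS)
    """

    n_r: int = 5
    n_aa: float = 0.64
    n_bb: float = 0.17
    n_het: float = 0.17
    x_filter: int = 386
    x_minimum: float = 0.1
    x_call: int = 575
    require_rs: bool = False

    def as_dict(self) -> dict:
        return {
            "n_r": self.n_r,
            "n_aa": self.n_aa,
            "n_bb": self.n_bb,
            "n_het": self.n_het,
            "x_filter": self.x_filter,
            "x_minimum": self.x_minimum,
            "x_call": self.x_call,
            "require_rs": self.require_rs,
        }


class GenotypeClass(enum.Enum):
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    DISCARDED = 3

    @property
    def is_hom(self) -> bool:
        return self in (GenotypeClass.HOM_REF, GenotypeClass.HOM_ALT)


@dataclass(frozen=True)
class GenotypedVariant:
    chrom: str
    pos: int
    genotype: GenotypeClass
    rs_id: str | None = None
    source: str = "sequencing"  # or "microarray"


# ---------------------------------------------------------------------------
# filtering and re-genotyping, record at a time
# ---------------------------------------------------------------------------

def basic_filter(
    record: VariantRecord, params: GenotypingParams
) -> tuple[bool, str | None]:
    """Return (keep, drop_reason). Reasons checked in order: RS id,
    non-SNV, multiallelic, depth."""
    if params.require_rs and record.rs_id is None:
        return False, "no_rs_id"
    if len(record.ref_allele) != 1 or any(
        len(a) != 1 or a.startswith("<") for a in record.alt_alleles
    ):
        return False, "non_snv"
    if len(record.alt_alleles) > 1:
        return False, "multiallelic"
    depth = (
        record.total_depth
        if record.total_depth is not None
        else record.ref_depth + record.alt_depth
    )
    if depth < params.n_r:
        return False, "low_depth"
    return True, None


def regenotype(
    record: VariantRecord, params: GenotypingParams
) -> GenotypeClass:
    """Re-call the genotype from allele read fractions (ordered rules)."""
    d = record.ref_depth + record.alt_depth
    if d == 0:
        return GenotypeClass.DISCARDED
    p_ref = record.ref_depth / d
    p_alt = record.alt_depth / d
    if p_alt >= 1.0 - params.n_bb:
        return GenotypeClass.HOM_ALT
    if 0.5 - params.n_het <= p_ref <= 0.5 + params.n_het:
        return GenotypeClass.HET
    if p_ref >= params.n_aa:
        return GenotypeClass.HOM_REF
    return GenotypeClass.DISCARDED


def genotype_sample(
    records: Iterable[VariantRecord], params: GenotypingParams
) -> tuple[list[GenotypedVariant], AttritionLog]:
    """Filter and re-genotype a sorted variant stream.

    Discarded variants never reach the returned list; they are tallied
    by reason in the attrition log.
    """
    out: list[GenotypedVariant] = []
    log = AttritionLog()
    for rec in records:
        log.seen += 1
        keep, reason = basic_filter(rec, params)
        if not keep:
            log.drop(reason)
            continue
        gt = regenotype(rec, params)
        if gt is GenotypeClass.DISCARDED:
            log.drop("ungenotyped")
            continue
        log.kept += 1
        out.append(
            GenotypedVariant(chrom=rec.chrom, pos=rec.pos, genotype=gt, rs_id=rec.rs_id)
        )
    return out, log


_ARRAY_CALL_MAP = {
    "AA": GenotypeClass.HOM_REF,
    "AB": GenotypeClass.HET,
    "BB": GenotypeClass.HOM_ALT,
}


def microarray_to_genotyped(
    calls: Iterable[ArrayGenotype],
) -> list[GenotypedVariant]:
    """Map array calls directly to genotype classes.

    Array genotypes cannot be re-called from read evidence, so they
    bypass basic filtering and re-genotyping and join the pipeline at
    the heterozygote-smoothing stage.
    """
    out = []
    for c in calls:
        try:
            gt = _ARRAY_CALL_MAP[c.call]
        except KeyError:
            raise ValueError(f"unknown microarray call {c.call!r}") from None
        out.append(
            GenotypedVariant(chrom=c.chrom, pos=c.pos, genotype=gt, source="microarray")
        )
    return out


# ---------------------------------------------------------------------------
# columnar fast path
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Columnar view of a sample's variants, for repeated re-genotyping
    under many candidate parameter sets (the optimizer's hot loop).

    Semantics are identical to basic_filter + regenotype on each record;
    equivalence is covered by tests.
    """

    chrom: np.ndarray        # unicode labels
    pos: np.ndarray          # int64
    ref_depth: np.ndarray    # int64
    alt_depth: np.ndarray    # int64
    depth: np.ndarray        # int64; DP, or ref+alt where DP absent
    has_rs: np.ndarray       # bool
    is_snv: np.ndarray       # bool: single-base ref and alt
    is_biallelic: np.ndarray  # bool: exactly one ALT

    @classmethod
    def from_records(cls, records: Sequence[VariantRecord]) -> "VariantTable":
        n = len(records)
        chrom = np.array([r.chrom for r in records])
        pos = np.fromiter((r.pos for r in records), dtype=np.int64, count=n)
        ref_d = np.fromiter((r.ref_depth for r in records), dtype=np.int64, count=n)
        alt_d = np.fromiter((r.alt_depth for r in records), dtype=np.int64, count=n)
        depth = np.fromiter(
            (
                r.total_depth if r.total_depth is not None else r.ref_depth + r.alt_depth
                for r in records
            ),
            dtype=np.int64,
            count=n,
        )
        has_rs = np.fromiter((r.rs_id is not None for r in records), dtype=bool, count=n)
        is_snv = np.fromiter(
            (
                len(r.ref_allele) == 1
                and all(len(a) == 1 and not a.startswith("<") for a in r.alt_alleles)
                for r in records
            ),
            dtype=bool,
            count=n,
        )
        is_bi = np.fromiter(
            (len(r.alt_alleles) == 1 for r in records), dtype=bool, count=n
        )
        return cls(chrom, pos, ref_d, alt_d, depth, has_rs, is_snv, is_bi)

    def __len__(self) -> int:
        return len(self.pos)

    def genotype(
        self, params: GenotypingParams
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised filter + re-genotype.

        Returns (chrom, pos, genotype_code) for kept variants, with
        genotype codes matching :class:`GenotypeClass` values.
        """
        keep = self.is_snv & self.is_biallelic & (self.depth >= params.n_r)
        if params.require_rs:
            keep &= self.has_rs
        d = self.ref_depth + self.alt_depth
        keep &= d > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            p_ref = np.where(d > 0, self.ref_depth / np.maximum(d, 1), 0.0)
            p_alt = np.where(d > 0, self.alt_depth / np.maximum(d, 1), 0.0)
        code = np.full(len(self), GenotypeClass.DISCARDED.value, dtype=np.int8)
        hom_alt = p_alt >= 1.0 - params.n_bb
        het = (~hom_alt) & (0.5 - params.n_het <= p_ref) & (p_ref <= 0.5 + params.n_het)
        hom_ref = (~hom_alt) & (~het) & (p_ref >= params.n_aa)
        code[hom_alt] = GenotypeClass.HOM_ALT.value
        code[het] = GenotypeClass.HET.value
        code[hom_ref] = GenotypeClass.HOM_REF.value
        keep &= code != GenotypeClass.DISCARDED.value
        return self.chrom[keep], self.pos[keep], code[keep]
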