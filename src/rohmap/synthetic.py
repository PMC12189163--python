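"""Ground-truthed synthetic samples for exercising the detector.

The generator plants non-overlapping autozygous segments (default
expectation: 1/16 of the genome, the first-cousin-offspring level),
places variant sites at array-like or exome-like density, and samples
per-site read evidence: allele frequencies per site, Hardy-Weinberg
genotypes outside segments, forced homozygosity inside them, binomial
allele-depth sampling with a per-read error rate, and optional
contamination (erroneous heterozygotes inside segments, error hotspots
with elevated het rates and missing RS ids).

It is a statistical stand-in for real exome/genome data: real call
errors cluster at misalignment- and coverage-driven hotspots in ways no
simple rate model reproduces, which is why the optional hotspot knobs
exist and why synthetic benchmarks bound, rather than measure, real
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotyping import GenotypeClass
from .io_formats import ArrayGenotype, Region, RegionSet, VariantRecord, write_region_table

#: approximate autosome lengths (bp, build hg19 scale)
AUTOSOME_LENGTHS_BP: dict[str, int] = {
    "1": 249_250_000, "2": 243_200_000, "3": 198_000_000, "4": 191_200_000,
    "5": 180_900_000, "6": 171_100_000, "7": 159_100_000, "8": 146_400_000,
    "9": 141_200_000, "10": 135_500_000, "11": 135_000_000, "12": 133_900_000,
    "13": 115_200_000, "14": 107_300_000, "15": 102_500_000, "16": 90_400_000,
    "17": 81_200_000, "18": 78_100_000, "19": 59_100_000, "20": 63_000_000,
    "21": 48_100_000, "22": 51_300_000,
}

#: site density that reproduces ~70,700 chromosome 1 sites at full scale
DEFAULT_SITE_RATE = 70_700 / AUTOSOME_LENGTHS_BP["1"]


@dataclass(frozen=True)
class GenomeSpec:
    """Genome geometry and variant-density model for one synthetic
    sample.

    ``site_rate`` is sites per bp (the default reproduces ~70,700
    chromosome 1 sites, i.e. a density scale factor of 1 at full
    scale).  ``density`` is "uniform" (array-like) or "exome"
    (clustered hot/cold blocks).  Planted segments are drawn uniformly
    from ``segment_length_range`` and kept at least
    ``min_segment_separation_bp`` apart so distinct segments stay
    distinct after post-processing.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(AUTOSOME_LENGTHS_BP)
    )
    site_rate: float = DEFAULT_SITE_RATE
    density: str = "uniform"  # "uniform" | "exome"
    autozygous_fraction: float = 1 / 16
    segment_length_range: tuple[int, int] = (2_000_000, 30_000_000)
    min_segment_separation_bp: int = 2_000_000
    alt_freq_range: tuple[float, float] = (0.05, 0.5)

    @classmethod
    def reduced(cls, scale: float = 0.1, **kwargs) -> "GenomeSpec":
        """Genome with autosome lengths multiplied by ``scale`` (site
        density unchanged, so the density scale factor shrinks with the
        genome)."""
        lengths = {c: max(1, int(l * scale)) for c, l in AUTOSOME_LENGTHS_BP.items()}
        return cls(chrom_lengths=lengths, **kwargs)

    @property
    def genome_bp(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass(frozen=True)
class ErrorModel:
    """Noise model for the presented genotypes and read evidence.

    het_in_autozygous_rate  probability a site inside a planted segment
                            is presented as heterozygous (genotyping
                            error; default 0.5%)
    depth_mean              mean per-site depth (Poisson, or negative
                            binomial when depth_dispersion is set)
    depth_dispersion        NB size parameter; None -> Poisson
    read_error              per-read error rate epsilon used in the
                            binomial allele-depth sampling
    rs_assigned_rate        fraction of sites given an RS id
    hotspot_count           number of error hotspots planted per genome
    hotspot_length_bp       hotspot extent
    hotspot_het_rate        presented-het probability inside hotspots
    hotspot_rs_rate         RS-assignment rate inside hotspots (low:
                            artefactual calls mostly lack RS ids)
    """

    het_in_autozygous_rate: float = 0.005
    depth_mean: float = 30.0
    depth_dispersion: float | None = None
    read_error: float = 0.005
    rs_assigned_rate: float = 0.95
    hotspot_count: int = 0
    hotspot_length_bp: int = 100_000
    hotspot_het_rate: float = 0.25
    hotspot_rs_rate: float = 0.2


@dataclass
class SyntheticSample:
    """A simulated sample: raw variant records, the equivalent
    microarray calls, and the planted truth regions."""

    sample_id: str
    records: list[VariantRecord]
    array_calls: list[ArrayGenotype]
    truth: RegionSet


# ---------------------------------------------------------------------------
# truth planning
# ---------------------------------------------------------------------------

def plan_segments(
    spec: GenomeSpec, rng: np.random.Generator, sample_id: str = "truth"
) -> RegionSet:
    """Plant non-overlapping autozygous segments totalling the target
    fraction of the genome (within ~20%); deterministic given the rng
    state."""
    target = spec.autozygous_fraction * spec.genome_bp
    if target <= 0:
        return RegionSet(sample_id=sample_id, regions=[])
    chroms = sorted(spec.chrom_lengths, key=lambda c: int(c))
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    total = 0
    attempts = 0
    lo, hi = spec.segment_length_range
    while total < target and attempts < 10_000:
        attempts += 1
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        clen = spec.chrom_lengths[c]
        seg_len = int(rng.uniform(lo, min(hi, max(lo, clen // 2))))
        if seg_len >= clen:
            continue
        start = int(rng.integers(1, clen - seg_len + 1))
        end = start + seg_len - 1
        sep = spec.min_segment_separation_bp
        if any(start - sep <= e and end + sep >= s for s, e in placed[c]):
            continue
        # avoid overshooting the +20% tolerance band
        if total + seg_len > 1.2 * target:
            seg_len = int(target - total) + 1
            if seg_len < lo:
                break
            end = start + seg_len - 1
            if any(start - sep <= e and end + sep >= s for s, e in placed[c]):
                continue
        placed[c].append((start, end))
        total += end - start + 1
    regions = [
        Region(chrom=c, start=s, end=e)
        for c in chroms
        for s, e in sorted(placed[c])
    ]
    return RegionSet(sample_id=sample_id, regions=regions)


# ---------------------------------------------------------------------------
# sample simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1"}


def _site_positions(
    n: int, length: int, density: str, rng: np.random.Generator
) -> np.ndarray:
    """n distinct sorted 1-based positions on [1, length]."""
    if n <= 0:
        return np.array([], dtype=np.int64)
    if density == "exome":
        # clustered density: gamma-weighted 500 kb blocks
        n_blocks = max(1, length // 500_000)
        w = rng.gamma(0.3, size=n_blocks)
        counts = rng.multinomial(n, w / w.sum())
        edges = np.linspace(1, length + 1, n_blocks + 1)
        parts = [
            rng.integers(int(edges[b]), int(edges[b + 1]), size=counts[b])
            for b in range(n_blocks)
            if counts[b]
        ]
        pos = np.concatenate(parts) if parts else np.array([], dtype=np.int64)
    else:
        pos = rng.integers(1, length + 1, size=n + max(16, n // 50))
    pos = np.unique(pos)
    while len(pos) < n:  # rare collision top-up
        pos = np.unique(
            np.concatenate([pos, rng.integers(1, length + 1, size=n)])
        )
    if len(pos) > n:
        pos = np.sort(rng.choice(pos, size=n, replace=False))
    return pos.astype(np.int64)


def _interval_membership(
    pos: np.ndarray, intervals: Sequence[tuple[int, int]]
) -> np.ndarray:
    inside = np.zeros(len(pos), dtype=bool)
    for s, e in intervals:
        inside |= (pos >= s) & (pos <= e)
    return inside


def simulate_sample(
    truth: RegionSet,
    spec: GenomeSpec,
    errors: ErrorModel = ErrorModel(),
    rng: np.random.Generator | None = None,
    sample_id: str = "synthetic",
) -> SyntheticSample:
    """Simulate read-level variant records and array calls for a genome
    carrying the planted ``truth`` segments."""
    rng = rng if rng is not None else np.random.default_rng(0)
    truth_by = truth.by_chrom()
    # plant error hotspots genome-wide
    chroms = sorted(spec.chrom_lengths, key=lambda c: int(c))
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    hotspots: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for _ in range(errors.hotspot_count):
        c = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
        clen = spec.chrom_lengths[c]
        hlen = min(errors.hotspot_length_bp, clen - 1)
        s = int(rng.integers(1, clen - hlen + 1))
        hotspots[c].append((s, s + hlen - 1))

    records: list[VariantRecord] = []
    array_calls: list[ArrayGenotype] = []
    rs_counter = 1
    for c in chroms:
        clen = spec.chrom_lengths[c]
        n = int(round(clen * spec.site_rate))
        pos = _site_positions(n, clen, spec.density, rng)
        if len(pos) == 0:
            continue
        p = rng.uniform(*spec.alt_freq_range, size=len(pos))
        in_seg = _interval_membership(
            pos, [(r.start, r.end) for r in truth_by.get(c, [])]
        )
        in_hot = _interval_membership(pos, hotspots[c])
        u = rng.random(len(pos))
        # outside segments: Hardy-Weinberg given per-site alt frequency
        het_p = 2 * p * (1 - p)
        gt = np.where(u < het_p, 1, np.where(u < het_p + p * p, 2, 0))
        # inside segments: homozygous for the IBD haplotype's allele
        hap_alt = rng.random(len(pos)) < p
        gt = np.where(in_seg, np.where(hap_alt, 2, 0), gt)
        # genotyping-error contamination
        err_het = rng.random(len(pos))
        gt = np.where(in_seg & (err_het < errors.het_in_autozygous_rate), 1, gt)
        gt = np.where(in_hot & (err_het < errors.hotspot_het_rate), 1, gt)
        # read evidence
        if errors.depth_dispersion is None:
            depth = rng.poisson(errors.depth_mean, size=len(pos))
        else:
            r = errors.depth_dispersion
            depth = rng.negative_binomial(
                r, r / (r + errors.depth_mean), size=len(pos)
            )
        eps = errors.read_error
        pi = np.choose(gt, [eps, 0.5, 1 - eps])
        alt_d = rng.binomial(depth, pi)
        ref_d = depth - alt_d
        # alleles and RS ids
        ref_idx = rng.integers(0, 4, size=len(pos))
        alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
        rs_rate = np.where(in_hot, errors.hotspot_rs_rate, errors.rs_assigned_rate)
        has_rs = rng.random(len(pos)) < rs_rate
        for k in range(len(pos)):
            rs = f"rs{rs_counter}" if has_rs[k] else None
            rs_counter += 1
            records.append(
                VariantRecord(
                    chrom=c,
                    pos=int(pos[k]),
                    ref_allele=str(_BASES[ref_idx[k]]),
                    alt_alleles=(str(_BASES[alt_idx[k]]),),
                    rs_id=rs,
                    ref_depth=int(ref_d[k]),
                    alt_depth=int(alt_d[k]),
                    total_depth=int(depth[k]),
                    reported_genotype=_GT_STRING[int(gt[k])],
                )
            )
            array_calls.append(
                ArrayGenotype(
                    chrom=c, pos=int(pos[k]), call=("AA", "AB", "BB")[int(gt[k])]
                )
            )
    return SyntheticSample(
        sample_id=sample_id,
        records=records,
        array_calls=array_calls,
        truth=RegionSet(sample_id=sample_id, regions=list(truth.regions)),
    )


def generate_sample(
    spec: GenomeSpec = GenomeSpec(),
    errors: ErrorModel = ErrorModel(),
    seed: int = 0,
    sample_id: str = "synthetic",
) -> SyntheticSample:
    """Plan truth segments and simulate a sample in one deterministic
    step."""
    rng = np.random.default_rng(seed)
    truth = plan_segments(spec, rng, sample_id=sample_id)
    return simulate_sample(truth, spec, errors, rng, sample_id=sample_id)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_synthetic_vcf(
    sample: SyntheticSample,
    out_dir: str | Path,
    spec: GenomeSpec | None = None,
) -> tuple[Path, Path]:
    """Write a VCF 4.2 file (GT/AD/DP format fields) plus the sidecar
    truth region table; returns (vcf_path, truth_path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / f"{sample.sample_id}.vcf"
    truth_path = out_dir / f"{sample.sample_id}.truth.tsv"
    lengths = (spec or GenomeSpec()).chrom_lengths
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohmap-synthetic\n")
        for c in sorted(lengths, key=lambda c: int(c)):
            fh.write(f"##contig=<ID={c},length={lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
            '"Allelic depths for the ref and alt alleles">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample.sample_id}\n"
        )
        for r in sample.records:
            rs = r.rs_id if r.rs_id is not None else "."
            gt = r.reported_genotype or "./."
            fh.write(
                f"{r.chrom}\t{r.pos}\t{rs}\t{r.ref_allele}\t"
                f"{','.join(r.alt_alleles)}\t.\tPASS\t.\tGT:AD:DP\t"
                f"{gt}:{r.ref_depth},{r.alt_depth}:{r.total_depth}\n"
            )
    write_region_table({sample.sample_id: sample.truth}, truth_path)
    return vcf_path, truth_path


def write_array_table(sample: SyntheticSample, path: str | Path) -> Path:
    """Write the sample's microarray-format genotype table."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tcall\n")
        for c in sample.array_calls:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.call}\n")
    return path
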