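"""Independent brute-force oracles used by the test suite.

Each oracle restates a pipeline rule naively (explicit walks, per-base
sets, full recounting) and stays independent of the vectorised
implementation paths it checks.
"""

from __future__ import annotations

from rohmap.genotyping import GenotypeClass

HET = GenotypeClass.HET


def oracle_regenotype(ref_depth: int, alt_depth: int, params) -> GenotypeClass:
    """Ordered genotyping rules, restated directly."""
    d = ref_depth + alt_depth
    if d == 0:
        return GenotypeClass.DISCARDED
    p_ref = ref_depth / d
    p_alt = alt_depth / d
    if p_alt >= 1.0 - params.n_bb:
        return GenotypeClass.HOM_ALT
    if 0.5 - params.n_het <= p_ref <= 0.5 + params.n_het:
        return GenotypeClass.HET
    if p_ref >= params.n_aa:
        return GenotypeClass.HOM_REF
    return GenotypeClass.DISCARDED


def oracle_flank_removal(genotypes, threshold: int) -> list[bool]:
    """Keep-mask from explicit per-heterozygote flank walks on the
    original list (runs broken by any other heterozygote)."""
    n = len(genotypes)
    keep = [True] * n
    for k in range(n):
        if genotypes[k] is not HET:
            continue
        left = 0
        i = k - 1
        while i >= 0 and genotypes[i] is not HET:
            left += 1
            i -= 1
        right = 0
        i = k + 1
        while i < n and genotypes[i] is not HET:
            right += 1
            i += 1
        if left >= 1 and right >= 1 and left + right >= threshold:
            keep[k] = False
    return keep


def oracle_call_runs(positions, genotypes, x_minimum: float, min_count: int):
    """Greedy maximal-stretch enumeration with naive recounting.

    From each uncovered homozygote i, the stretch runs to the last
    homozygote j with aggregate het fraction <= x_minimum, never
    crossing two adjacent heterozygotes at distinct positions; stretches
    of at least min_count variants become (start, end, count) regions.
    """
    n = len(genotypes)
    regions = []
    scan = 0
    while scan < n:
        i = scan
        while i < n and genotypes[i] is HET:
            i += 1
        if i >= n:
            break
        best_j = i
        for j in range(i, n):
            if (
                j > i
                and genotypes[j] is HET
                and genotypes[j - 1] is HET
                and positions[j] != positions[j - 1]
            ):
                break
            hets = sum(1 for g in genotypes[i : j + 1] if g is HET)
            if genotypes[j] is not HET and hets <= x_minimum * (j - i + 1):
                best_j = j
        count = best_j - i + 1
        if count >= min_count:
            regions.append((positions[i], positions[best_j], count))
        scan = best_j + 1
    return regions


def oracle_symmetric_difference_bp(regions_a, regions_b) -> int:
    """Per-base set arithmetic (small coordinates only)."""
    def bases(regions):
        out = set()
        for r in regions:
            out |= {(r.chrom, b) for b in range(r.start, r.end + 1)}
        return out

    return len(bases(regions_a) ^ bases(regions_b))


def oracle_membership_counts(positions_by_chrom, predicted, gold):
    """Per-variant confusion counts by explicit membership checks."""
    tp = fp = tn = fn = 0
    for chrom, positions in positions_by_chrom.items():
        for pos in positions:
            in_p = any(
                r.start <= pos <= r.end for r in predicted.regions if r.chrom == chrom
            )
            in_g = any(
                r.start <= pos <= r.end for r in gold.regions if r.chrom == chrom
            )
            if in_p and in_g:
                tp += 1
            elif in_p:
                fp += 1
            elif in_g:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn
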