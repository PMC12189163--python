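import numpy as np
import pytest

from rohmap.evaluation import jaccard
from rohmap.genotyping import GenotypeClass, GenotypingParams, genotype_sample, microarray_to_genotyped
from rohmap.io_formats import Region
from rohmap.roh_detection import (
    RohConstants,
    ScaleFactor,
    call_runs,
    compute_scale_factor,
    detect_from_genotyped,
    postprocess_regions,
    remove_aberrant_hets,
    scaled_threshold,
)

from conftest import make_genotypes, random_genotypes
from oracles import oracle_call_runs, oracle_flank_removal


class TestScaleFactor:
    @pytest.mark.parametrize("n_chr1,expected", [(70_700, 1.0), (141_400, 2.0), (35_350, 0.5)])
    def test_reference_ratio(self, n_chr1, expected):
        variants = make_genotypes("h" * 10, chrom="2")
        variants += [v for v in make_genotypes("h", chrom="1")] * n_chr1
        assert compute_scale_factor(variants).value == expected

    def test_no_chr1_fatal(self):
        with pytest.raises(ValueError, match="chromosome 1"):
            compute_scale_factor(make_genotypes("hhhh", chrom="5"))

    def test_scaled_threshold_rounding(self):
        # half-up rounding with a floor of 1
        assert scaled_threshold(575, ScaleFactor(35_350)) == 288  # 287.5 -> 288
        assert scaled_threshold(386, ScaleFactor(70_700)) == 386
        assert scaled_threshold(386, ScaleFactor(7)) == 1


class TestSmoothing:
    def params(self, x_filter):
        return GenotypingParams(x_filter=x_filter)

    def test_removed_when_flanks_reach_threshold(self):
        pattern = "h" * 200 + "e" + "H" * 200
        out, removed = remove_aberrant_hets(
            make_genotypes(pattern), self.params(386), ScaleFactor(70_700)
        )
        assert removed == 1 and len(out) == 400
        assert all(v.genotype is not GenotypeClass.HET for v in out)

    def test_retained_below_threshold(self):
        pattern = "h" * 100 + "e" + "h" * 100
        out, removed = remove_aberrant_hets(
            make_genotypes(pattern), self.params(386), ScaleFactor(70_700)
        )
        assert removed == 0 and len(out) == 201

    def test_chromosome_start_het_retained(self):
        pattern = "e" + "h" * 1000
        out, removed = remove_aberrant_hets(
            make_genotypes(pattern), self.params(386), ScaleFactor(70_700)
        )
        assert removed == 0

    def test_decisions_against_original_list(self):
        # two hets 100 homs apart: each sees the other as a run break,
        # so neither reaches 386 even though removing one would let the
        # other qualify in a fixpoint iteration
        pattern = "h" * 300 + "e" + "h" * 100 + "e" + "h" * 300
        out, removed = remove_aberrant_hets(
            make_genotypes(pattern), self.params(386), ScaleFactor(70_700)
        )
        assert removed == 2  # 300+100=400 >= 386 on both: both removed
        pattern = "h" * 200 + "e" + "h" * 100 + "e" + "h" * 200
        out, removed = remove_aberrant_hets(
            make_genotypes(pattern), self.params(386), ScaleFactor(70_700)
        )
        assert removed == 0  # 200+100=300 < 386 for each

    def test_oracle_equivalence_random(self):
        """Vectorised smoothing equals explicit per-het flank walks on
        200 seeded random genotype lists."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            variants = random_genotypes(rng, het_prob=float(rng.uniform(0.05, 0.6)))
            threshold = int(rng.integers(1, 30))
            params = GenotypingParams(x_filter=threshold)
            out, _ = remove_aberrant_hets(variants, params, ScaleFactor(70_700))
            keep = oracle_flank_removal([v.genotype for v in variants], threshold)
            assert out == [v for v, k in zip(variants, keep) if k]

    def test_never_removes_homozygotes(self):
        rng = np.random.default_rng(7)
        variants = random_genotypes(rng, n=400, het_prob=0.3)
        out, _ = remove_aberrant_hets(variants, self.params(5), ScaleFactor(70_700))
        homs_in = [v for v in variants if v.genotype is not GenotypeClass.HET]
        homs_out = [v for v in out if v.genotype is not GenotypeClass.HET]
        assert homs_in == homs_out
        n_het_out = sum(v.genotype is GenotypeClass.HET for v in out)
        n_het_in = sum(v.genotype is GenotypeClass.HET for v in variants)
        assert n_het_out <= n_het_in


class TestCallRuns:
    def test_pure_homozygous_run_called(self):
        regions = call_runs(make_genotypes("H" * 600), GenotypingParams(),
                            ScaleFactor(70_700))
        assert len(regions) == 1
        assert regions[0].n_variants == 600
        assert (regions[0].start, regions[0].end) == (1_000, 600_000)

    def test_short_run_not_called(self):
        assert call_runs(make_genotypes("H" * 500), GenotypingParams(),
                         ScaleFactor(70_700)) == []

    def test_spread_hets_tolerated(self):
        # 30 hets evenly spread in 600 variants: fraction 0.05 <= 0.1
        pattern = ("h" * 19 + "e") * 30
        regions = call_runs(make_genotypes(pattern), GenotypingParams(),
                            ScaleFactor(70_700))
        assert len(regions) == 1
        # trimmed to homozygous endpoints: trailing het excluded
        assert regions[0].n_variants == 599

    def test_alternating_not_called(self):
        assert call_runs(make_genotypes("He" * 300), GenotypingParams(),
                         ScaleFactor(70_700)) == []

    def test_adjacent_het_pair_breaks_run(self):
        # two long pure runs separated by a double het: two stretches,
        # each below the 575 count, so nothing is called ...
        pattern = "H" * 400 + "ee" + "H" * 400
        assert call_runs(make_genotypes(pattern), GenotypingParams(),
                         ScaleFactor(70_700)) == []
        # ... while a single het glues them into one qualifying stretch
        pattern = "H" * 400 + "e" + "H" * 400
        regions = call_runs(make_genotypes(pattern), GenotypingParams(),
                            ScaleFactor(70_700))
        assert len(regions) == 1 and regions[0].n_variants == 801

    def test_empty_input(self):
        assert call_runs([], GenotypingParams(), ScaleFactor(70_700)) == []

    def test_oracle_equivalence_random(self):
        """call_runs equals the naive greedy maximal-stretch enumeration
        on 200 seeded random genotype lists of up to 500 variants."""
        rng = np.random.default_rng(512)
        for _ in range(200):
            variants = random_genotypes(rng, het_prob=float(rng.uniform(0.02, 0.5)))
            x_min = float(rng.uniform(0.01, 0.5))
            min_count = int(rng.integers(1, 60))
            params = GenotypingParams(x_minimum=x_min, x_call=min_count)
            got = call_runs(variants, params, ScaleFactor(70_700))
            expected = oracle_call_runs(
                [v.pos for v in variants], [v.genotype for v in variants],
                x_min, min_count,
            )
            assert [(r.start, r.end, r.n_variants) for r in got] == expected

    def test_duplication_equivariance(self):
        """Duplicating every post-smoothing variant (doubling density
        and the scaled count threshold) leaves region coordinates
        unchanged."""
        rng = np.random.default_rng(99)
        for _ in range(50):
            variants = random_genotypes(rng, het_prob=0.15)
            doubled = [v for v in variants for _ in range(2)]
            # scales where the rounded count threshold itself doubles
            # exactly; at other scales half-up rounding can move a
            # borderline stretch by one variant
            for scale1 in (0.5, 1.0, 2.0):
                params = GenotypingParams(x_call=int(rng.integers(5, 40)))
                r1 = call_runs(variants, params, ScaleFactor(int(70_700 * scale1)))
                r2 = call_runs(doubled, params, ScaleFactor(int(2 * 70_700 * scale1)))
                assert [(r.start, r.end) for r in r1] == [(r.start, r.end) for r in r2]


class TestPostprocess:
    def test_merge_below_gap(self):
        regions = [
            Region("2", 10_000_000, 12_000_000, 500),
            Region("2", 12_050_000, 14_000_000, 400),
        ]
        out = postprocess_regions(regions)
        assert [(r.chrom, r.start, r.end, r.n_variants) for r in out.regions] == [
            ("2", 10_000_000, 14_000_000, 900)
        ]

    def test_exact_gap_not_merged(self):
        # gap exactly 100,000 is not < 100 kb: both survive on length
        regions = [
            Region("2", 10_000_000, 12_000_000),
            Region("2", 12_100_001, 14_000_000),
        ]
        out = postprocess_regions(regions)
        assert len(out) == 2

    def test_short_region_discounted(self):
        assert len(postprocess_regions([Region("1", 1, 1_400_000)])) == 0
        assert len(postprocess_regions([Region("1", 1, 1_500_000)])) == 1

    def test_merge_before_filter_rescues_short_pair(self):
        # two 1.0 Mb regions 40 kb apart merge into ~2.04 Mb and survive;
        # filter-first would discard both
        regions = [
            Region("4", 1_000_000, 1_999_999),
            Region("4", 2_040_000, 3_039_999),
        ]
        assert len(postprocess_regions(regions)) == 1
        filter_first = RohConstants(merge_first=False)
        assert len(postprocess_regions(regions, filter_first)) == 0

    def test_idempotent_on_random_inputs(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            regions = []
            for _ in range(rng.integers(0, 12)):
                chrom = str(rng.integers(1, 5))
                start = int(rng.integers(1, 50_000_000))
                length = int(rng.integers(100_000, 5_000_000))
                regions.append(Region(chrom, start, start + length - 1))
            # drop overlaps to satisfy input contract
            regions.sort(key=lambda r: (r.chrom, r.start))
            pruned = []
            for r in regions:
                if pruned and pruned[-1].chrom == r.chrom and r.start <= pruned[-1].end:
                    continue
                pruned.append(r)
            once = postprocess_regions(pruned)
            twice = postprocess_regions(once.regions)
            assert once.regions == twice.regions

    def test_all_outputs_satisfy_invariants(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            regions = []
            pos = 1
            for _ in range(rng.integers(1, 10)):
                pos += int(rng.integers(10_000, 3_000_000))
                length = int(rng.integers(100_000, 4_000_000))
                regions.append(Region("1", pos, pos + length - 1))
                pos += length
            out = postprocess_regions(regions)
            for r in out.regions:
                assert r.length >= 1_500_000
            for a, b in zip(out.regions, out.regions[1:]):
                assert b.start - a.end - 1 >= 100_000


class TestFullPipeline:
    def test_planted_segment_recovered(self, small_sample):
        genotyped, _ = genotype_sample(small_sample.records, GenotypingParams())
        detected, report = detect_from_genotyped(genotyped, sample_id="S1")
        assert jaccard(detected, small_sample.truth) >= 0.95
        assert report["n_regions"] == len(detected)

    def test_outbred_sample_empty(self, small_outbred_sample):
        genotyped, _ = genotype_sample(small_outbred_sample.records,
                                       GenotypingParams())
        detected, _ = detect_from_genotyped(genotyped)
        assert len(detected) == 0

    def test_regions_meet_count_and_length_floors(self, small_sample):
        genotyped, _ = genotype_sample(small_sample.records, GenotypingParams())
        detected, report = detect_from_genotyped(genotyped)
        for r in detected.regions:
            assert r.n_variants >= report["x_call_scaled"]
            assert r.length >= 1_500_000

    def test_microarray_route_matches_sequencing(self, small_sample):
        """Array calls of the same genome (joining at the smoothing
        stage) give regions closely matching the sequencing-derived
        list."""
        genotyped, _ = genotype_sample(small_sample.records, GenotypingParams())
        seq_regions, _ = detect_from_genotyped(genotyped, sample_id="S1")
        arr = microarray_to_genotyped(small_sample.array_calls)
        arr_regions, _ = detect_from_genotyped(arr, sample_id="S1")
        assert jaccard(seq_regions, arr_regions) >= 0.95
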