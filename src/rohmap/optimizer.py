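"""Genetic-algorithm tuning of the detection parameters.

Candidate parameter sets live on the discrete grids below.  Each
candidate is scored by running the full detector on every training
sample and summing the megabase discordance between the detected and
gold-standard regions (lower is better).  Each generation keeps every
candidate scoring no worse than the tenth-best (ties retained),
carries the survivors forward unchanged, fills with children of
randomly paired survivors — each child parameter a fair coin pick
between its parents, overwritten with probability 1/5 by a fresh
uniform draw — and pads with random sets back to the population size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .evaluation import megabase_difference_score
from .genotyping import GenotypingParams, VariantTable
from .io_formats import RegionSet
from .roh_detection import RohConstants, _call_runs_arrays, _smooth_mask, postprocess_regions, scaled_threshold, ScaleFactor

logger = logging.getLogger(__name__)

#: (lower, upper, granularity) search grid per tunable parameter
DEFAULT_RANGES: dict[str, tuple[float, float, float]] = {
    "n_r": (0, 19, 1),
    "n_aa": (0.56, 0.95, 0.01),
    "n_bb": (0.05, 0.34, 0.01),
    "n_het": (0.05, 0.34, 0.01),
    "x_filter": (75, 574, 1),
    "x_minimum": (0.01, 0.50, 0.01),
    "x_call": (300, 1499, 1),
}

_INT_PARAMS = {"n_r", "x_filter", "x_call"}


@dataclass(frozen=True)
class ParameterRanges:
    grids: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )

    def n_steps(self, name: str) -> int:
        lo, hi, step = self.grids[name]
        return int(round((hi - lo) / step)) + 1

    def draw(self, name: str, rng: np.random.Generator) -> float | int:
        lo, _, step = self.grids[name]
        v = lo + step * int(rng.integers(0, self.n_steps(name)))
        return int(round(v)) if name in _INT_PARAMS else round(v, 10)

    def contains(self, params: GenotypingParams) -> bool:
        d = params.as_dict()
        for name, (lo, hi, step) in self.grids.items():
            v = d[name]
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                return False
            if abs((v - lo) / step - round((v - lo) / step)) > 1e-6:
                return False
        return True


@dataclass(frozen=True)
class ScoredParameterSet:
    params: GenotypingParams
    score: float
    generation: int = 0


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    survivor_rank: int = 10
    mutation_prob: float = 0.2
    generations: int = 45
    restarts: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.population_size >= self.survivor_rank >= 2):
            raise ValueError("need population_size >= survivor_rank >= 2")
        if not (0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("mutation_prob must be in [0, 1]")


# ---------------------------------------------------------------------------
# GA primitives
# ---------------------------------------------------------------------------

def random_parameter_set(
    ranges: ParameterRanges, rng: np.random.Generator
) -> GenotypingParams:
    """Uniform draw from each parameter's discrete grid."""
    return GenotypingParams(
        **{name: ranges.draw(name, rng) for name in ranges.grids}
    )


def mate(
    a: GenotypingParams,
    b: GenotypingParams,
    ranges: ParameterRanges,
    mutation_prob: float,
    rng: np.random.Generator,
) -> GenotypingParams:
    """Per parameter: mutate with probability ``mutation_prob`` (fresh
    uniform grid draw), else a fair coin pick between the parents."""
    da, db = a.as_dict(), b.as_dict()
    child = {}
    for name in ranges.grids:
        if rng.random() < mutation_prob:
            child[name] = ranges.draw(name, rng)
        else:
            child[name] = da[name] if rng.random() < 0.5 else db[name]
    return replace(a, **child)


def select_survivors(
    population: Sequence[ScoredParameterSet], survivor_rank: int
) -> list[ScoredParameterSet]:
    """Every member scoring <= the survivor_rank-th best score (ties
    can make the survivor list longer than the rank)."""
    ordered = sorted(population, key=lambda m: m.score)
    if len(ordered) <= survivor_rank:
        return ordered
    cutoff = ordered[survivor_rank - 1].score
    return [m for m in ordered if m.score <= cutoff]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class _Scorer:
    """Runs the detector on prepared columnar training samples; caches
    by parameter tuple so elitist survivors are never re-scored."""

    def __init__(
        self,
        training: Sequence[tuple[VariantTable, RegionSet]],
        constants: RohConstants = RohConstants(),
    ):
        if not training:
            raise ValueError("empty training set")
        self.training = list(training)
        self.constants = constants
        self.cache: dict[tuple, float] = {}

    @staticmethod
    def _key(params: GenotypingParams) -> tuple:
        d = params.as_dict()
        return tuple(d[k] for k in sorted(d))

    def score(self, params: GenotypingParams) -> float:
        key = self._key(params)
        if key in self.cache:
            return self.cache[key]
        total = 0.0
        for table, gold in self.training:
            chrom, pos, codes = table.genotype(params)
            n_chr1 = int((chrom == "1").sum())
            if n_chr1 == 0:
                total += sum(
                    g.total_bp() for _, g in self.training
                ) / 1e6 + 1e6  # unusable parameters: worst possible
                break
            scale = ScaleFactor(chr1_variant_count=n_chr1)
            raw = []
            for c in np.unique(chrom):
                m = chrom == c
                keep = _smooth_mask(
                    codes[m], scaled_threshold(params.x_filter, scale)
                )
                raw.extend(
                    _call_runs_arrays(
                        pos[m][keep],
                        codes[m][keep],
                        params.x_minimum,
                        scaled_threshold(params.x_call, scale),
                        str(c),
                    )
                )
            detected = postprocess_regions(raw, self.constants, gold.sample_id)
            total += megabase_difference_score(detected, gold)
        self.cache[key] = total
        return total


# ---------------------------------------------------------------------------
# evolution loop
# ---------------------------------------------------------------------------

def evolve(
    training: Sequence[tuple[VariantTable, RegionSet]],
    config: GAConfig = GAConfig(),
    ranges: ParameterRanges = ParameterRanges(),
    constants: RohConstants = RohConstants(),
) -> tuple[ScoredParameterSet, list[dict]]:
    """Run the GA; returns the best-ever scored set and a per-generation
    history (restart, generation, best, mean, population size).

    Fully deterministic given ``config.rng_seed``; ``restarts``
    independent repetitions keep the global best.
    """
    scorer = _Scorer(training, constants)
    best_overall: ScoredParameterSet | None = None
    history: list[dict] = []
    for restart in range(config.restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.rng_seed, restart])
        )
        population = [
            ScoredParameterSet(
                params=random_parameter_set(ranges, rng),
                score=np.nan,
                generation=0,
            )
            for _ in range(config.population_size)
        ]
        for gen in range(config.generations):
            population = [
                ScoredParameterSet(m.params, scorer.score(m.params), gen)
                if np.isnan(m.score)
                else m
                for m in population
            ]
            scores = [m.score for m in population]
            history.append(
                {
                    "restart": restart,
                    "generation": gen,
                    "best": float(min(scores)),
                    "mean": float(np.mean(scores)),
                    "population": len(population),
                }
            )
            survivors = select_survivors(population, config.survivor_rank)
            if best_overall is None or survivors[0].score < best_overall.score:
                best_overall = survivors[0]
            if gen == config.generations - 1:
                break
            # elitism: survivors persist unchanged; children of random
            # survivor pairs fill the rest; pad with random sets.  the
            # population is kept free of duplicate parameter vectors:
            # fitness plateaus make cutoff ties common, and without
            # deduplication tied clones swell the survivor list until
            # no new candidate is ever tried
            seen: set = set()
            nxt: list[ScoredParameterSet] = []
            for m in survivors:
                key = _Scorer._key(m.params)
                if key not in seen:
                    seen.add(key)
                    nxt.append(m)
            n_elite = len(nxt)
            n_children = max(
                config.population_size - n_elite, config.population_size // 2
            )
            attempts = 0
            while (
                len(nxt) < n_elite + n_children
                and n_elite >= 2
                and attempts < 50 * n_children
            ):
                attempts += 1
                i, j = rng.choice(n_elite, size=2, replace=False)
                child = mate(
                    nxt[int(i)].params,
                    nxt[int(j)].params,
                    ranges,
                    config.mutation_prob,
                    rng,
                )
                key = _Scorer._key(child)
                if key in seen:
                    continue
                seen.add(key)
                nxt.append(ScoredParameterSet(child, np.nan, gen + 1))
            while len(nxt) < config.population_size:
                fresh = random_parameter_set(ranges, rng)
                key = _Scorer._key(fresh)
                if key in seen:
                    continue
                seen.add(key)
                nxt.append(ScoredParameterSet(fresh, np.nan, gen + 1))
            population = nxt
    assert best_overall is not None
    logger.info("GA best score %.3f", best_overall.score)
    return best_overall, history
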