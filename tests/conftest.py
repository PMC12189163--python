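from __future__ import annotations

import numpy as np
import pytest

from rohmap.genotyping import GenotypeClass, GenotypedVariant, GenotypingParams
from rohmap.synthetic import ErrorModel, GenomeSpec, generate_sample

_CODE = {
    "h": GenotypeClass.HOM_REF,
    "H": GenotypeClass.HOM_ALT,
    "e": GenotypeClass.HET,
}


def make_genotypes(pattern: str, chrom: str = "1", start: int = 1_000,
                   step: int = 1_000) -> list[GenotypedVariant]:
    """Genotype list from a compact pattern: h=hom-ref, H=hom-alt, e=het."""
    return [
        GenotypedVariant(chrom=chrom, pos=start + k * step, genotype=_CODE[c])
        for k, c in enumerate(pattern)
    ]


def random_genotypes(rng: np.random.Generator, n: int | None = None,
                     het_prob: float = 0.3, chrom: str = "1"):
    """Random sorted genotype list with distinct positions."""
    n = n if n is not None else int(rng.integers(1, 501))
    pos = np.sort(rng.choice(np.arange(1, n * 10 + 1), size=n, replace=False))
    kinds = rng.choice(
        [GenotypeClass.HOM_REF, GenotypeClass.HET, GenotypeClass.HOM_ALT],
        size=n,
        p=[(1 - het_prob) / 2, het_prob, (1 - het_prob) / 2],
    )
    return [
        GenotypedVariant(chrom=chrom, pos=int(p), genotype=g)
        for p, g in zip(pos, kinds)
    ]


@pytest.fixture(scope="session")
def default_params() -> GenotypingParams:
    return GenotypingParams()


@pytest.fixture(scope="session")
def small_sample():
    """One reduced-scale autozygous sample shared across tests."""
    return generate_sample(GenomeSpec.reduced(0.05), ErrorModel(), seed=11,
                           sample_id="S1")


@pytest.fixture(scope="session")
def small_outbred_sample():
    return generate_sample(
        GenomeSpec.reduced(0.05, autozygous_fraction=0.0), ErrorModel(), seed=12,
        sample_id="S0",
    )
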