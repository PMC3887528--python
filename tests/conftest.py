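"""Shared fixtures: small hand-built records and a desk-scale simulation."""

import numpy as np
import pytest
from hypothesis import settings

from popld.simulate import SimulationConfig, simulate_founders, simulate_population
from popld.vcf_io import SiteRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_record(
    chrom="2R",
    pos=100,
    ref="A",
    alts=("T",),
    dosages=(0, 1, 2),
    missing=(),
    annotations=None,
):
    """SiteRecord from a dosage tuple; indices in ``missing`` become ./."""
    genotypes = []
    for i, d in enumerate(dosages):
        if i in missing:
            genotypes.append((None, None))
        else:
            genotypes.append((0, 0) if d == 0 else (0, 1) if d == 1 else (1, 1))
    return SiteRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        genotypes=genotypes,
        annotations=annotations or {},
    )


@pytest.fixture(scope="session")
def small_matrix():
    """2,000-site two-population matrix on a 200 kb chromosome."""
    cfg = SimulationConfig(
        seed=11,
        chrom="2R",
        chrom_length=200_000,
        n_sites=2000,
        n_founders=24,
        theta_fst=0.06,
        n_per_pop={"TZ": 12, "CM": 8},
        inversions=[],
        centromere=None,
    )
    matrix, truth = simulate_population(simulate_founders(cfg), cfg)
    return matrix, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
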