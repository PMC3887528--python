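"""Genotype r², LD decay and windowed LD against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popld.linkage import (
    genotype_r2,
    ld_decay,
    mean_r2_in_regions,
    windowed_ld,
)
from popld.simulate import SimulationConfig, simulate_founders, simulate_population
from popld.vcf_io import MISSING, GenotypeMatrix


def brute_force_r2(d1, d2):
    """Oracle: numpy Pearson correlation on the complete-case subset."""
    d1, d2 = np.asarray(d1), np.asarray(d2)
    ok = (d1 != MISSING) & (d2 != MISSING)
    if ok.sum() < 2:
        return None
    x, y = d1[ok].astype(float), d2[ok].astype(float)
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def brute_force_decay(matrix, max_dist, bin_width):
    """Oracle: exhaustive double loop over all site pairs."""
    nb = max_dist // bin_width + (1 if max_dist % bin_width else 0)
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=int)
    for i in range(matrix.n_sites):
        ci, pi = matrix.sites[i][0], matrix.sites[i][1]
        for j in range(i + 1, matrix.n_sites):
            cj, pj = matrix.sites[j][0], matrix.sites[j][1]
            if ci != cj:
                continue
            dist = abs(pj - pi)
            if dist == 0 or dist > max_dist:
                continue
            r2 = brute_force_r2(matrix.dosages[i], matrix.dosages[j])
            if r2 is None:
                continue
            b = min((dist - 1) // bin_width, nb - 1)
            sums[b] += r2
            counts[b] += 1
    return sums, counts


def random_matrix(rng, n_sites=60, n_samples=8, missing_rate=0.0, chroms=("2R",)):
    positions = {}
    sites = []
    for c in chroms:
        pos = np.sort(rng.choice(np.arange(1, 2000), size=n_sites, replace=False))
        positions[c] = pos
        sites += [(c, int(p), "A", "T") for p in pos]
    dosages = rng.integers(0, 3, size=(len(sites), n_samples)).astype(np.int8)
    if missing_rate:
        mask = rng.random(dosages.shape) < missing_rate
        dosages = np.where(mask, np.int8(MISSING), dosages)
    samples = [f"S{i}" for i in range(n_samples)]
    return GenotypeMatrix(sites=sites, dosages=dosages, samples=samples)


class TestGenotypeR2:
    def test_identical_vectors(self):
        assert genotype_r2(np.array([0, 1, 2, 0]), np.array([0, 1, 2, 0])) == pytest.approx(1.0)

    def test_orthogonal_contrast(self):
        assert genotype_r2(np.array([0, 0, 2, 2]), np.array([0, 2, 0, 2])) == pytest.approx(0.0)

    def test_complete_case_subset_hand_computed(self):
        # complete cases are the first four samples; r = 0.5 there
        d1 = np.array([0, 1, 2, 1, MISSING])
        d2 = np.array([0, 1, 1, 2, 2])
        assert genotype_r2(d1, d2) == pytest.approx(0.25)

    def test_constant_vector_skipped(self):
        assert genotype_r2(np.array([1, 1, 1, 1]), np.array([0, 1, 2, 0])) is None
        # constant only after restriction to complete cases
        assert genotype_r2(np.array([0, 1, 1, 1]), np.array([MISSING, 0, 1, 2])) is None

    @settings(deadline=None, max_examples=200)
    @given(
        d1=st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=2, max_size=12),
        seed=st.integers(0, 2**20),
    )
    def test_matches_numpy_oracle_and_symmetry(self, d1, seed):
        rng = np.random.default_rng(seed)
        d2 = rng.choice([0, 1, 2, MISSING], size=len(d1))
        got = genotype_r2(np.array(d1), d2)
        expected = brute_force_r2(d1, d2)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)
            assert genotype_r2(d2, np.array(d1)) == pytest.approx(got)

    def test_invariant_under_flip_and_affine_rescaling(self):
        rng = np.random.default_rng(5)
        d1 = rng.integers(0, 3, size=20)
        d2 = rng.integers(0, 3, size=20)
        base = genotype_r2(d1, d2)
        assert genotype_r2(2 - d1, d2) == pytest.approx(base)
        assert genotype_r2(d1, 2 - d2) == pytest.approx(base)
        # affine rescaling of the underlying vectors leaves Pearson r² unchanged
        x, y = d1.astype(float), d2.astype(float)
        r = np.corrcoef(3.0 * x + 1.0, -2.0 * y + 5.0)[0, 1] ** 2
        assert r == pytest.approx(base)


class TestLdDecay:
    def test_single_close_pair(self):
        m = GenotypeMatrix(
            sites=[("2R", 100, "A", "T"), ("2R", 150, "A", "T")],
            dosages=np.array([[0, 1, 2, 0], [0, 1, 2, 0]], dtype=np.int8),
            samples=["a", "b", "c", "d"],
        )
        curves = ld_decay(m, max_dist=1000, bin_width=100)
        assert curves["2R"].mean_r2[0] == pytest.approx(1.0)
        assert curves["2R"].pair_count[0] == 1

    def test_pairs_on_different_chromosomes_ignored(self):
        m = GenotypeMatrix(
            sites=[("2R", 100, "A", "T"), ("3R", 150, "A", "T")],
            dosages=np.array([[0, 1, 2, 0], [0, 1, 2, 0]], dtype=np.int8),
            samples=["a", "b", "c", "d"],
        )
        curves = ld_decay(m, max_dist=1000, bin_width=100)
        assert curves["all"].pair_count.sum() == 0

    @pytest.mark.parametrize("missing_rate", [0.0, 0.15])
    def test_matches_exhaustive_double_loop(self, missing_rate, rng):
        m = random_matrix(rng, n_sites=50, missing_rate=missing_rate, chroms=("2R", "3L"))
        curves = ld_decay(m, max_dist=500, bin_width=50, per_chromosome=False)
        sums, counts = brute_force_decay(m, max_dist=500, bin_width=50)
        curve = curves["all"]
        assert (curve.pair_count == counts).all()
        for b in range(len(counts)):
            if counts[b]:
                assert curve.mean_r2[b] == pytest.approx(sums[b] / counts[b])

    def test_mosaic_simulation_decays_with_distance(self):
        cfg = SimulationConfig(
            seed=3,
            chrom_length=100_000,
            n_sites=1500,
            n_founders=6,
            switch_rate=1e-3,
            theta_fst=0.0,
            n_per_pop={"TZ": 20},
            inversions=[],
            centromere=None,
        )
        m, _ = simulate_population(simulate_founders(cfg), cfg)
        curves = ld_decay(m, max_dist=1000, bin_width=100)
        curve = curves["2R"]
        assert curve.bin_mean(0, 100) > curve.bin_mean(900, 1000)


class TestWindowedLd:
    def _matrix_with_pairs(self, n_sites, spacing, n_samples=6, length=100_000):
        rng = np.random.default_rng(9)
        pos = np.arange(1, n_sites + 1) * spacing
        dos = np.tile(rng.integers(0, 3, size=n_samples), (n_sites, 1)).astype(np.int8)
        sites = [("2R", int(p), "A", "T") for p in pos]
        return GenotypeMatrix(sites=sites, dosages=dos, samples=[f"S{i}" for i in range(n_samples)])

    def test_identical_sites_give_window_mean_one(self):
        m = self._matrix_with_pairs(40, 2000)
        stats = windowed_ld(m, min_pairs=10, chrom_lengths={"2R": 100_000})
        kept = [w for w in stats if not w.excluded]
        assert kept and all(w.value == pytest.approx(1.0) for w in kept)

    def test_pairs_closer_than_min_sep_not_counted(self):
        m = self._matrix_with_pairs(10, 500)  # all gaps 500 bp < 1 kb... up to 4.5 kb
        stats = windowed_ld(m, min_sep=1000, max_sep=10_000, min_pairs=1, chrom_lengths={"2R": 100_000})
        n_total = sum(w.n_values for w in stats if w.start % 100_000 == 0)
        # pairs at distance 500 excluded; only >= 1000 bp pairs counted
        positions = m.positions("2R")
        expected = sum(
            1
            for i in range(len(positions))
            for j in range(i + 1, len(positions))
            if 1000 <= positions[j] - positions[i] <= 10_000
        )
        assert n_total == expected

    def test_min_pairs_exclusion_boundary(self):
        # windows need >= min_pairs contributing values
        m = self._matrix_with_pairs(15, 1500)
        stats = windowed_ld(m, min_pairs=10**6, chrom_lengths={"2R": 100_000})
        assert all(w.excluded for w in stats)

    def test_invalid_separation_rejected(self, small_matrix):
        matrix, _, _ = small_matrix
        with pytest.raises(ValueError):
            windowed_ld(matrix, min_sep=5000, max_sep=1000)


class TestSimulationLimits:
    def test_zero_switch_rate_two_founders_gives_complete_ld(self):
        cfg = SimulationConfig(
            seed=7,
            chrom_length=50_000,
            n_sites=150,
            n_founders=2,
            switch_rate=0.0,
            theta_fst=0.0,
            n_per_pop={"TZ": 10},
            inversions=[],
            centromere=None,
        )
        m, _ = simulate_population(simulate_founders(cfg), cfg)
        polymorphic = [
            i for i in range(m.n_sites) if len(np.unique(m.dosages[i])) > 1
        ]
        assert len(polymorphic) > 10
        for i in polymorphic[:25]:
            for j in polymorphic[1:26]:
                if i >= j:
                    continue
                r2 = genotype_r2(m.dosages[i], m.dosages[j])
                assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_inversion_heterokaryotype_suppression_elevates_ld(self):
        cfg = SimulationConfig(seed=1)  # default: 2Rc inversion, 50/50 karyotypes
        m, _ = simulate_population(simulate_founders(cfg), cfg)
        iv = [(cfg.chrom, cfg.inversions[0].start, cfg.inversions[0].end)]
        inside, n_in = mean_r2_in_regions(m, iv)
        outside, n_out = mean_r2_in_regions(m, iv, invert=True)
        assert n_in > 1000 and n_out > 1000
        assert inside > outside
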