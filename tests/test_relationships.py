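"""Pedigree A, its sparse inverse, genomic G and IBD inbreeding."""

import numpy as np
import pytest

from conftest import recursive_kinship
from sgesim.fixtures import make_fixture
from sgesim.genome import GenomeSpec, make_offspring, simulate_founders
from sgesim.relationships import (
    build_A,
    build_A_inverse,
    build_G,
    true_inbreeding,
)


def _random_pedigree(n, n_founders, seed):
    rng = np.random.default_rng(seed)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(n_founders, n):
        sire[i], dam[i] = rng.integers(0, i, size=2)
    return sire, dam


class TestA:
    def test_textbook_values(self):
        fx = make_fixture("trio_pedigree")
        a = build_A(fx.inputs["sire"], fx.inputs["dam"])
        np.testing.assert_allclose(a, fx.expected["A"])
        # full sibs related 0.5; their offspring has F = 0.25
        sire = np.array([-1, -1, 0, 0, 2])
        dam = np.array([-1, -1, 1, 1, 3])
        a = build_A(sire, dam)
        assert a[2, 3] == pytest.approx(0.5)
        assert a[4, 4] == pytest.approx(1.25)

    def test_matches_recursive_kinship_oracle(self):
        sire, dam = _random_pedigree(200, 20, seed=5)
        a = build_A(sire, dam)
        oracle = recursive_kinship(sire, dam)
        np.testing.assert_allclose(a, oracle, atol=1e-12)

    def test_unsorted_pedigree_rejected(self):
        with pytest.raises(ValueError):
            build_A(np.array([1, -1]), np.array([-1, -1]))


class TestAInverse:
    def test_founders_give_identity(self):
        sire = np.full(4, -1)
        dam = np.full(4, -1)
        np.testing.assert_allclose(
            build_A_inverse(sire, dam).toarray(), np.eye(4)
        )

    def test_trio_pattern(self):
        fx = make_fixture("trio_pedigree")
        ainv = build_A_inverse(fx.inputs["sire"], fx.inputs["dam"]).toarray()
        np.testing.assert_allclose(ainv, fx.expected["A_inv"], atol=1e-12)
        np.testing.assert_allclose(np.diag(ainv), [1.5, 1.5, 2.0])

    def test_product_with_A_is_identity(self):
        sire, dam = _random_pedigree(500, 40, seed=9)
        a = build_A(sire, dam)
        ainv = build_A_inverse(sire, dam).toarray()
        np.testing.assert_allclose(a @ ainv, np.eye(500), atol=1e-8)


@pytest.fixture(scope="module")
def genome():
    spec = GenomeSpec.random(
        n_chromosomes=10, total_length=20.0, n_markers=5000, n_qtl=10, seed=3
    )
    founders = simulate_founders(spec, 40, seed=4)
    return spec, founders


class TestG:
    def test_duplicated_animal_rows_match(self, genome):
        spec, founders = genome
        d = founders.dosage(spec.marker_indices)
        d2 = np.vstack([d, d[:1]])
        p = d.mean(axis=0) / 2
        g = build_G(d2, p, blend=0.0)  # pure VanRaden: clones are identical
        np.testing.assert_allclose(g[0], g[-1], atol=1e-12)
        g_blend = build_G(d2, p)
        assert g_blend[0, -1] == pytest.approx(g_blend[0, 0], rel=0.02)

    def test_parent_offspring_expectation(self, genome):
        """E[G] for a parent-offspring pair is ~0.5 at many markers."""
        spec, founders = genome
        rng = np.random.default_rng(5)
        sires = np.arange(20)
        dams = np.arange(20, 40)
        off = make_offspring(founders, sires, dams, spec, rng)
        from sgesim.genome import HaplotypeSet

        both = HaplotypeSet.concatenate([founders, off])
        d = both.dosage(spec.marker_indices)
        p = founders.dosage(spec.marker_indices).mean(axis=0) / 2
        g = build_G(d, p)
        po = np.array([g[s, 40 + i] for i, s in enumerate(sires)])
        assert po.mean() == pytest.approx(0.5, abs=0.05)

    def test_base_diagonal_scaling(self, genome):
        """VanRaden scaling: mean diagonal ~ 1 for the base cohort when base
        frequencies are used for centering."""
        spec, founders = genome
        d = founders.dosage(spec.marker_indices)
        p = d.mean(axis=0) / 2
        g = build_G(d, p)
        assert np.diag(g).mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_markers_rejected(self):
        with pytest.raises(ValueError):
            build_G(np.zeros((3, 5)), np.zeros(5))


class TestTrueInbreeding:
    def test_founders_not_inbred(self):
        spec = GenomeSpec.random(
            n_chromosomes=2, total_length=2.0, n_markers=50, n_qtl=10, seed=6
        )
        founders = simulate_founders(spec, 5, seed=7)
        np.testing.assert_array_equal(true_inbreeding(founders.labels), 0.0)

    def test_selfed_founder_half_inbred(self):
        spec = GenomeSpec.random(
            n_chromosomes=5, total_length=5.0, n_markers=900, n_qtl=100, seed=8
        )
        founders = simulate_founders(spec, 2, seed=9)
        rng = np.random.default_rng(10)
        selfed = make_offspring(
            founders, np.zeros(200, dtype=int), np.zeros(200, dtype=int), spec, rng
        )
        assert true_inbreeding(selfed.labels).mean() == pytest.approx(0.5, abs=0.02)

    def test_wright_rate_in_closed_population(self):
        """Delta F in a closed random-mating population with 10 males and 10
        females per generation is ~ 1/(8 Nm) + 1/(8 Nf) = 2.5% per
        generation (Wright's formula)."""
        from sgesim.metrics import delta_f

        spec = GenomeSpec.random(
            n_chromosomes=6, total_length=6.0, n_markers=400, n_qtl=50, seed=11
        )
        nm = nf = 10
        rates = []
        for rep in range(12):
            rng = np.random.default_rng(100 + rep)
            pop = simulate_founders(spec, nm + nf, seed=200 + rep)
            fbar = {}
            for gen in range(2, 9):
                # random union of gametes within the sex constraint
                sires = rng.integers(0, nm, size=nm + nf)
                dams = nm + rng.integers(0, nf, size=nm + nf)
                pop = make_offspring(pop, sires, dams, spec, rng)
                fbar[gen] = float(true_inbreeding(pop.labels).mean())
            rates.append(delta_f(fbar, sorted(fbar)))
        expected = 100 * (1 / (8 * nm) + 1 / (8 * nf))
        assert np.mean(rates) == pytest.approx(expected, abs=0.6)
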