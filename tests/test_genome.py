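"""Gene dropping, founder sampling and QTL-effect scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sgesim.genome import (
    GenomeSpec,
    make_offspring,
    meiosis,
    sample_raw_effects,
    scale_qtl_effects,
    simulate_founders,
    true_genetic_values,
)


@pytest.fixture(scope="module")
def small_spec():
    return GenomeSpec.random(
        n_chromosomes=4, total_length=4.0, n_markers=60, n_qtl=40, seed=7
    )


class TestFounders:
    def test_counts_labels_and_shapes(self):
        spec = GenomeSpec.random(
            n_chromosomes=1, total_length=1.0, n_markers=8, n_qtl=2, seed=0
        )
        founders = simulate_founders(spec, 2, seed=1)
        assert founders.alleles.shape == (2, 2, 10)
        labels = np.unique(founders.labels)
        assert labels.size == 4  # two unique labels per founder
        # labels constant along the locus axis
        assert np.all(founders.labels.min(axis=2) == founders.labels.max(axis=2))

    def test_mean_allele_frequency_matches_sampler(self):
        # with the sampler pinned at 0.5 the realized frequency is binomial
        spec = GenomeSpec.random(
            n_chromosomes=1, total_length=1.0, n_markers=99000, n_qtl=1000,
            seed=0, freq_low=0.5, freq_high=0.5,
        )
        founders = simulate_founders(spec, 20, seed=3)
        assert abs(founders.alleles.mean() - 0.5) < 0.005

    def test_seeded_rerun_is_identical(self, small_spec):
        a = simulate_founders(small_spec, 5, seed=11)
        b = simulate_founders(small_spec, 5, seed=11)
        np.testing.assert_array_equal(a.alleles, b.alleles)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_too_few_founders_rejected(self, small_spec):
        with pytest.raises(ValueError):
            simulate_founders(small_spec, 1, seed=0)


class TestMeiosis:
    def test_poisson_crossover_rate(self):
        # one chromosome of 1 Morgan, dense loci: label switches along the
        # gamete count realized crossovers (double crossovers between
        # adjacent loci are vanishingly rare at this density)
        spec = GenomeSpec.random(
            n_chromosomes=1, total_length=1.0, n_markers=900, n_qtl=100, seed=2
        )
        parent = simulate_founders(spec, 2, seed=4)
        rng = np.random.default_rng(9)
        n_meioses = 30000
        switches = 0
        for _ in range(n_meioses):
            _, labels = meiosis(parent.alleles[0], parent.labels[0], spec, rng)
            switches += np.sum(labels[1:] != labels[:-1])
        assert abs(switches / n_meioses - 1.0) < 0.02

    def test_zero_length_chromosome_is_intact(self):
        # a (near-)zero map length means no recombination: the gamete is an
        # intact parental haplotype chosen with probability one half
        spec = GenomeSpec.random(
            n_chromosomes=1, total_length=1e-9, n_markers=20, n_qtl=4, seed=5
        )
        parent = simulate_founders(spec, 2, seed=6)
        rng = np.random.default_rng(0)
        hits = set()
        for _ in range(40):
            _, labels = meiosis(parent.alleles[0], parent.labels[0], spec, rng)
            assert np.unique(labels).size == 1  # an intact parental haplotype
            hits.add(int(labels[0]))
        assert hits == {0, 1}  # both haplotypes chosen over repeats

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_ibd_closure(self, seed, small_spec):
        """Offspring founder labels are a subset of the parents' labels."""
        founders = simulate_founders(small_spec, 4, seed=seed)
        rng = np.random.default_rng(seed)
        off = make_offspring(founders, np.array([0, 1]), np.array([2, 3]),
                             small_spec, rng)
        for i, (s, d) in enumerate([(0, 2), (1, 3)]):
            allowed = set(founders.labels[s].ravel()) | set(founders.labels[d].ravel())
            assert set(off.labels[i].ravel()) <= allowed

    def test_drift_only_allele_frequencies_stable(self, small_spec):
        """Without selection, offspring allele frequencies match the parents
        in expectation (pure drift)."""
        founders = simulate_founders(small_spec, 60, seed=8)
        rng = np.random.default_rng(8)
        sires = rng.integers(0, 30, size=1000)
        dams = rng.integers(30, 60, size=1000)
        off = make_offspring(founders, sires, dams, small_spec, rng)
        p0 = founders.dosage().mean(axis=0) / 2
        p1 = off.dosage().mean(axis=0) / 2
        assert abs(np.mean(p1 - p0)) < 0.01


class TestQTLScaling:
    def _founders(self, spec, n=400, seed=1):
        return simulate_founders(spec, n, seed=seed)

    def test_zero_target_correlation_is_exact(self, small_spec):
        target = np.array([[1.0, 0.0], [0.0, 0.01]])
        f = self._founders(small_spec)
        raw = sample_raw_effects(small_spec.n_qtl, target, np.random.default_rng(2))
        eff = scale_qtl_effects(raw, f.dosage(small_spec.qtl_indices), target)
        u = f.dosage(small_spec.qtl_indices) @ eff.effects
        c = np.cov(u, rowvar=False)
        assert abs(c[0, 1]) < 1e-8
        assert abs(c[0, 0] - 1.0) < 1e-8
        assert abs(c[1, 1] - 0.01) < 1e-8

    def test_nonzero_covariance_matches_definition(self, small_spec):
        cov = 0.5 * np.sqrt(0.001)
        target = np.array([[1.0, cov], [cov, 0.001]])
        f = self._founders(small_spec)
        raw = sample_raw_effects(small_spec.n_qtl, target, np.random.default_rng(3))
        eff = scale_qtl_effects(raw, f.dosage(small_spec.qtl_indices), target)
        u = f.dosage(small_spec.qtl_indices) @ eff.effects
        assert abs(np.cov(u, rowvar=False)[0, 1] - cov) < 1e-8

    def test_scale_invariance_of_raw_effects(self, small_spec):
        target = np.array([[1.0, 0.0], [0.0, 0.01]])
        f = self._founders(small_spec)
        raw = sample_raw_effects(small_spec.n_qtl, target, np.random.default_rng(4))
        d = f.dosage(small_spec.qtl_indices)
        e1 = scale_qtl_effects(raw, d, target)
        e2 = scale_qtl_effects(2.0 * raw, d, target)
        c1 = np.cov(d @ e1.effects, rowvar=False)
        c2 = np.cov(d @ e2.effects, rowvar=False)
        np.testing.assert_allclose(c1, c2, atol=1e-10)

    def test_scaling_is_idempotent(self, small_spec):
        target = np.array([[1.0, 0.05], [0.05, 0.01]])
        f = self._founders(small_spec)
        raw = sample_raw_effects(small_spec.n_qtl, target, np.random.default_rng(5))
        d = f.dosage(small_spec.qtl_indices)
        once = scale_qtl_effects(raw, d, target)
        twice = scale_qtl_effects(once.effects, d, target)
        np.testing.assert_allclose(once.effects, twice.effects, atol=1e-10)

    def test_singular_raw_covariance_rejected(self, small_spec):
        f = self._founders(small_spec)
        raw = np.zeros((small_spec.n_qtl, 2))
        with pytest.raises(ValueError):
            scale_qtl_effects(raw, f.dosage(small_spec.qtl_indices),
                              np.array([[1.0, 0.0], [0.0, 0.01]]))


class TestTrueValues:
    def test_tbv_formula(self):
        eff = sample_raw_effects(3, np.eye(2), np.random.default_rng(0))
        from sgesim.genome import QTLEffects

        q = QTLEffects(effects=np.array([[0.3, 0.02]]), target=np.eye(2))
        u_d, u_s, u_tbv = true_genetic_values(np.array([[1.0]]), q, 12)
        assert u_d[0] == pytest.approx(0.3)
        assert u_s[0] == pytest.approx(0.02)
        assert u_tbv[0] == pytest.approx(0.3 + 11 * 0.02)

    def test_tbv_reduces_to_dge_without_social_effects(self):
        from sgesim.genome import QTLEffects

        q = QTLEffects(effects=np.array([[0.5, 0.0], [0.2, 0.0]]))
        d = np.array([[2.0, 1.0], [0.0, 2.0]])
        u_d, u_s, u_tbv = true_genetic_values(d, q, 12)
        np.testing.assert_allclose(u_tbv, u_d)
        np.testing.assert_allclose(u_s, 0.0)

    def test_founder_tbv_variance_matches_closed_form(self, small_spec):
        """var(u_TBV) in the scaled founder cohort equals
        s2_D + 2(n-1)s_DS + (n-1)^2 s2_S exactly, by construction."""
        target = np.array([[1.0, 0.0], [0.0, 0.01]])
        f = simulate_founders(small_spec, 300, seed=10)
        raw = sample_raw_effects(small_spec.n_qtl, target, np.random.default_rng(6))
        eff = scale_qtl_effects(raw, f.dosage(small_spec.qtl_indices), target)
        _, _, u_tbv = true_genetic_values(f.dosage(small_spec.qtl_indices), eff, 12)
        assert np.var(u_tbv, ddof=1) == pytest.approx(2.21, abs=1e-8)
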