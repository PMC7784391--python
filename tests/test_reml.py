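"""AI-REML: closed-form checks, likelihood ascent, parameter recovery and
the mis-specification law for the classical model."""

import numpy as np
import pytest

from sgesim.config import ScaleBlock, ScenarioConfig
from sgesim.fixtures import make_fixture
from sgesim.program import run_replicate
from sgesim.reml import ai_reml, choose_vc, fit_reml
from sgesim.traits import VarianceComponents


class TestClosedForm:
    def test_balanced_oneway_matches_anova(self):
        """REML equals the ANOVA estimators in a balanced one-way layout."""
        fx = make_fixture("balanced_oneway", seed=1)
        y = fx.inputs["y"]
        pen = fx.inputs["pen"]
        m = y.size
        v_pen = (pen[:, None] == pen[None, :]).astype(float)
        res = ai_reml(
            y, np.ones((m, 1)),
            [("var_pen", v_pen), ("var_residual", np.eye(m))],
            start=np.array([0.3, 1.2]),
        )
        assert res.converged
        assert res.theta["var_pen"] == pytest.approx(
            fx.expected["var_pen"], abs=fx.tolerance
        )
        assert res.theta["var_residual"] == pytest.approx(
            fx.expected["var_residual"], abs=fx.tolerance
        )


@pytest.fixture(scope="module")
def sgm_dataset():
    sc = ScaleBlock(
        n_sires=4, n_dams=48, litter_size=6, pen_size=12, n_generations=3,
        n_preselect_males=48, n_preselect_females=72, n_select_dams=48,
        n_chromosomes=10, total_map_length=15.0, n_markers=60, n_qtl=400,
    )
    cfg = ScenarioConfig(scheme="SGM_TBV", relationship="A", vc_mode="true",
                         scale=sc, seed=31, evaluate_final=False)
    return cfg


class TestAscentAndDiagnostics:
    def test_restricted_likelihood_is_monotone(self, sgm_dataset):
        rep = run_replicate(sgm_dataset, 0)
        pop = rep.population
        start = VarianceComponents.sgm(0.05, 0.3, sigma2_d=0.4, var_pen=0.6,
                                       var_litter=0.1, var_residual=1.5)
        res = fit_reml(pop.phenotypes, pop.sire, pop.dam, "sgm", start, 12,
                       a_matrix=pop.a_matrix)
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs >= -1e-8)
        assert res.vc is not None and res.vc.model == "sgm"

    def test_iteration_cap_flags_nonconvergence(self, sgm_dataset):
        rep = run_replicate(sgm_dataset, 1)
        pop = rep.population
        start = VarianceComponents.sgm(0.05, 0.0, sigma2_d=0.3,
                                       var_residual=1.0)
        res = fit_reml(pop.phenotypes, pop.sire, pop.dam, "sgm", start, 12,
                       max_iter=2, a_matrix=pop.a_matrix)
        assert not res.converged
        assert res.iterations == 2


class TestRecovery:
    def test_cgm_truth_recovered_on_cgm_data(self):
        """Mean estimates over replicates match the generating values when
        the classical model is the truth."""
        rng_master = np.random.default_rng(77)
        truth = dict(var_dge=1.0, var_pen=0.35, var_litter=0.25, var_residual=2.5)
        n_sires, n_lit, lit = 12, 48, 6
        n_pens = n_lit * lit // 12
        m = n_lit * lit
        est = []
        for rep in range(12):
            rng = np.random.default_rng(rng_master.integers(2**31))
            n_par = n_sires + n_lit
            off_s = np.repeat(np.arange(n_sires), (n_lit // n_sires) * lit)
            off_d = n_sires + np.repeat(np.arange(n_lit), lit)
            sire = np.concatenate([np.full(n_par, -1), off_s])
            dam = np.concatenate([np.full(n_par, -1), off_d])
            from sgesim.relationships import build_A

            a = build_A(sire, dam)
            n = sire.size
            u = np.zeros(n)
            u[:n_par] = rng.normal(0, 1, n_par)
            for i in range(n_par, n):
                u[i] = 0.5 * (u[sire[i]] + u[dam[i]]) + rng.normal(0, np.sqrt(0.5))
            pen = rng.permutation(np.arange(m) // 12)
            litter = np.arange(m) // lit
            y = (
                u[n_par:]
                + rng.normal(0, np.sqrt(truth["var_pen"]), n_pens)[pen]
                + rng.normal(0, np.sqrt(truth["var_litter"]), n_lit)[litter]
                + rng.normal(0, np.sqrt(truth["var_residual"]), m)
            )
            import pandas as pd

            rec = pd.DataFrame({
                "animal": np.arange(n_par, n), "generation": 2,
                "pen": pen, "litter": litter, "y": y,
            })
            start = VarianceComponents(model="cgm", var_dge=0.5, var_pen=0.2,
                                       var_litter=0.4, var_residual=2.0)
            res = fit_reml(rec, sire, dam, "cgm", start, 12, a_matrix=a)
            est.append([res.theta[k] for k in truth])
        est = np.array(est)
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        for j, (k, v) in enumerate(truth.items()):
            assert abs(est[:, j].mean() - v) < 3 * se[j] + 0.02, k

    def test_cgm_pen_variance_absorbs_social_variance(self):
        """Fitting CGM to social-model data at r_DS = 0 inflates the pen
        variance toward s2_pen + (n-2) s2_S (here 0.25 -> 0.35)."""
        sc = ScaleBlock(
            n_sires=5, n_dams=100, litter_size=6, pen_size=12, n_generations=3,
            n_preselect_males=100, n_preselect_females=150, n_select_dams=100,
            n_chromosomes=18, total_map_length=30.0, n_markers=40, n_qtl=800,
        )
        cfg = ScenarioConfig(scheme="SGM_TBV", relationship="A", vc_mode="true",
                             scale=sc, seed=91, evaluate_final=False)
        pens = []
        for rep in range(12):
            r = run_replicate(cfg, rep)
            pop = r.population
            start = VarianceComponents(model="cgm", var_dge=1.1, var_pen=0.3,
                                       var_litter=0.22, var_residual=2.4)
            res = fit_reml(pop.phenotypes, pop.sire, pop.dam, "cgm", start, 12,
                           a_matrix=pop.a_matrix)
            pens.append(res.theta["var_pen"])
        pens = np.array(pens)
        se = pens.std(ddof=1) / np.sqrt(len(pens))
        target = 0.25 + 10 * 0.01
        # closer to the inflated value than to the simulated pen variance,
        # and consistent with the inflated value
        assert abs(pens.mean() - target) < abs(pens.mean() - 0.25)
        assert abs(pens.mean() - target) < 3 * se + 0.02


class TestChooseVC:
    def test_true_mode_returns_simulation_values(self):
        vc = VarianceComponents.sgm(0.01, 0.0)
        assert choose_vc("true", "sgm", vc) is vc

    def test_true_mode_rejected_for_cgm(self):
        vc = VarianceComponents.sgm(0.01, 0.0)
        with pytest.raises(ValueError):
            choose_vc("true", "cgm", vc)

    def test_estimated_mode_returns_reml_fit(self, sgm_dataset):
        rep = run_replicate(sgm_dataset, 2)
        pop = rep.population
        start = VarianceComponents.sgm(0.02, 0.0)
        res = fit_reml(pop.phenotypes, pop.sire, pop.dam, "sgm", start, 12,
                       a_matrix=pop.a_matrix)
        out = choose_vc("estimated", "sgm", sgm_dataset.true_vc, res)
        assert out is res.vc
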