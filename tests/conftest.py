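"""Shared oracles and dataset builders for the test suite.

The oracles here are deliberately independent of the implementation paths
they check: kinship by naive recursion, BLUP via the full phenotypic
covariance matrix, and constrained merit maximization via a generic NLP
solver.
"""

from __future__ import annotations

import functools

import numpy as np
import pandas as pd
import pytest

from sgesim.config import ScaleBlock, ScenarioConfig
from sgesim.program import run_replicate


# ---------------------------------------------------------------------------
# independent oracles


def recursive_kinship(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Coancestry by direct recursion (Malecot), memoized; A = 2 * kinship."""
    n = sire.size

    @functools.lru_cache(maxsize=None)
    def phi(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return 0.5 * (1.0 + phi(int(sire[i]), int(dam[i])))
        if i < j:
            i, j = j, i
        # i is the younger (later) animal
        return 0.5 * (phi(int(sire[i]), j) + phi(int(dam[i]), j))

    a = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            a[i, j] = a[j, i] = 2.0 * phi(i, j)
    return a


def gls_blup(records: pd.DataFrame, a: np.ndarray, vc, group_size: int):
    """BLUP via the full phenotypic covariance matrix (GLS oracle).

    Builds V record by record from first principles and predicts the
    genetic effects of *all* pedigree animals as Cov(u, y) V^-1 (y - X b),
    with b the GLS estimate of the generation means.
    """
    animal = records["animal"].to_numpy()
    m = len(records)
    n = a.shape[0]
    pens = records["pen"].to_numpy()
    mates = []
    for i in range(m):
        same = np.flatnonzero((pens == pens[i]) & (np.arange(m) != i))
        mates.append(animal[same])
    s2d, sds, s2s = vc.var_dge, vc.cov_dge_sge, vc.var_sge
    litters = records["litter"].to_numpy()
    v = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            ai, aj = animal[i], animal[j]
            val = s2d * a[ai, aj]
            val += sds * (a[ai, mates[j]].sum() + a[mates[i], aj].sum())
            val += s2s * a[np.ix_(mates[i], mates[j])].sum()
            if pens[i] == pens[j]:
                val += vc.var_pen
            if litters[i] == litters[j]:
                val += vc.var_litter
            if i == j:
                val += vc.var_residual
            v[i, j] = val
    gens, gidx = np.unique(records["generation"].to_numpy(), return_inverse=True)
    x = np.zeros((m, gens.size))
    x[np.arange(m), gidx] = 1.0
    y = records["y"].to_numpy(dtype=float)
    vinv = np.linalg.inv(v)
    beta = np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ y)
    resid = vinv @ (y - x @ beta)
    cov_d = np.zeros((n, m))
    cov_s = np.zeros((n, m))
    for j in range(m):
        cov_d[:, j] = s2d * a[:, animal[j]] + sds * a[:, mates[j]].sum(axis=1)
        cov_s[:, j] = sds * a[:, animal[j]] + s2s * a[:, mates[j]].sum(axis=1)
    return cov_d @ resid, cov_s @ resid, beta


def ocs_merit_oracle(ebv, a_cand, n_sires, constraint, seed=0):
    """Constrained-merit oracle: SLSQP on the simplex with the coancestry cap."""
    from scipy.optimize import minimize

    ns = n_sires
    nd = a_cand.shape[0] - ns
    d = np.full(nd, 0.5 / nd)
    a_ss = a_cand[:ns, :ns]
    a_sd_d = a_cand[:ns, ns:] @ d
    dam_term = d @ a_cand[ns:, ns:] @ d

    def neg_merit(c):
        return -c @ ebv

    def coan(c):
        return constraint - (0.5 * c @ a_ss @ c + c @ a_sd_d + 0.5 * dam_term)

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(6):
        c0 = rng.dirichlet(np.ones(ns)) * 0.5 if trial else np.full(ns, 0.5 / ns)
        res = minimize(
            neg_merit,
            c0,
            method="SLSQP",
            bounds=[(0.0, 0.5)] * ns,
            constraints=[
                {"type": "eq", "fun": lambda c: c.sum() - 0.5},
                {"type": "ineq", "fun": coan},
            ],
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if res.success and (best is None or res.fun < best):
            best = res.fun
    return -best


# ---------------------------------------------------------------------------
# dataset builders


def tiny_scale(**kwargs) -> ScaleBlock:
    defaults = dict(
        n_sires=2, n_dams=40, n_generations=5, n_markers=200, n_qtl=100,
        n_chromosomes=6, total_map_length=6.0,
    )
    defaults.update(kwargs)
    return ScaleBlock.desk(**defaults)


def small_records(seed: int = 0, n_dams: int = 8, group: int = 6):
    """A compact two-generation dataset with pedigree, pens and phenotypes."""
    sc = ScaleBlock(
        n_sires=2, n_dams=n_dams, litter_size=6, pen_size=group,
        n_generations=3, n_preselect_males=4, n_preselect_females=4,
        n_select_dams=4, n_chromosomes=4, total_map_length=4.0,
        n_markers=60, n_qtl=60,
    )
    cfg = ScenarioConfig(
        scheme="SGM_TBV", relationship="A", vc_mode="true", scale=sc,
        seed=seed, evaluate_final=False,
    )
    rep = run_replicate(cfg, 0)
    return rep.population, cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
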