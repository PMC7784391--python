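"""Average-information REML for the social and classical animal models.

The models are expressed in observation space: the phenotypic covariance is
a linear combination ``V = sum_i theta_i V_i`` of fixed basis matrices (the
genetic direct/covariance/social blocks built from the pedigree
relationship matrix, the pen and litter block-diagonals, and the identity
for the residual).  Scores and the average-information matrix are computed
from the projection matrix P; updates are AI steps safeguarded by
backtracking step-halving and a projection onto the parameter space
(eigenvalue clipping of the 2x2 genetic block), which keeps the restricted
likelihood non-decreasing across accepted iterations.

Convergence follows common animal-breeding solver defaults: Frobenius norm
of the update vector below 1e-7 within 200 iterations; non-convergence is
flagged and the estimates are returned anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.linalg.lapack import dpotrf, dpotri

from sgesim.relationships import build_A
from sgesim.traits import VarianceComponents, SGM, CGM

__all__ = [
    "REMLResult",
    "ai_reml",
    "build_reml_bases",
    "fit_reml",
    "choose_vc",
]

_EIG_FLOOR = 1e-8


@dataclass
class REMLResult:
    """Estimates, uncertainties and diagnostics from one REML run."""

    theta: dict[str, float]
    vc: VarianceComponents | None
    se: dict[str, float]
    loglik_trace: list[float]
    iterations: int
    converged: bool
    update_norm: float
    model: str | None = None


def _chol_inverse(v: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Inverse and log-determinant of a symmetric PD matrix, or None."""
    c, info = dpotrf(v, lower=1, overwrite_a=0)
    if info != 0:
        return None
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    inv, info = dpotri(c, lower=1, overwrite_c=0)
    if info != 0:
        return None
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv, logdet


def _project(theta: np.ndarray, genetic_block: tuple[int, int, int] | None) -> np.ndarray:
    """Clip the parameter vector back into the parameter space."""
    out = theta.copy()
    cov_idx = -1
    if genetic_block is not None:
        i, j, k = genetic_block
        cov_idx = j
        g = np.array([[out[i], out[j]], [out[j], out[k]]])
        w, v = np.linalg.eigh(g)
        if w.min() < _EIG_FLOOR:
            g = v @ np.diag(np.maximum(w, _EIG_FLOOR)) @ v.T
            out[i], out[j], out[k] = g[0, 0], g[0, 1], g[1, 1]
    for idx in range(out.size):
        if idx != cov_idx:
            out[idx] = max(out[idx], _EIG_FLOOR)
    return out


def ai_reml(
    y: np.ndarray,
    x: np.ndarray,
    bases: list[tuple[str, np.ndarray]],
    start: np.ndarray,
    genetic_block: tuple[int, int, int] | None = None,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> REMLResult:
    """Maximize the restricted likelihood of ``V = sum theta_i V_i``.

    Parameters other than the covariance entry named by ``genetic_block``
    are variances and kept non-negative; the genetic 2x2 block is kept
    positive semi-definite by eigenvalue clipping.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.size:
        x = x.T
    m = y.size
    names = [n for n, _ in bases]
    vs = [np.asarray(v, dtype=float) for _, v in bases]
    theta = _project(np.asarray(start, dtype=float).copy(), genetic_block)

    def evaluate(th: np.ndarray):
        v = np.zeros((m, m))
        for t, vi in zip(th, vs):
            v += t * vi
        ci = _chol_inverse(v)
        if ci is None:
            return None
        vinv, logdet_v = ci
        vinv_x = vinv @ x
        xtvx = x.T @ vinv_x
        ci2 = _chol_inverse(xtvx)
        if ci2 is None:
            return None
        xtvx_inv, logdet_x = ci2
        beta = xtvx_inv @ (vinv_x.T @ y)
        py = vinv @ y - vinv_x @ beta
        loglik = -0.5 * (logdet_v + logdet_x + y @ py)
        return {"vinv": vinv, "vinv_x": vinv_x, "xtvx_inv": xtvx_inv, "py": py,
                "loglik": loglik}

    state = evaluate(theta)
    if state is None:
        raise ValueError("starting values give a non-positive-definite V")
    trace = [state["loglik"]]
    converged = False
    update_norm = np.inf
    ai = np.eye(len(vs))
    it = 0
    for it in range(1, max_iter + 1):
        vinv, vinv_x = state["vinv"], state["vinv_x"]
        xtvx_inv, py = state["xtvx_inv"], state["py"]

        score = np.empty(len(vs))
        w = np.empty((len(vs), m))
        pw = np.empty((len(vs), m))
        for i, vi in enumerate(vs):
            w[i] = vi @ py
            # tr(P V_i) = tr(Vinv V_i) - tr((X'VinvX)^-1 X'Vinv V_i Vinv X)
            tr1 = np.sum(vinv * vi)
            b = vinv_x.T @ (vi @ vinv_x)
            tr2 = np.sum(xtvx_inv * b)
            score[i] = -0.5 * ((tr1 - tr2) - py @ w[i])
            tmp = vinv @ w[i] - vinv_x @ (xtvx_inv @ (vinv_x.T @ w[i]))
            pw[i] = tmp
        ai = 0.5 * (w @ pw.T)
        ai = 0.5 * (ai + ai.T)

        try:
            delta = np.linalg.solve(ai + 1e-10 * np.eye(len(vs)) * max(ai.max(), 1.0), score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(ai, score, rcond=None)[0]

        step = 1.0
        accepted = None
        for _ in range(15):
            cand = _project(theta + step * delta, genetic_block)
            cand_state = evaluate(cand)
            if cand_state is not None and cand_state["loglik"] >= state["loglik"] - 1e-10:
                accepted = (cand, cand_state)
                break
            step *= 0.5
        if accepted is None:
            # no ascent direction left: treat as stalled convergence
            update_norm = 0.0
            converged = True
            break
        new_theta, new_state = accepted
        update_norm = float(np.linalg.norm(new_theta - theta))
        theta, state = new_theta, new_state
        trace.append(state["loglik"])
        if update_norm < tol:
            converged = True
            break

    try:
        ai_inv = np.linalg.inv(ai)
        se = np.sqrt(np.clip(np.diag(ai_inv), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(vs), np.nan)
    return REMLResult(
        theta=dict(zip(names, theta.tolist())),
        vc=None,
        se=dict(zip(names, se.tolist())),
        loglik_trace=trace,
        iterations=it,
        converged=converged,
        update_norm=update_norm,
    )


def _social_incidence(records: pd.DataFrame, group_size: int, n_animals: int) -> sp.csr_matrix:
    """Sparse matrix summing pen mates' columns for each record row."""
    animal = records["animal"].to_numpy()
    pen_codes, pen_idx = np.unique(records["pen"].to_numpy(), return_inverse=True)
    order = np.argsort(pen_idx, kind="stable")
    rows, cols = [], []
    m = len(records)
    for start in range(0, m, group_size):
        block = order[start : start + group_size]
        members = animal[block]
        for r, a in zip(block, members):
            mates = members[members != a]
            rows.append(np.full(mates.size, r))
            cols.append(mates)
    return sp.csr_matrix(
        (np.ones(sum(r.size for r in rows)), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, n_animals),
    )


def build_reml_bases(
    records: pd.DataFrame,
    a_matrix: np.ndarray,
    model: str,
    group_size: int,
) -> tuple[list[tuple[str, np.ndarray]], tuple[int, int, int] | None]:
    """Observation-space covariance bases for SGM or CGM.

    Returns the ordered basis list and, for SGM, the index triple of the
    genetic (direct variance, covariance, social variance) parameters.
    """
    animal = records["animal"].to_numpy()
    m = len(records)
    n = a_matrix.shape[0]
    a_rr = a_matrix[np.ix_(animal, animal)]

    pen_codes, pen_idx = np.unique(records["pen"].to_numpy(), return_inverse=True)
    lit_codes, lit_idx = np.unique(records["litter"].to_numpy(), return_inverse=True)
    v_pen = (pen_idx[:, None] == pen_idx[None, :]).astype(float)
    v_lit = (lit_idx[:, None] == lit_idx[None, :]).astype(float)

    if model == CGM:
        bases = [
            ("var_dge", a_rr),
            ("var_pen", v_pen),
            ("var_litter", v_lit),
            ("var_residual", np.eye(m)),
        ]
        return bases, None

    s = _social_incidence(records, group_size, n)
    sa = np.asarray(s @ a_matrix)  # S A, m x n
    v_s = np.asarray(s @ sa.T).T  # S A S'
    v_s = 0.5 * (v_s + v_s.T)
    # direct-social cross block: T_D A S' + S A T_D'
    cross = sa[:, animal]  # S A T_D'
    v_ds = cross + cross.T
    bases = [
        ("var_dge", a_rr),
        ("cov_dge_sge", v_ds),
        ("var_sge", v_s),
        ("var_pen", v_pen),
        ("var_litter", v_lit),
        ("var_residual", np.eye(m)),
    ]
    return bases, (0, 1, 2)


def fit_reml(
    records: pd.DataFrame,
    sire: np.ndarray,
    dam: np.ndarray,
    model: str,
    start: VarianceComponents,
    group_size: int,
    tol: float = 1e-7,
    max_iter: int = 200,
    a_matrix: np.ndarray | None = None,
) -> REMLResult:
    """Pedigree AI-REML fit of SGM or CGM to a phenotype dataset.

    ``records`` uses the same layout as :func:`sgesim.mixed_models.build_mme`
    with ``animal`` indexing the pedigree arrays.  Fixed effects are the
    generation means.
    """
    if a_matrix is None:
        a_matrix = build_A(sire, dam)
    bases, genetic_block = build_reml_bases(records, a_matrix, model, group_size)
    y = records["y"].to_numpy(dtype=float)
    gens, gen_idx = np.unique(records["generation"].to_numpy(), return_inverse=True)
    x = np.zeros((len(records), gens.size))
    x[np.arange(len(records)), gen_idx] = 1.0

    if model == SGM:
        theta0 = np.array(
            [start.var_dge, start.cov_dge_sge, start.var_sge,
             start.var_pen, start.var_litter, start.var_residual]
        )
    else:
        theta0 = np.array(
            [start.var_dge, start.var_pen, start.var_litter, start.var_residual]
        )
    res = ai_reml(y, x, bases, theta0, genetic_block, tol=tol, max_iter=max_iter)
    res.model = model
    t = res.theta
    if model == SGM:
        res.vc = VarianceComponents(
            model=SGM,
            var_dge=t["var_dge"],
            cov_dge_sge=t["cov_dge_sge"],
            var_sge=t["var_sge"],
            var_pen=t["var_pen"],
            var_litter=t["var_litter"],
            var_residual=t["var_residual"],
        )
    else:
        res.vc = VarianceComponents(
            model=CGM,
            var_dge=t["var_dge"],
            var_pen=t["var_pen"],
            var_litter=t["var_litter"],
            var_residual=t["var_residual"],
        )
    return res


def choose_vc(
    vc_mode: str,
    model: str,
    true_vc: VarianceComponents,
    reml_result: REMLResult | None = None,
) -> VarianceComponents:
    """Variance components to plug into BLUP for a scheme.

    ``true`` mode returns the simulation values and is only defined for the
    social model — the classical model's parameters have no simulation
    truth, so requesting them is an error.  ``estimated`` mode returns the
    replicate's generation-3 REML estimate, converged or not.
    """
    if vc_mode == "true":
        if model == CGM:
            raise ValueError("true variance components are not defined for CGM")
        return true_vc
    if vc_mode == "estimated":
        if reml_result is None or reml_result.vc is None:
            raise ValueError("estimated mode requires a REML result")
        if reml_result.vc.model != model:
            raise ValueError("REML result model does not match requested model")
        return reml_result.vc
    raise ValueError(f"unknown vc_mode {vc_mode!r}")
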