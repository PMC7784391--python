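"""Henderson mixed-model equations for the social and classical models.

The social model (SGM) fits, per phenotype record,

    y = generation mean + u_D(self) + sum of u_S over the 11 pen mates
        + pen + litter + residual,

with (u_D, u_S) jointly normal with covariance ``G0 (x) U`` where ``G0`` is
the 2x2 genetic matrix and ``U`` either the pedigree matrix A or the
genomic matrix G.  The classical model (CGM) drops the social term.  Pen
and litter effects carry identity covariance.  The equations are solved by
a preconditioned conjugate gradient with a diagonal (Jacobi) preconditioner;
the generation-mean columns of the fixed block are mutually orthogonal, so
the diagonal *is* the fixed block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from sgesim.traits import VarianceComponents, SGM, CGM

__all__ = [
    "MMESystem",
    "EBVSet",
    "build_mme",
    "solve_pcg",
    "extract_ebv",
    "SCHEME_SGM_TBV",
    "SCHEME_SGM_DGE",
    "SCHEME_CGM_DGE",
]

SCHEME_SGM_TBV = "SGM_TBV"
SCHEME_SGM_DGE = "SGM_DGE"
SCHEME_CGM_DGE = "CGM_DGE"

SCHEME_MODEL = {
    SCHEME_SGM_TBV: SGM,
    SCHEME_SGM_DGE: SGM,
    SCHEME_CGM_DGE: CGM,
}

_GENETIC_EIG_FLOOR = 1e-8


@dataclass
class MMESystem:
    """Assembled mixed-model equations in operator form.

    The coefficient matrix is ``W'W / sigma2_e + blockdiag(0, Kinv,
    I/sigma2_pen, I/sigma2_litter)`` with ``Kinv = inv(G0) (x) inv(U)``.
    ``apply`` performs the matrix-vector product; ``diagonal`` returns the
    matrix diagonal for the preconditioner.
    """

    model: str
    n_fixed: int
    n_animals: int
    n_pens: int
    n_litters: int
    wtw: sp.csr_matrix
    rhs: np.ndarray
    sigma2_e: float
    genetic_precision: np.ndarray  # inv(G0), 1x1 or 2x2
    u_inverse: object  # sparse or dense inverse of the relationship matrix
    var_pen: float
    var_litter: float
    generation_levels: np.ndarray = field(default_factory=lambda: np.array([]))
    pen_levels: np.ndarray = field(default_factory=lambda: np.array([]))
    litter_levels: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_genetic_effects(self) -> int:
        return 2 if self.model == SGM else 1

    @property
    def n_equations(self) -> int:
        return (
            self.n_fixed
            + self.n_genetic_effects * self.n_animals
            + self.n_pens
            + self.n_litters
        )

    def _slices(self) -> dict[str, slice]:
        o = self.n_fixed
        out = {"fixed": slice(0, o)}
        out["u_d"] = slice(o, o + self.n_animals)
        o += self.n_animals
        if self.model == SGM:
            out["u_s"] = slice(o, o + self.n_animals)
            o += self.n_animals
        out["pen"] = slice(o, o + self.n_pens)
        o += self.n_pens
        out["litter"] = slice(o, o + self.n_litters)
        return out

    def _prior_apply(self, v: np.ndarray) -> np.ndarray:
        out = np.zeros_like(v)
        sl = self._slices()
        g = self.genetic_precision
        ud = v[sl["u_d"]]
        tu = self.u_inverse @ ud
        if self.model == SGM:
            us = v[sl["u_s"]]
            ts = self.u_inverse @ us
            out[sl["u_d"]] = g[0, 0] * tu + g[0, 1] * ts
            out[sl["u_s"]] = g[1, 0] * tu + g[1, 1] * ts
        else:
            out[sl["u_d"]] = g[0, 0] * tu
        out[sl["pen"]] = v[sl["pen"]] / self.var_pen
        out[sl["litter"]] = v[sl["litter"]] / self.var_litter
        return out

    def apply(self, v: np.ndarray) -> np.ndarray:
        return self.wtw @ v / self.sigma2_e + self._prior_apply(v)

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.wtw.diagonal()) / self.sigma2_e
        sl = self._slices()
        udiag = (
            self.u_inverse.diagonal()
            if sp.issparse(self.u_inverse)
            else np.diag(self.u_inverse)
        )
        g = self.genetic_precision
        d[sl["u_d"]] += g[0, 0] * udiag
        if self.model == SGM:
            d[sl["u_s"]] += g[1, 1] * udiag
        d[sl["pen"]] += 1.0 / self.var_pen
        d[sl["litter"]] += 1.0 / self.var_litter
        return d

    def dense_lhs(self) -> np.ndarray:
        """Materialized coefficient matrix; for small systems and tests."""
        p = self.n_equations
        lhs = np.asarray(self.wtw.todense()) / self.sigma2_e
        sl = self._slices()
        uinv = (
            np.asarray(self.u_inverse.todense())
            if sp.issparse(self.u_inverse)
            else self.u_inverse
        )
        g = self.genetic_precision
        lhs[sl["u_d"], sl["u_d"]] += g[0, 0] * uinv
        if self.model == SGM:
            lhs[sl["u_d"], sl["u_s"]] += g[0, 1] * uinv
            lhs[sl["u_s"], sl["u_d"]] += g[1, 0] * uinv
            lhs[sl["u_s"], sl["u_s"]] += g[1, 1] * uinv
        lhs[sl["pen"], sl["pen"]] += np.eye(self.n_pens) / self.var_pen
        lhs[sl["litter"], sl["litter"]] += np.eye(self.n_litters) / self.var_litter
        return lhs


@dataclass
class EBVSet:
    """Predicted genetic effects and scheme EBV per animal."""

    data: pd.DataFrame  # columns: animal, u_d, u_s (NaN under CGM), ebv, scheme
    scheme: str | None
    iterations: int
    converged: bool
    fixed_effects: np.ndarray | None = None


def _stable_inverse(g0: np.ndarray) -> np.ndarray:
    """Inverse of the genetic matrix with an eigenvalue floor.

    Estimated genetic matrices can sit on the boundary of the parameter
    space (e.g. a social variance clipped at zero); flooring the eigenvalues
    keeps the prior precision finite so the solver can proceed, mirroring
    how boundary estimates are used as-is in practice.
    """
    w, v = np.linalg.eigh(np.atleast_2d(g0))
    w = np.maximum(w, _GENETIC_EIG_FLOOR)
    return v @ np.diag(1.0 / w) @ v.T


def build_mme(
    records: pd.DataFrame,
    vc: VarianceComponents,
    u_inverse,
    n_animals: int,
    group_size: int,
) -> MMESystem:
    """Assemble the MME for SGM or CGM (chosen by ``vc.model``).

    ``records`` must contain columns ``animal`` (0-based index into the
    relationship structure), ``generation``, ``pen``, ``litter`` and ``y``.
    All members of a pen must have records, so each social-incidence row has
    exactly ``group_size - 1`` ones and excludes the animal itself.
    """
    required = {"animal", "generation", "pen", "litter", "y"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    animal = records["animal"].to_numpy()
    if animal.min() < 0 or animal.max() >= n_animals:
        raise ValueError("record animal index outside relationship structure")
    m = len(records)
    y = records["y"].to_numpy(dtype=float)

    gen_levels, gen_idx = np.unique(records["generation"].to_numpy(), return_inverse=True)
    pen_levels, pen_idx = np.unique(records["pen"].to_numpy(), return_inverse=True)
    lit_levels, lit_idx = np.unique(records["litter"].to_numpy(), return_inverse=True)

    pen_counts = np.bincount(pen_idx)
    if np.any(pen_counts != group_size):
        raise ValueError("every pen in the records must have group_size members")

    rows = [np.arange(m)]
    cols = [gen_idx]
    offset = gen_levels.size
    n_fixed = gen_levels.size

    # direct genetic incidence
    rows.append(np.arange(m))
    cols.append(offset + animal)
    offset += n_animals

    if vc.model == SGM:
        # social incidence: each record points at the pen mates' u_S columns
        order = np.argsort(pen_idx, kind="stable")
        srows = []
        scols = []
        for start in range(0, m, group_size):
            block = order[start : start + group_size]
            members = animal[block]
            for r, a in zip(block, members):
                mates = members[members != a] if np.sum(members == a) == 1 else np.delete(
                    members, np.flatnonzero(members == a)[:1]
                )
                srows.append(np.full(group_size - 1, r))
                scols.append(offset + mates)
        rows.append(np.concatenate(srows))
        cols.append(np.concatenate(scols))
        offset += n_animals

    rows.append(np.arange(m))
    cols.append(offset + pen_idx)
    offset += pen_levels.size
    rows.append(np.arange(m))
    cols.append(offset + lit_idx)
    offset += lit_levels.size

    w = sp.csr_matrix(
        (
            np.ones(sum(r.size for r in rows)),
            (np.concatenate(rows), np.concatenate(cols)),
        ),
        shape=(m, offset),
    )
    wtw = (w.T @ w).tocsr()
    rhs = w.T @ y / vc.var_residual

    return MMESystem(
        model=vc.model,
        n_fixed=n_fixed,
        n_animals=n_animals,
        n_pens=pen_levels.size,
        n_litters=lit_levels.size,
        wtw=wtw,
        rhs=rhs,
        sigma2_e=vc.var_residual,
        genetic_precision=_stable_inverse(vc.genetic_matrix()),
        u_inverse=u_inverse,
        var_pen=vc.var_pen,
        var_litter=vc.var_litter,
        generation_levels=gen_levels,
        pen_levels=pen_levels,
        litter_levels=lit_levels,
    )


def solve_pcg(
    system: MMESystem, tol: float = 1e-8, max_iter: int = 2000
) -> EBVSet:
    """Preconditioned conjugate gradient solve of the assembled MME.

    Terminates when the relative residual norm drops below ``tol`` (default
    1e-8) or after ``max_iter`` rounds (default 2000); non-convergence is
    flagged, not fatal — the solution reached is returned and used as-is.
    """
    b = system.rhs
    bnorm = np.linalg.norm(b)
    x = np.zeros_like(b)
    if bnorm == 0.0:
        return _solution_to_ebvset(system, x, 0, True)
    minv = 1.0 / system.diagonal()
    r = b - system.apply(x)
    z = minv * r
    p = z.copy()
    rz = r @ z
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ap = system.apply(p)
        alpha = rz / (p @ ap)
        x += alpha * p
        r -= alpha * ap
        if np.linalg.norm(r) / bnorm <= tol:
            converged = True
            break
        z = minv * r
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    return _solution_to_ebvset(system, x, it, converged)


def _solution_to_ebvset(
    system: MMESystem, x: np.ndarray, iterations: int, converged: bool
) -> EBVSet:
    sl = system._slices()
    u_d = x[sl["u_d"]]
    u_s = x[sl["u_s"]] if system.model == SGM else np.full(system.n_animals, np.nan)
    df = pd.DataFrame(
        {"animal": np.arange(system.n_animals), "u_d": u_d, "u_s": u_s}
    )
    return EBVSet(
        data=df,
        scheme=None,
        iterations=iterations,
        converged=converged,
        fixed_effects=x[sl["fixed"]],
    )


def extract_ebv(solution: EBVSet, scheme: str, group_size: int) -> EBVSet:
    """Populate the scheme-specific EBV column.

    ``SGM_TBV`` uses the predicted total breeding value
    ``u_d + (n - 1) u_s``; ``SGM_DGE`` and ``CGM_DGE`` use the predicted
    direct effect alone.
    """
    if scheme not in SCHEME_MODEL:
        raise ValueError(f"unknown scheme {scheme!r}")
    df = solution.data.copy()
    if scheme == SCHEME_SGM_TBV:
        if df["u_s"].isna().any():
            raise ValueError("TBV scheme requires social predictions")
        df["ebv"] = df["u_d"] + (group_size - 1) * df["u_s"]
    else:
        df["ebv"] = df["u_d"]
    return EBVSet(
        data=df,
        scheme=scheme,
        iterations=solution.iterations,
        converged=solution.converged,
        fixed_effects=solution.fixed_effects,
    )
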